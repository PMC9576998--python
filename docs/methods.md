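# Methods

## Problem setting

Multi-subject labeled feature data — the motivating case is frontal-EEG
band-power features with a binary mental-workload label — rarely satisfy the
i.i.d. assumption across subjects.  Treating each subject *i* as a domain
D_i with labeling rule f_i, the risk of a classifier transferred to an
unseen subject is bounded by the source risk plus (a) the divergence between
the marginal feature distributions and (b) the mismatch between labeling
rules, min{E_{D_i}1[f_i ≠ f_j], E_{D_j}1[f_i ≠ f_j]}.  The package estimates
both terms for every pair of subjects and aggregates them, so a practitioner
can check whether the covariate-shift assumption (identical p(y|x), shifted
p(x)) is tenable before reaching for a domain-adaptation method that
presumes it.

## Conditional-shift estimator

Each subject's labeling rule is approximated by a k-NN classifier trained on
that subject's sample; μ_{i,j} is the empirical disagreement of subject i's
labels with subject j's approximated rule, and the disparity matrix stores
d_{i,j} = min(μ_{i,j}, μ_{j,i}).  Design choices:

- **k = 5** by default: odd (no vote ties), small enough to track a local
  rule, large enough to smooth single mislabeled neighbors.  Exposed
  everywhere as `k` / `--knn-k`.
- **Determinism**: distance ties resolve to the lowest reference-point
  index (stable argsort over the distance matrix), exact vote ties to label
  0.  The predictor is implemented directly on a scipy distance matrix so
  these tie rules are contractual, not incidental.
- **Diagonal**: d_{i,i} uses a label-stratified 50/50 split of the subject's
  own data (seeded) — it measures the approximation error of f̃_i itself and
  is the natural floor for the off-diagonal entries.
- **Aggregate**: ‖D‖_F / M.  M is the largest Frobenius norm attainable by
  an M×M matrix with entries in [0, 1], so the aggregate is in [0, 1] for
  any M and is 0 iff D is zero.  (Rescaling by the observed maximum instead
  would make values incomparable across feature spaces, which defeats the
  purpose of the aggregate.)
- Per-subject "average cross-subject disparity" summaries are column means
  of the mean disparity matrix over **off-diagonal** entries; the diagonal
  is within-subject approximation error, not a cross-subject quantity.

## Marginal-shift estimator

The H-divergence classifier proxy: pool two subjects' feature samples with
labels = subject identity, and cross-validate a discriminator.  Entries of H
store the **accuracy** of the discriminator (0.5 = indistinguishable, 1 =
disjoint supports); the error-rate view and the proxy A-distance transform
2(1 − 2ε) are available (`as_error`, `h_divergence_proxy`, `--report-error`).
Choices:

- **Discriminator**: random forest, 20 trees, stratified 5-fold CV with
  seeded shuffling.  Workload labels are never read, so the estimate is
  bit-invariant to label permutations.
- **Leaf floor**: `min_samples_leaf=5`.  Fully grown trees are not
  consistent estimators of the Bayes rule in low dimension — on two 1-D
  unit-variance Gaussians two means apart they plateau ≈0.06 below the Bayes
  accuracy Φ(1) ≈ 0.8413 — and a small leaf floor is the standard variance
  control for classifier two-sample tests.  With it the estimator tracks the
  Bayes oracle within ±0.02 at n = 2000 per domain.  Exposed as a parameter.
- **Class balance**: the larger sample of a pair is truncated to the smaller
  (seeded, order-preserving) so chance level is exactly 0.5.
- **Diagonal**: a half-vs-half self-split of each subject, expected at
  chance on exchangeable data; diagonal entries enter the Frobenius
  aggregate (the aggregate therefore has a floor of about 0.5/√M · √M = 0.5
  per-entry contribution on null data, which is visible in all reported
  values and comparable across feature spaces).

## Feature pipeline

Raw recordings (EDF via mne, or delimited text) are band-pass filtered with
a 4th-order Butterworth applied forward–backward (zero phase; ≥20 dB
attenuation one octave beyond each edge after the two passes), resampled to
250 Hz by a polyphase FIR whose anti-alias cutoff follows the target rate,
cut into 4 s epochs with 3 s overlap (E = ⌊(T/rate − 4)/1⌋ + 1; a 600 s
session gives exactly 597 epochs), and reduced to per-channel band powers by
integrating a Hann-windowed periodogram over each band with the trapezoid
rule.  Single-segment epochs make the periodogram coincide with a Welch
estimate.  Band powers are kept linear (a log10 option exists but is off by
default).  The default beta band is 2–30 Hz — the band table the feature set
was defined with, kept verbatim even though it overlaps theta/alpha and
12–30 Hz is the conventional range; pass explicit `BandDefinition`s to
change it.  Zero-phase filtering leaves a startup transient at recording
edges (seconds long, set by the 0.5 Hz edge); band-power tests therefore
evaluate steady-state sections, and practitioners should discard edge epochs.

## Normalization

Four per-subject feature spaces: `none`, `zscore` (β/γ from the subject's
own task rows), `baseline1` (rest segment), `baseline2`
(physical-activity-only segment); x' = (x − β)/γ per feature.  Sample sd
uses ddof=1 (baseline segments are short).  Statistics are never pooled
across subjects.  Zero-variance features raise a named error rather than
being epsilon-regularized — in EEG they almost always mean a dead channel.
Baseline statistics pool all rows of the named phase per subject.

## Repeated-sampling protocol and LOSO

Estimates are repeated over seeded subsamples: 300 task rows per
(subject, session) cell, 30 repetitions, base seed 10; repetition r draws
with seed base_seed + r, giving distinct but reproducible partitions.  Both
sessions of a subject are pooled into one domain (configurable via the
phase/session columns).  LOSO evaluation fits a 30-tree random forest on all
subjects but one, after removing a seeded session-stratified holdout of 200
rows per training subject; training accuracy on the pooled holdout estimates
the source risk, test accuracy on the held-out subject the target risk, and
the gap is |train − test| per repetition (averaging per-repetition absolute
differences; this coincides with |mean − mean| whenever train > test in
every run).  The holdout is refreshed each repetition with the repetition
seed.

## Synthetic generators

`generate_multidomain` emulates an M-subject cohort: domain m draws
x = offset_m + scale_m(±(sep/2)u_m + z), z ~ N(0, I_F), labels from the
linear rule 1[u_m·x > 0] flipped i.i.d. with rate p_m; the session (low/high
workload) is the level implied by the final label, mirroring a design where
each session fixes one workload level.  baseline1 rows come from a shared
rest distribution N(0, I), baseline2 rows from the domain's offset
distribution without class structure.  The marginal control δ_m (offset
along e1) and the conditional controls (rotation θ_m of the rule normal in
the (e_{F−1}, e_F) plane; flip rate p_m) are orthogonal by construction:
feature draws, class-center assignment and flips use independent seeded
child streams, the rule acts on absolute coordinates, and the offset axis is
orthogonal to the rotation plane.  At class_separation = 0 the feature
sample is bit-identical across θ/p settings; with class_separation > 0 the
marginal becomes bimodal along u_m, so rotation then moves the marginal too
— orthogonality experiments use separation 0, recovery/LOSO experiments use
a separated (margin) regime.

What the generator does **not** emulate: EEG nonstationarity, artifacts,
electrode drift, heavy-tailed band-power distributions, or temporal
autocorrelation between epochs.  Passing tests therefore certify the
estimators' statistical behavior (calibration, monotonicity, orthogonality,
recovery), not performance on any particular recording hardware or task.

`generate_synthetic_eeg` emulates the recording structure: per subject, two
~2 min task sessions plus rest and activity-only baselines; each channel is
a sum of four band carriers (2/6/10/20 Hz) with a log-normal per-subject
amplitude scale, a workload multiplier (default 2.0) on alpha and theta in
the high session, and white noise.  EDF export is not provided; synthetic
recordings are written as delimited text (EDF reading is supported).

## Problem sizes and defaults

Library defaults mirror the study scale (M = 9 subjects per group, ~600
task rows per subject × session, F = 16, protocol 300/30/seed 10).  The
`run-study` demo profile and the acceptance script use a scaled-down cohort
(M = 5, 240 rows per session, F = 8, protocol 150/5) — the package's demo
size, chosen so a full four-strategy study completes in about a minute while
every per-cell sample is still large enough for stable forest and k-NN
fits.  Experiment-specific sizes (n = 2000 for flip-rate recovery and the
Bayes-oracle check, n = 1000 per domain for monotonicity grids) follow the
corresponding statistical requirements: recovery bias from the k-NN
approximation error must stay well under the ±0.05 reporting resolution.

## Numerical notes and limitations

- All seeds are mixed through `numpy.random.SeedSequence` (`derive_seed`),
  so matrix cells, repetitions and subjects never share a stream; every
  reported pipeline is bit-reproducible given its seed.
- Disparity entries are exact rationals (counts/N); matrix symmetry is exact
  by construction in both estimators, never approximate.
- μ estimates conflate true labeling-rule mismatch with the k-NN
  approximation error; the matrix diagonal quantifies that error and should
  be read alongside the off-diagonal entries.  With heavy marginal shift the
  cross-domain k-NN evaluation extrapolates and the conditional estimate can
  drift upward (observed ≤ 0.04 at δ = 2 under the default geometry).
- The divergence accuracy saturates at 1, compressing differences between
  strongly shifted pairs; the proxy A-distance view de-compresses them.
- Degenerate inputs raise typed errors (`SchemaError`, `ValidationError`,
  `DataError`) that the CLI maps to exit codes 2/2/3.
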