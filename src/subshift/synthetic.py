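"""Synthetic multi-domain data with independently controllable shifts.

Two generators make the whole pipeline testable without any external
recording download.

``generate_multidomain`` emulates M subject-domains of two-class feature
data.  Each domain draws features from a Gaussian cloud (optionally bimodal
along the labeling direction when ``class_separation`` > 0) with a per-domain
mean offset (marginal-shift control δ_m) and covariance scale; labels come
from a shared linear rule whose normal can be rotated per domain
(conditional-shift control θ_m) and are then flipped i.i.d. with a per-domain
rate p_m (a second, noise-type conditional-shift control).  The two controls
are orthogonal by construction: feature draws, class-center assignment and
label flips use independent seeded streams, the rule acts on absolute
coordinates, and the default offset axis (e1) is orthogonal to the rotation
plane (e_{F-1}, e_F), so changing θ or p at class_separation = 0 leaves the
feature sample bit-identical while changing δ never touches the labels.

``generate_synthetic_eeg`` emulates the recording structure those features
come from: per subject, two task sessions (low/high workload) plus a rest
baseline and a physical-activity-only baseline, each channel a sum of
delta/theta/alpha/beta carriers with per-subject amplitudes, a workload
multiplier on the alpha/theta amplitudes in the high session, and white
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FeatureTable, ValidationError
from .features import RawRecording, features_from_recording

__all__ = [
    "SyntheticSpec",
    "SyntheticEEGSpec",
    "EEGRecord",
    "generate_multidomain",
    "generate_synthetic_eeg",
    "features_from_synthetic_eeg",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of an M-domain two-class synthetic cohort.

    Defaults mirror the study scale: 9 subjects, two sessions of ~600 task
    rows each, 16 features (4 channels x 4 bands), seed 10.  Shift controls
    default to the null (no marginal or conditional shift between domains).
    """

    M: int = 9
    n_per_domain: int = 600  # task rows per session (two sessions per domain)
    F: int = 16
    class_prior: float = 0.5
    marginal_offsets: tuple | None = None  # per-domain scalar δ_m (along e1) or vectors
    covariance_scale: tuple | float = 1.0
    boundary_angles: tuple | float = 0.0  # per-domain rotation θ_m, degrees
    label_flip_rate: tuple | float = 0.0  # per-domain p_m in [0, 0.5]
    class_separation: float = 0.0
    n_baseline: int = 120  # rows per subject per baseline phase
    seed: int = 10

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValidationError("need at least two domains")
        if self.F < 2:
            raise ValidationError("need F >= 2 features")
        if not 0.0 < self.class_prior < 1.0:
            raise ValidationError("class_prior must lie in (0, 1)")
        if self.n_per_domain < 1 or self.n_baseline < 2:
            raise ValidationError("row counts must be positive (>= 2 baselines)")
        for p in np.atleast_1d(self.label_flip_rate):
            if not 0.0 <= p <= 0.5:
                raise ValidationError("label flip rates must lie in [0, 0.5]")
        for s in np.atleast_1d(self.covariance_scale):
            if s <= 0:
                raise ValidationError("covariance scales must be positive")


def _per_domain(value, M: int, F: int | None = None) -> np.ndarray:
    """Broadcast a scalar / per-domain sequence / (M, F) array to M entries."""
    if value is None:
        return np.zeros(M) if F is None else np.zeros((M, F))
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.repeat(arr, M)
    if F is not None:
        if arr.ndim == 1:  # scalar magnitudes: offset along the first axis
            out = np.zeros((M, F))
            out[:, 0] = arr
            arr = out
        if arr.shape != (M, F):
            raise ValidationError(f"expected {M} offsets of dimension {F}")
        return arr
    if arr.shape != (M,):
        raise ValidationError(f"expected one value per domain (M={M})")
    return arr


def _rule_normal(F: int, angle_deg: float) -> np.ndarray:
    """Unit normal of the labeling rule: e_F rotated toward e_{F-1} (or e_1)."""
    theta = np.deg2rad(angle_deg)
    u = np.zeros(F)
    partner = F - 2 if F >= 3 else 0
    u[F - 1] = np.cos(theta)
    u[partner] = np.sin(theta)
    return u


def generate_multidomain(spec: SyntheticSpec) -> FeatureTable:
    """Draw the full feature table for a synthetic cohort.

    Task rows: x = offset_m + scale_m * (±(sep/2) u_m + z), z ~ N(0, I);
    label = 1[u_m · x > 0] flipped i.i.d. with rate p_m; the session is the
    workload level implied by the final label (low/high).  baseline1 rows are
    drawn from a shared rest distribution N(0, I); baseline2 rows from the
    domain's offset distribution without class structure.
    """
    offsets = _per_domain(spec.marginal_offsets, spec.M, spec.F)
    scales = _per_domain(spec.covariance_scale if spec.covariance_scale is not None else 1.0, spec.M)
    angles = _per_domain(spec.boundary_angles, spec.M)
    flips = _per_domain(spec.label_flip_rate, spec.M)
    width = len(str(spec.M - 1))
    frames = []
    for m in range(spec.M):
        subject = f"S{m:0{width}d}"
        rng_x = np.random.default_rng(np.random.SeedSequence([spec.seed, m, 0]))
        rng_y0 = np.random.default_rng(np.random.SeedSequence([spec.seed, m, 1]))
        rng_flip = np.random.default_rng(np.random.SeedSequence([spec.seed, m, 2]))
        rng_base = np.random.default_rng(np.random.SeedSequence([spec.seed, m, 3]))
        u = _rule_normal(spec.F, angles[m])
        n = 2 * spec.n_per_domain
        z = rng_x.standard_normal((n, spec.F))
        if spec.class_separation > 0:
            y0 = rng_y0.random(n) < spec.class_prior
            z = z + np.outer(2 * y0.astype(float) - 1, (spec.class_separation / 2) * u)
        x = offsets[m] + scales[m] * z
        label = (x @ u > 0).astype(int)
        if flips[m] > 0:
            flip_mask = rng_flip.random(n) < flips[m]
            label = np.where(flip_mask, 1 - label, label)
        session = np.where(label == 0, "low", "high")
        task = pd.DataFrame(x, columns=[f"f{i + 1}" for i in range(spec.F)])
        task.insert(0, "subject", subject)
        task.insert(1, "session", session)
        task.insert(2, "phase", "task")
        task.insert(3, "label", label.astype(float))
        b1 = rng_base.standard_normal((spec.n_baseline, spec.F))
        b2 = offsets[m] + scales[m] * rng_base.standard_normal(
            (spec.n_baseline, spec.F)
        )
        baselines = pd.DataFrame(
            np.vstack([b1, b2]), columns=[f"f{i + 1}" for i in range(spec.F)]
        )
        baselines.insert(0, "subject", subject)
        baselines.insert(1, "session", "rest")
        baselines.insert(
            2, "phase",
            ["baseline1"] * spec.n_baseline + ["baseline2"] * spec.n_baseline,
        )
        baselines.insert(3, "label", np.nan)
        frames.append(pd.concat([task, baselines], ignore_index=True))
    frame = pd.concat(frames, ignore_index=True)
    return FeatureTable(frame, [f"f{i + 1}" for i in range(spec.F)])


# ---------------------------------------------------------------------------
# synthetic EEG recordings


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Specification of a small synthetic EEG cohort (recording structure)."""

    subjects: int = 3
    duration_s: float = 120.0
    rate: float = 250.0
    channels: tuple = ("AF7", "FP1", "FP2", "AF8")
    amp_scale_sd: float = 0.2  # log-normal sd of the per-subject amplitude scale
    workload_gain: float = 2.0  # alpha/theta amplitude multiplier, high session
    noise_sd: float = 1.0
    baseline1_s: float = 30.0
    baseline2_s: float = 30.0
    seed: int = 10

    def __post_init__(self) -> None:
        if self.subjects < 1:
            raise ValidationError("need at least one subject")
        if min(self.duration_s, self.baseline1_s, self.baseline2_s) < 4.0:
            raise ValidationError("every segment must hold at least one 4 s epoch")
        if self.rate <= 2 * 20.0:
            raise ValidationError("rate must exceed twice the highest carrier (20 Hz)")


#: carrier frequency (Hz) and base amplitude per canonical band
_CARRIERS = {"delta": (2.0, 4.0), "theta": (6.0, 3.0), "alpha": (10.0, 2.0), "beta": (20.0, 1.0)}


@dataclass
class EEGRecord:
    raw: RawRecording
    subject: str
    session: str
    phase: str


def _oscillation(
    rng: np.random.Generator,
    spec: SyntheticEEGSpec,
    duration_s: float,
    amp_scale: float,
    gains: dict[str, float],
) -> RawRecording:
    t = np.arange(int(round(duration_s * spec.rate))) / spec.rate
    signal = np.empty((len(spec.channels), len(t)))
    for c in range(len(spec.channels)):
        acc = np.zeros_like(t)
        for band, (freq, amp) in _CARRIERS.items():
            phase = rng.uniform(0, 2 * np.pi)
            acc += amp_scale * amp * gains.get(band, 1.0) * np.sin(
                2 * np.pi * freq * t + phase
            )
        acc += spec.noise_sd * rng.standard_normal(len(t))
        signal[c] = acc
    return RawRecording(signal, list(spec.channels), spec.rate)


def generate_synthetic_eeg(spec: SyntheticEEGSpec) -> list[EEGRecord]:
    """Per subject: low/high task sessions plus the two baseline segments."""
    records = []
    for s in range(spec.subjects):
        subject = f"S{s}"
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, s]))
        amp_scale = float(np.exp(rng.normal(0.0, spec.amp_scale_sd)))
        for session in ("low", "high"):
            gains = (
                {"alpha": spec.workload_gain, "theta": spec.workload_gain}
                if session == "high"
                else {}
            )
            raw = _oscillation(rng, spec, spec.duration_s, amp_scale, gains)
            records.append(EEGRecord(raw, subject, session, "task"))
        records.append(
            EEGRecord(
                _oscillation(rng, spec, spec.baseline1_s, amp_scale, {}),
                subject, "rest", "baseline1",
            )
        )
        records.append(
            EEGRecord(
                _oscillation(rng, spec, spec.baseline2_s, amp_scale, {}),
                subject, "rest", "baseline2",
            )
        )
    return records


def features_from_synthetic_eeg(
    spec: SyntheticEEGSpec, **pipeline_kwargs
) -> FeatureTable:
    """Run the feature pipeline over a synthetic cohort; label = session level."""
    tables = []
    for rec in generate_synthetic_eeg(spec):
        label = {"low": 0, "high": 1}.get(rec.session) if rec.phase == "task" else None
        tables.append(
            features_from_recording(
                rec.raw, rec.subject, rec.session, rec.phase, label=label,
                **pipeline_kwargs,
            )
        )
    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    return FeatureTable(frame, tables[0].feature_columns)
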