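"""EEG preprocessing, epoching and band-power feature extraction."""

import numpy as np
import pytest

from subshift import (
    BandDefinition,
    RawRecording,
    ValidationError,
    band_power,
    epoch,
    preprocess,
)


def sine(freq, duration_s=20.0, rate=500.0, amp=1.0):
    t = np.arange(int(duration_s * rate)) / rate
    return RawRecording(amp * np.sin(2 * np.pi * freq * t)[None, :], ["ch"], rate)


def test_preprocess_halves_sample_count_at_half_rate():
    raw = sine(10.0, duration_s=10.0, rate=500.0)
    out = preprocess(raw, target_rate=250.0)
    assert out.rate == 250.0
    assert abs(out.signal.shape[1] - raw.signal.shape[1] // 2) <= 1


def test_preprocess_attenuates_out_of_band_tone():
    # 60 Hz sits above the 45 Hz passband edge; the zero-phase Butterworth
    # must knock its steady-state RMS below 10% of the input RMS (the central
    # section excludes the filter's startup transient at the recording edges)
    raw = sine(60.0, duration_s=60.0, rate=500.0)
    out = preprocess(raw, target_rate=250.0)
    n = out.signal.shape[1]
    mid = slice(n // 4, 3 * n // 4)
    in_rms = np.sqrt(np.mean(raw.signal**2))
    out_rms = np.sqrt(np.mean(out.signal[:, mid] ** 2))
    assert out_rms < 0.1 * in_rms


def test_designed_filter_meets_stopband_contract():
    # >= 20 dB attenuation one octave beyond each band edge, from the
    # transfer function of the designed forward-backward filter
    from scipy import signal as sps

    sos = sps.butter(4, [0.5, 45.0], btype="bandpass", fs=500.0, output="sos")
    _, h = sps.sosfreqz(sos, worN=[0.25, 90.0], fs=500.0)
    assert (np.abs(h) ** 2 <= 0.1).all()  # |H|^2: applied forward and backward


def test_preprocess_passes_in_band_tone():
    raw = sine(10.0, duration_s=20.0, rate=500.0)
    out = preprocess(raw, target_rate=250.0)
    assert np.sqrt(np.mean(out.signal**2)) > 0.8 * np.sqrt(np.mean(raw.signal**2))


def test_preprocess_zero_signal_stays_zero():
    raw = RawRecording(np.zeros((2, 5000)), ["a", "b"], 500.0)
    out = preprocess(raw)
    np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)


def test_preprocess_rejects_band_beyond_nyquist():
    raw = sine(10.0, rate=500.0)
    with pytest.raises(ValidationError, match="Nyquist"):
        preprocess(raw, target_rate=80.0, band=(0.5, 45.0))


def test_epoch_count_examples():
    # 600 s at 250 Hz, 4 s epochs with 3 s overlap -> 597 epochs
    raw = RawRecording(np.zeros((1, 600 * 250)), ["ch"], 250.0)
    assert epoch(raw, 4.0, 3.0).epochs.shape == (597, 1, 1000)
    assert epoch(RawRecording(np.zeros((1, 1000)), ["ch"], 250.0)).epochs.shape[0] == 1
    with pytest.raises(ValidationError, match="shorter"):
        epoch(RawRecording(np.zeros((1, 975)), ["ch"], 250.0))
    with pytest.raises(ValidationError):
        epoch(raw, 4.0, 4.0)


def test_epoch_count_matches_naive_sliding_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        rate = float(rng.choice([100, 128, 200, 250, 500]))
        duration = float(rng.uniform(5.0, 60.0))
        raw = RawRecording(np.zeros((1, int(duration * rate))), ["ch"], rate)
        got = epoch(raw, 4.0, 3.0).epochs.shape[0]
        # naive oracle: count full windows by stepping one hop at a time
        length, hop, n = int(4.0 * rate), int(1.0 * rate), raw.signal.shape[1]
        expect = sum(1 for s in range(0, n, hop) if s + length <= n)
        assert got == expect


def test_band_power_localizes_pure_tone_in_alpha():
    raw = RawRecording(
        np.sin(2 * np.pi * 10.0 * np.arange(1000) / 250.0)[None, :], ["ch"], 250.0
    )
    feats = band_power(epoch(raw))
    assert feats.loc[0, "ch_alpha"] > 10 * feats.loc[0, "ch_theta"]
    assert feats.loc[0, "ch_alpha"] > 10 * feats.loc[0, "ch_delta"]


def test_band_power_white_noise_proportional_to_bandwidth():
    rng = np.random.default_rng(3)
    raw = RawRecording(rng.standard_normal((1, 103 * 250)), ["ch"], 250.0)
    bands = (BandDefinition("narrow", 20.0, 30.0), BandDefinition("wide", 40.0, 80.0))
    feats = band_power(epoch(raw), bands)  # ~100 epochs averaged
    ratio = feats["ch_wide"].mean() / feats["ch_narrow"].mean()
    assert 4.0 * 0.7 < ratio < 4.0 * 1.3


def test_band_power_zero_signal_and_empty_bands():
    raw = RawRecording(np.zeros((1, 2000)), ["ch"], 250.0)
    feats = band_power(epoch(raw))
    assert (feats.to_numpy() == 0).all()
    with pytest.raises(ValidationError):
        band_power(epoch(raw), ())


def test_band_power_partition_approximates_total_power():
    # disjoint bands tiling (0, Nyquist) integrate to the full PSD integral
    rng = np.random.default_rng(4)
    raw = RawRecording(rng.standard_normal((1, 20 * 250)), ["ch"], 250.0)
    epoched = epoch(raw)
    edges = [0.0, 30.0, 60.0, 125.0]
    parts = tuple(
        BandDefinition(f"b{i}", lo, hi) for i, (lo, hi) in enumerate(zip(edges, edges[1:]))
    )
    total = band_power(epoched, (BandDefinition("all", 0.0, 125.0),))
    summed = band_power(epoched, parts).sum(axis=1)
    np.testing.assert_allclose(summed, total["ch_all"], rtol=0.01)


def test_band_power_invariant_to_epoch_order():
    rng = np.random.default_rng(6)
    raw = RawRecording(rng.standard_normal((2, 10 * 250)), ["a", "b"], 250.0)
    epoched = epoch(raw)
    feats = band_power(epoched)
    perm = rng.permutation(epoched.epochs.shape[0])
    epoched.epochs = epoched.epochs[perm]
    permuted = band_power(epoched)
    np.testing.assert_allclose(permuted.to_numpy(), feats.to_numpy()[perm])
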