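"""The nine qEEG features against independently coded brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from edemaeeg import features as ft
from edemaeeg.core import FEATURE_NAMES, ArtifactMask, RawEEG, Segment
from edemaeeg.features import FeatureParams


# --------------------------------------------------------------------------
# independent oracles (direct definitions, no shared code with the package)


def oracle_entropy(x, bins=64):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in x:
        k = int((v - lo) / width)
        counts[min(k, bins - 1)] = counts[min(k, bins - 1)] + 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log2(p)
    return h


def oracle_regularity(x):
    s = sorted((v * v for v in x), reverse=True)
    n = len(s)
    total = sum(s)
    if total == 0:
        return 1.0
    num = sum((i + 1) ** 2 * si for i, si in enumerate(s))
    return min(math.sqrt(num / ((n * n / 3.0) * total)), 1.0)


def oracle_band_power(x, lo, hi, fs):
    nper = min(len(x), int(round(4 * fs)))
    f, pxx = sps.welch(x, fs=fs, nperseg=nper)
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(pxx[sel], f[sel]))


def oracle_bsr(x, fs, thr=5.0, min_s=0.5, smooth_s=0.05):
    w = max(int(round(smooth_s * fs)), 1)
    env = np.convolve(np.abs(np.asarray(x, float)), np.ones(w) / w, mode="same")
    min_run = int(round(min_s * fs))
    suppressed = run = 0
    for b in env < thr:
        if b:
            run += 1
        else:
            if run >= min_run:
                suppressed += run
            run = 0
    if run >= min_run:
        suppressed += run
    return suppressed / len(x)


def oracle_spike(x, fs, k=6.0, wmin=20.0, wmax=140.0, refract_ms=200.0):
    x = [float(v) for v in x]
    med = sorted(x)[len(x) // 2] if len(x) % 2 else \
        0.5 * (sorted(x)[len(x) // 2 - 1] + sorted(x)[len(x) // 2])
    dev = [abs(v - med) for v in x]
    mad = sorted(abs(d - 0) for d in dev)
    madv = mad[len(mad) // 2] if len(mad) % 2 else \
        0.5 * (mad[len(mad) // 2 - 1] + mad[len(mad) // 2])
    thr = k * 1.4826 * madv
    if all(d == 0 for d in dev):
        return 0.0
    refract = max(int(round(refract_ms / 1000 * fs)), 1)
    count, last = 0, -refract - 1
    for i in range(1, len(dev) - 1):
        if not (dev[i] >= dev[i - 1] and dev[i] > dev[i + 1] and dev[i] > thr):
            continue
        if i - last < refract:
            continue
        half = dev[i] / 2
        j = i
        while j > 0 and dev[j] > half:
            j -= 1
        left = float(j) if dev[j] > half else \
            j + (half - dev[j]) / (dev[j + 1] - dev[j])
        j = i
        while j < len(dev) - 1 and dev[j] > half:
            j += 1
        right = float(j) if dev[j] > half else \
            j - 1 + (dev[j - 1] - half) / (dev[j - 1] - dev[j])
        width = (right - left) / fs * 1000
        if wmin <= width <= wmax:
            count += 1
            last = i
    return count / (len(x) / fs / 60)


ORACLES = {
    "ShannonEntropy": lambda x, fs: oracle_entropy(x),
    "Regularity": lambda x, fs: oracle_regularity(x),
    "DeltaPower": lambda x, fs: oracle_band_power(x, 0.5, 4, fs),
    "ThetaPower": lambda x, fs: oracle_band_power(x, 4, 8, fs),
    "AlphaPower": lambda x, fs: oracle_band_power(x, 8, 13, fs),
    "BetaPower": lambda x, fs: oracle_band_power(x, 13, 30, fs),
    "AlphaDeltaRatio": lambda x, fs: oracle_band_power(x, 8, 13, fs)
    / (oracle_band_power(x, 0.5, 4, fs) + 1e-12),
    "SpikeFrequency": lambda x, fs: oracle_spike(x, fs),
    "BurstSuppressionRatio": lambda x, fs: oracle_bsr(x, fs),
}


def test_all_nine_features_match_brute_force_oracles(rng):
    """100 random epochs: every feature agrees with its direct definition."""
    fs = 100.0
    for trial in range(100):
        n = int(rng.integers(10 * fs, 16 * fs))
        kind = trial % 4
        if kind == 0:
            x = 20 * rng.standard_normal(n)
        elif kind == 1:  # burst-suppression-like
            x = 15 * rng.standard_normal(n)
            gate = (rng.random(n // 100 + 1) > 0.6).repeat(100)[:n]
            x = x * np.where(gate, 1.0, 0.05)
        elif kind == 2:  # oscillatory + noise
            t = np.arange(n) / fs
            x = (30 * np.sin(2 * np.pi * 2.5 * t)
                 + 10 * np.sin(2 * np.pi * 10 * t)
                 + 5 * rng.standard_normal(n))
        else:  # spiky
            x = 3 * rng.standard_normal(n)
            for pos in rng.integers(50, n - 50, size=8):
                w = int(0.06 * fs)
                x[pos:pos + w] += 80 * np.sin(np.pi * np.arange(w) / w) ** 2
        got = ft.compute_epoch_features(x, fs)
        for i, name in enumerate(FEATURE_NAMES):
            want = ORACLES[name](x, fs)
            assert got[i] == pytest.approx(want, rel=1e-6, abs=1e-9), \
                f"{name} trial {trial}"


# --------------------------------------------------------------------------
# analytic anchors


def test_entropy_anchors():
    assert ft.shannon_entropy(np.full(500, 3.7)) == 0.0
    x = np.repeat(np.linspace(0.0, 1.0, 64), 10)  # 64 equally filled bins
    assert ft.shannon_entropy(x, bins=64) == pytest.approx(6.0)


def test_entropy_matches_histogram_oracle_precisely(rng):
    x = rng.standard_normal(3000)
    assert ft.shannon_entropy(x) == pytest.approx(oracle_entropy(x), abs=1e-9)


def test_regularity_anchors():
    n = 2000
    t = np.arange(n)
    # constant-amplitude signal: q -> 1 as N -> inf
    assert ft.signal_regularity(np.ones(n)) == pytest.approx(1.0, abs=0.02)
    one = np.zeros(n)
    one[5] = 4.0
    assert ft.signal_regularity(one) == pytest.approx(math.sqrt(3) / n, rel=1e-9)
    assert ft.signal_regularity(np.zeros(n)) == 1.0
    # burst-suppression vs continuous at equal total power
    cont = np.sin(2 * np.pi * 10 * t / 200.0)
    burst = np.concatenate([cont[: n // 4] * 2, np.zeros(3 * n // 4)])
    assert ft.signal_regularity(burst) < ft.signal_regularity(cont)


def test_band_power_anchors():
    fs = 100.0
    t = np.arange(int(30 * fs)) / fs
    alpha_tone = np.sin(2 * np.pi * 10 * t)
    p = {b: ft.band_power(alpha_tone, b, fs) for b in ("delta", "theta",
                                                       "alpha", "beta")}
    for b in ("delta", "theta", "beta"):
        assert p["alpha"] >= 20 * p[b]
    assert all(ft.band_power(np.zeros(3000), b, fs) == 0.0
               for b in ("delta", "theta", "alpha", "beta"))
    mix = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 10 * t)
    assert ft.band_power(mix, "delta", fs) == pytest.approx(
        ft.band_power(mix, "alpha", fs), rel=0.10)


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError):
        ft.band_power(np.zeros(100), "beta", fs=50.0)


def test_alpha_delta_ratio_anchors():
    fs = 100.0
    t = np.arange(int(30 * fs)) / fs
    assert ft.alpha_delta_ratio(np.sin(2 * np.pi * 10 * t), fs) > 100
    assert ft.alpha_delta_ratio(np.sin(2 * np.pi * 2 * t), fs) < 0.01
    mix = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 10 * t)
    assert ft.alpha_delta_ratio(mix, fs) == pytest.approx(1.0, rel=0.15)


def test_bsr_anchors():
    fs = 100.0
    assert ft.burst_suppression_ratio(np.zeros(int(60 * fs)), fs) == 1.0
    t = np.arange(int(60 * fs)) / fs
    loud = 50 * np.sin(2 * np.pi * 10 * t)
    assert ft.burst_suppression_ratio(loud, fs) == 0.0
    # 50% duty cycle: 5 s on / 5 s off
    gate = (np.floor(t / 5.0) % 2 == 0)
    assert ft.burst_suppression_ratio(loud * gate, fs) == pytest.approx(
        0.5, abs=0.05)
    with pytest.raises(ValueError):
        ft.burst_suppression_ratio(np.zeros(100), fs)


def _spiky_epoch(rng, n_spikes, fs=100.0, dur=60.0):
    n = int(dur * fs)
    x = 2.0 * rng.standard_normal(n)
    w = int(0.06 * fs)
    positions = np.linspace(2 * w, n - 2 * w, n_spikes).astype(int)
    for pos in positions:
        x[pos:pos + w] += 100 * np.sin(np.pi * np.arange(w) / w) ** 2
    return x


def test_spike_frequency_anchors(rng):
    fs = 100.0
    t = np.arange(int(60 * fs)) / fs
    assert ft.spike_frequency(np.sin(2 * np.pi * 10 * t), fs) == 0.0
    assert ft.spike_frequency(np.zeros(int(60 * fs)), fs) == 0.0
    x12 = _spiky_epoch(rng, 12)
    assert ft.spike_frequency(x12, fs) == pytest.approx(12.0, abs=1.0)
    x24 = _spiky_epoch(rng, 24)
    assert ft.spike_frequency(x24, fs) == pytest.approx(24.0, abs=1.0)


# --------------------------------------------------------------------------
# invariants (property-based)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.25, 4.0))
def test_scale_equivariance(seed, c):
    """Band powers scale by c^2; regularity is scale-invariant; BSR is
    invariant when its threshold scales with the signal."""
    fs = 100.0
    x = 10 * np.random.default_rng(seed).standard_normal(int(12 * fs))
    for band in ("delta", "alpha"):
        assert ft.band_power(c * x, band, fs) == pytest.approx(
            c * c * ft.band_power(x, band, fs), rel=1e-9)
    assert ft.signal_regularity(c * x) == pytest.approx(
        ft.signal_regularity(x), rel=1e-9)
    assert ft.burst_suppression_ratio(c * x, fs, threshold_uv=5 * c) == \
        ft.burst_suppression_ratio(x, fs, threshold_uv=5.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_features_finite_and_in_range(seed):
    fs = 100.0
    r = np.random.default_rng(seed)
    x = r.uniform(1, 50) * r.standard_normal(int(r.uniform(10, 20) * fs))
    v = ft.compute_epoch_features(x, fs)
    assert np.all(np.isfinite(v))
    assert v[0] >= 0                      # entropy
    assert 0 <= v[1] <= 1                 # regularity
    assert np.all(v[2:6] >= 0)            # band powers
    assert v[6] >= 0                      # ADR
    assert v[7] >= 0                      # spikes/min
    assert 0 <= v[8] <= 1                 # BSR


# --------------------------------------------------------------------------
# epoching / tensor assembly / imputation


def _toy_segment(n_ch=3, fs=10.0, hours=1.0, rng=None):
    n = int(hours * 3600 * fs)
    data = (rng or np.random.default_rng(0)).standard_normal((n_ch, n)) * 20
    eeg = RawEEG(tuple(f"C{i}-D{i}" for i in range(n_ch)), fs, data, 24.0)
    return Segment(eeg, 24.0, hours, 1.0)


def test_epoch_counts():
    seg4 = _toy_segment(hours=4.0)
    blocks, missing = ft.epoch_signal(seg4, None, 300.0)
    assert len(blocks) == 48 and not missing.any()
    seg8 = _toy_segment(hours=8.0)
    blocks, _ = ft.epoch_signal(seg8, None, 300.0)
    assert len(blocks) == 96


def test_fully_flagged_epoch_is_missing():
    seg = _toy_segment(hours=1.0)
    n_win = math.ceil(seg.eeg.n_samples / (10 * seg.eeg.sample_rate))
    mask = ArtifactMask(np.ones((3, int(n_win)), dtype=bool), 10.0)
    _, missing = ft.epoch_signal(seg, mask, 300.0)
    assert missing.all()


def test_feature_tensor_shape_and_all_missing_cases(rng):
    seg = _toy_segment(n_ch=18, fs=80.0, hours=0.2, rng=rng)
    tensor = ft.build_feature_tensor(seg, None, 36.0, "p1")
    assert tensor.values.shape == (20, 18, 9)
    assert not tensor.missing_mask.any()
    empty = Segment(RawEEG(seg.eeg.channel_labels, 80.0,
                           np.empty((18, 0)), 24.0), 24.0, 0.2, 0.0)
    t2 = ft.build_feature_tensor(empty, None, 36.0, "p2")
    assert t2.missing_mask.all() and np.isnan(t2.values).all()


def test_mean_imputation_properties(rng):
    vals = rng.uniform(1, 5, size=(4, 2, 9))
    miss = np.zeros_like(vals, dtype=bool)
    t1 = ft.FeatureTensor("a", 300.0, vals.copy(), miss.copy())
    t2 = ft.FeatureTensor("b", 300.0, vals.copy() + 1, miss.copy())
    t2.values[1, 0, 2] = np.nan
    t2.missing_mask[1, 0, 2] = True
    observed_mean = np.nanmean(np.concatenate(
        [t1.values[..., 2].ravel(), t2.values[..., 2].ravel()]))
    out = ft.impute_missing([t1, t2])
    assert out[1].values[1, 0, 2] == pytest.approx(observed_mean)
    # identity when nothing is missing
    out0 = ft.impute_missing([t1])
    assert np.array_equal(out0[0].values, t1.values)
    # mean preserved after imputation
    post = np.concatenate([o.values[..., 2].ravel() for o in out])
    assert np.mean(post) == pytest.approx(observed_mean, rel=1e-9)


def test_unimputable_feature_raises():
    vals = np.full((2, 2, 9), np.nan)
    t = ft.FeatureTensor("a", 300.0, vals, np.ones_like(vals, dtype=bool))
    with pytest.raises(ft.UnimputableFeatureError):
        ft.impute_missing([t])


def test_standardization_masks_become_neutral(rng):
    vals = rng.normal(5, 2, size=(6, 3, 9))
    miss = np.zeros_like(vals, dtype=bool)
    miss[0, 0, :] = True
    vals[0, 0, :] = np.nan
    t = ft.FeatureTensor("a", 300.0, vals, miss)
    stats = ft.fit_standardization([t])
    z = ft.apply_standardization(t, stats)
    assert np.all(z[0, 0] == 0.0)
    obs = z[~miss.reshape(z.shape[0], z.shape[1], 9)]
    assert abs(obs.mean()) < 1e-9
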