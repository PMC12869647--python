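"""The nine quantitative EEG features, epoching, and cohort-mean imputation.

Feature order (fixed): Shannon entropy, signal regularity, delta/theta/
alpha/beta band power, alpha-delta ratio, spike frequency, burst-suppression
ratio.  All features are computed per derivation per non-overlapping epoch;
epochs that are mostly artifact-flagged or outside recorded time are masked.

Definitions
-----------
* Shannon entropy: entropy in bits of the amplitude histogram with a fixed
  bin count (default 64) over the epoch's observed range; a constant epoch
  has entropy 0.
* Signal regularity: with squared amplitudes sorted descending s(1..N),
  ``q = sqrt( sum_i i^2 s(i) / ((N^2/3) sum_i s(i)) )`` — close to 1 for a
  continuous envelope, near 0 for isolated bursts.
* Band power: Welch-averaged periodogram integrated over the band
  (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30 Hz).
* Alpha-delta ratio: alpha power / (delta power + eps).
* Spike frequency: rate (per minute) of high-amplitude sharp transients —
  local extrema of |x - median| exceeding ``k`` robust SDs (MAD-based)
  whose half-height width falls in a sharpness window, with a refractory
  period between counted events.
* Burst-suppression ratio: fraction of the epoch whose smoothed amplitude
  envelope stays below a suppression threshold for a minimum duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import (
    FEATURE_NAMES,
    ArtifactMask,
    FeatureTensor,
    RawEEG,
    Segment,
    UnimputableFeatureError,
)

__all__ = [
    "BANDS",
    "FeatureParams",
    "epoch_signal",
    "shannon_entropy",
    "band_power",
    "alpha_delta_ratio",
    "signal_regularity",
    "burst_suppression_ratio",
    "spike_frequency",
    "compute_epoch_features",
    "build_feature_tensor",
    "impute_missing",
    "StandardizationStats",
    "fit_standardization",
    "apply_standardization",
]

#: Conventional qEEG band edges in Hz.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass(frozen=True)
class FeatureParams:
    """Tunable constants of the nine features (absolute units, never scaled)."""

    entropy_bins: int = 64
    adr_eps: float = 1e-12
    bsr_threshold_uv: float = 5.0
    bsr_min_suppression_s: float = 0.5
    bsr_smooth_s: float = 0.05
    spike_k_mad: float = 6.0
    spike_width_min_ms: float = 20.0
    spike_width_max_ms: float = 140.0
    spike_refractory_ms: float = 200.0


def epoch_signal(segment: Segment, mask: Optional[ArtifactMask],
                 epoch_length_s: float,
                 missing_fraction: float = 0.5
                 ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Split a segment into non-overlapping epochs aligned to its window.

    Epochs tile the *requested* window ``[start_h, start_h + duration_h)``
    so sequences from partially covered records stay time-aligned.  Returns
    ``(blocks, missing)`` where ``blocks[e]`` is a (n_channels, epoch_samples)
    array (zero-filled where uncovered) and ``missing[e, c]`` is True when
    more than ``missing_fraction`` of epoch ``e`` on channel ``c`` is
    artifact-flagged or uncovered.
    """
    eeg = segment.eeg
    fs = eeg.sample_rate
    ep = int(round(epoch_length_s * fs))
    total = int(round(segment.duration_h * 3600.0 * fs))
    if ep <= 0 or ep > total:
        raise ValueError("epoch length must be positive and fit the segment")
    n_epochs = int(round(total / ep))
    n_ch = eeg.n_channels
    blocks: List[np.ndarray] = []
    missing = np.zeros((n_epochs, n_ch), dtype=bool)
    # offset of the record's first sample inside the requested window
    off = int(round((eeg.t0_hours - segment.start_h) * 3600.0 * fs))
    win_samp = None
    if mask is not None:
        win_samp = int(round(mask.window_length_s * fs))
    for e in range(n_epochs):
        block = np.zeros((n_ch, ep))
        lo, hi = e * ep, (e + 1) * ep  # window-relative sample range
        rec_lo = max(lo - off, 0)
        rec_hi = min(hi - off, eeg.n_samples)
        covered = max(rec_hi - rec_lo, 0)
        if covered > 0:
            block[:, rec_lo + off - lo: rec_hi + off - lo] = eeg.data[:, rec_lo:rec_hi]
        bad = np.full(n_ch, float(ep - covered))  # uncovered samples count as bad
        if covered > 0 and mask is not None:
            for c in range(n_ch):
                w0, w1 = rec_lo // win_samp, (rec_hi - 1) // win_samp + 1
                flagged = mask.mask[c, w0:w1]
                for w in np.nonzero(flagged)[0] + w0:
                    s0 = max(w * win_samp, rec_lo)
                    s1 = min((w + 1) * win_samp, rec_hi)
                    bad[c] += max(s1 - s0, 0)
        missing[e] = bad > missing_fraction * ep
        blocks.append(block)
    return blocks, missing


def shannon_entropy(x: np.ndarray, bins: int = 64) -> float:
    """Entropy (bits) of the amplitude histogram over the epoch's range."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def _welch_psd_batch(X: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    """Welch-averaged periodogram of each row of ``X`` (rows, samples).

    Hann window, 50% overlap, per-segment constant detrend, density
    scaling — the standard averaged-periodogram estimator, computed with
    one batched FFT for speed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[1]
    nper = min(n, int(round(4.0 * fs)))
    step = nper // 2 if nper > 1 else 1
    n_frames = 1 + (n - nper) // step
    idx = (np.arange(nper)[None, :] + step * np.arange(n_frames)[:, None])
    frames = X[:, idx]                       # (rows, frames, nper)
    frames = frames - frames.mean(axis=2, keepdims=True)
    # periodic Hann window
    win = (0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(nper) / nper)
           if nper > 1 else np.ones(1))
    spec = np.fft.rfft(frames * win, axis=2)
    pxx = (np.abs(spec) ** 2) / (fs * np.sum(win ** 2))
    if nper % 2 == 0:
        pxx[..., 1:-1] *= 2.0
    else:
        pxx[..., 1:] *= 2.0
    f = np.fft.rfftfreq(nper, d=1.0 / fs)
    return f, pxx.mean(axis=1)


def _welch_psd(x: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    f, pxx = _welch_psd_batch(np.asarray(x)[None, :], fs)
    return f, pxx[0]


def band_power(x: np.ndarray, band: str, fs: float) -> float:
    """Welch PSD integrated over a named band, in uV^2."""
    lo, hi = BANDS[band]
    if hi > fs / 2.0:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2.0} Hz)")
    x = np.asarray(x, dtype=np.float64)
    f, pxx = _welch_psd(x, fs)
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        return 0.0
    return float(np.trapezoid(pxx[sel], f[sel]))


def alpha_delta_ratio(x: np.ndarray, fs: float, eps: float = 1e-12) -> float:
    """Alpha-band power over delta-band power (eps-guarded)."""
    return band_power(x, "alpha", fs) / (band_power(x, "delta", fs) + eps)


def signal_regularity(x: np.ndarray) -> float:
    """Envelope-continuity statistic in [0, 1].

    Sorted squared amplitudes s(1) >= ... >= s(N) are weighted by the square
    of their rank: a flat envelope keeps mass at high ranks (q -> 1), a
    single spike concentrates it at rank 1 (q -> sqrt(3)/N).  An all-zero
    epoch is defined as maximally regular (1.0).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    s = np.sort(x * x)[::-1]
    total = float(np.sum(s))
    if total == 0.0:
        return 1.0
    i = np.arange(1, n + 1, dtype=np.float64)
    q = math.sqrt(float(np.sum(i * i * s)) / ((n * n / 3.0) * total))
    return min(q, 1.0)


def burst_suppression_ratio(x: np.ndarray, fs: float,
                            threshold_uv: float = 5.0,
                            min_suppression_s: float = 0.5,
                            smooth_s: float = 0.05) -> float:
    """Fraction of the epoch spent in suppression.

    The envelope is a moving average of |x| (window ``smooth_s``);
    suppression is any contiguous run with envelope below ``threshold_uv``
    lasting at least ``min_suppression_s``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size / fs < 10.0:
        raise ValueError("burst-suppression ratio needs epochs >= 10 s")
    w = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(w) / w
    env = np.convolve(np.abs(x), kernel, mode="same")
    below = env < threshold_uv
    min_run = int(round(min_suppression_s * fs))
    edges = np.diff(np.concatenate(([0], below.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    suppressed = int(lengths[lengths >= min_run].sum())
    return suppressed / x.size


def spike_frequency(x: np.ndarray, fs: float, k_mad: float = 6.0,
                    width_min_ms: float = 20.0, width_max_ms: float = 140.0,
                    refractory_ms: float = 200.0) -> float:
    """Sharp high-amplitude transients per minute.

    A candidate is a local maximum of ``d = |x - median(x)|`` exceeding
    ``k_mad`` robust standard deviations (1.4826 * MAD).  It counts as a
    spike when its full width at half prominence lies within the sharpness
    window, and counted events are separated by the refractory period.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        return 0.0
    med = float(np.median(x))
    dev = np.abs(x - med)
    mad = float(np.median(dev))
    thr = k_mad * 1.4826 * mad  # robust SD; 0 for a flat background
    if np.all(dev == 0):
        return 0.0
    refract = max(int(round(refractory_ms / 1000.0 * fs)), 1)
    # candidate local maxima above threshold (plateaus count once, at their
    # left edge: dev rises into and falls out of the sample)
    cand = np.flatnonzero((dev[1:-1] >= dev[:-2]) & (dev[1:-1] > dev[2:])
                          & (dev[1:-1] > thr)) + 1
    count = 0
    last = -refract - 1
    for i in cand:
        if i - last < refract:
            continue
        half = dev[i] / 2.0
        # half-height crossings by backward/forward scan, linear interpolation
        j = i
        while j > 0 and dev[j] > half:
            j -= 1
        if dev[j] > half:
            left = float(j)
        else:
            left = j + (half - dev[j]) / (dev[j + 1] - dev[j])
        j = i
        while j < dev.size - 1 and dev[j] > half:
            j += 1
        if dev[j] > half:
            right = float(j)
        else:
            right = j - 1 + (dev[j - 1] - half) / (dev[j - 1] - dev[j])
        width_ms = (right - left) / fs * 1000.0
        if width_min_ms <= width_ms <= width_max_ms:
            count += 1
            last = i
    minutes = x.size / fs / 60.0
    return count / minutes


def compute_epoch_features(x: np.ndarray, fs: float,
                           params: FeatureParams = FeatureParams()) -> np.ndarray:
    """All nine features of one epoch on one derivation, in canonical order."""
    out = np.empty(9)
    out[0] = shannon_entropy(x, params.entropy_bins)
    out[1] = signal_regularity(x)
    # single Welch PSD shared by the four band integrals
    f, pxx = _welch_psd(np.asarray(x, dtype=np.float64), fs)
    for j, name in enumerate(("delta", "theta", "alpha", "beta")):
        lo, hi = BANDS[name]
        if hi > fs / 2.0:
            raise ValueError(f"band {name} exceeds Nyquist ({fs / 2.0} Hz)")
        sel = (f >= lo) & (f <= hi)
        out[2 + j] = float(np.trapezoid(pxx[sel], f[sel])) if np.any(sel) else 0.0
    out[6] = out[4] / (out[2] + params.adr_eps)
    out[7] = spike_frequency(x, fs, params.spike_k_mad, params.spike_width_min_ms,
                             params.spike_width_max_ms, params.spike_refractory_ms)
    out[8] = burst_suppression_ratio(x, fs, params.bsr_threshold_uv,
                                     params.bsr_min_suppression_s,
                                     params.bsr_smooth_s)
    return out


def build_feature_tensor(segment: Segment, mask: Optional[ArtifactMask],
                         epoch_length_s: float, patient_id: str = "",
                         params: FeatureParams = FeatureParams()) -> FeatureTensor:
    """Nine features for every (epoch, derivation); missing entries are NaN."""
    eeg = segment.eeg
    n_ch = eeg.n_channels
    if segment.empty or segment.coverage == 0.0:
        n_epochs = int(round(segment.duration_h * 3600.0 / epoch_length_s))
        values = np.full((n_epochs, n_ch, 9), np.nan)
        return FeatureTensor(patient_id, epoch_length_s, values,
                             np.ones_like(values, dtype=bool),
                             eeg.channel_labels)
    blocks, missing = epoch_signal(segment, mask, epoch_length_s)
    n_epochs = len(blocks)
    values = np.full((n_epochs, n_ch, 9), np.nan)
    rows = [(e, c) for e in range(n_epochs) for c in range(n_ch)
            if not missing[e, c]]
    if rows:
        fs = eeg.sample_rate
        X = np.stack([blocks[e][c] for e, c in rows])
        f, P = _welch_psd_batch(X, fs)  # one batched FFT for all epochs
        band_vals = {}
        for name, (lo, hi) in BANDS.items():
            if hi > fs / 2.0:
                raise ValueError(f"band {name} exceeds Nyquist ({fs / 2.0} Hz)")
            sel = (f >= lo) & (f <= hi)
            band_vals[name] = (np.trapezoid(P[:, sel], f[sel], axis=1)
                               if np.any(sel) else np.zeros(len(rows)))
        for r, (e, c) in enumerate(rows):
            x = blocks[e][c]
            v = values[e, c]
            v[0] = shannon_entropy(x, params.entropy_bins)
            v[1] = signal_regularity(x)
            v[2], v[3] = band_vals["delta"][r], band_vals["theta"][r]
            v[4], v[5] = band_vals["alpha"][r], band_vals["beta"][r]
            v[6] = v[4] / (v[2] + params.adr_eps)
            v[7] = spike_frequency(x, fs, params.spike_k_mad,
                                   params.spike_width_min_ms,
                                   params.spike_width_max_ms,
                                   params.spike_refractory_ms)
            v[8] = burst_suppression_ratio(x, fs, params.bsr_threshold_uv,
                                           params.bsr_min_suppression_s,
                                           params.bsr_smooth_s)
    missing3 = np.repeat(missing[:, :, None], 9, axis=2)
    return FeatureTensor(patient_id, epoch_length_s, values, missing3,
                         eeg.channel_labels)


def impute_missing(tensors: Sequence[FeatureTensor]) -> List[FeatureTensor]:
    """Cohort-mean imputation (prediction task only).

    Each missing entry is replaced by the mean of that feature's observed
    values pooled over epochs, derivations and patients.  A feature with no
    observed value anywhere raises :class:`UnimputableFeatureError`.
    """
    means = np.empty(9)
    for f in range(9):
        vals = np.concatenate([t.values[..., f][~t.missing_mask[..., f]]
                               for t in tensors])
        if vals.size == 0:
            raise UnimputableFeatureError(FEATURE_NAMES[f])
        means[f] = vals.mean()
    out = []
    for t in tensors:
        t2 = t.copy()
        for f in range(9):
            m = t2.missing_mask[..., f]
            t2.values[..., f][m] = means[f]
        t2.missing_mask[:] = False
        out.append(t2)
    return out


@dataclass
class StandardizationStats:
    """Per-feature z-score statistics fitted on training data only."""

    mean: np.ndarray  # (9,)
    sd: np.ndarray    # (9,)


def fit_standardization(tensors: Sequence[FeatureTensor]) -> StandardizationStats:
    mean = np.empty(9)
    sd = np.empty(9)
    for f in range(9):
        vals = np.concatenate([t.values[..., f][~t.missing_mask[..., f]]
                               for t in tensors])
        if vals.size == 0:
            raise UnimputableFeatureError(FEATURE_NAMES[f])
        mean[f] = vals.mean()
        s = vals.std()
        sd[f] = s if s > 0 else 1.0
    return StandardizationStats(mean, sd)


def apply_standardization(tensor: FeatureTensor,
                          stats: StandardizationStats) -> np.ndarray:
    """Z-scored (epochs, derivations, 9) array; masked entries become 0.

    Zero is the training mean on the standardized scale, so unimputed
    missing entries are neutral inputs to the sequence models.
    """
    z = (tensor.values - stats.mean) / stats.sd
    z[tensor.missing_mask] = 0.0
    z[~np.isfinite(z)] = 0.0
    return z
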