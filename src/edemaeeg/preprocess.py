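"""Recording standardization: montage, filtering, resampling, artifact
rejection by rule, and arrest-relative segment extraction.

The processing chain mirrors standard clinical qEEG practice: re-reference to
a longitudinal bipolar montage, band-pass 0.1-40 Hz (zero-phase Butterworth),
resample to 100 Hz, then flag 10-s windows that trip any of three artifact
rules (high amplitude, low variance, rapid change).  Flagged windows are
excluded from feature computation, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .core import (
    DOUBLE_BANANA,
    ArtifactMask,
    MissingChannelError,
    RawEEG,
    Segment,
)

__all__ = [
    "ArtifactThresholds",
    "to_bipolar",
    "bandpass",
    "resample",
    "detect_artifacts",
    "extract_segment",
    "extract_window",
    "extract_pre_recognition_segment",
    "IneligibleCaseError",
    "MIN_PRE_RECOGNITION_HOURS",
]

#: Minimum EEG available before radiographic recognition for a patient to
#: enter the prediction cohort.  The boundary is strict: exactly this much
#: is not enough.
MIN_PRE_RECOGNITION_HOURS = 1.0


class IneligibleCaseError(ValueError):
    """Case lacks the minimum pre-recognition EEG for the prediction task."""


@dataclass(frozen=True)
class ArtifactThresholds:
    """Rule thresholds for windowed artifact rejection.

    Defaults are common clinical-qEEG heuristics; each is configurable.
    """

    window_s: float = 10.0
    amp_max_uv: float = 500.0       # rule (a): max |amplitude|
    sd_min_uv: float = 0.1          # rule (b): flatline
    diff_max_uv: float = 100.0      # rule (c): one-sample jump

    def __post_init__(self) -> None:
        if min(self.window_s, self.amp_max_uv, self.sd_min_uv, self.diff_max_uv) <= 0:
            raise ValueError("artifact thresholds must be positive")


def to_bipolar(eeg: RawEEG, montage: Sequence[Tuple[str, str]] = DOUBLE_BANANA) -> RawEEG:
    """Re-reference a referential recording to a bipolar montage.

    Derivation i is ``anode - cathode`` labelled ``"A-B"``.  If the input's
    labels already equal the montage's derivation labels the input is
    returned unchanged (identity passthrough).
    """
    deriv_labels = tuple(f"{a}-{b}" for a, b in montage)
    if eeg.channel_labels == deriv_labels:
        return eeg
    rows = []
    for a, b in montage:
        rows.append(eeg.channel(a) - eeg.channel(b))
    return RawEEG(deriv_labels, eeg.sample_rate, np.vstack(rows) if rows else
                  np.empty((0, eeg.n_samples)), eeg.t0_hours)


def _butter_sos(low: float, high: float, fs: float, order: int = 4):
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(eeg: RawEEG, low: float = 0.1, high: float = 40.0,
             order: int = 4) -> RawEEG:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = eeg.sample_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz")
    if eeg.n_samples == 0:
        return eeg.copy()
    sos = _butter_sos(low, high, eeg.sample_rate, order)
    out = np.empty_like(eeg.data)
    for c in range(eeg.n_channels):  # row-wise is faster than the 2-D path
        out[c] = signal.sosfiltfilt(sos, eeg.data[c])
    return RawEEG(eeg.channel_labels, eeg.sample_rate, out, eeg.t0_hours)


def resample(eeg: RawEEG, target_rate: float = 100.0) -> RawEEG:
    """Polyphase resampling to ``target_rate`` (downsampling only).

    The caller is expected to have low-passed the signal below the target
    Nyquist (the standard band-pass does this for targets >= 100 Hz with a
    40 Hz upper edge).
    """
    if target_rate > eeg.sample_rate:
        raise ValueError("upsampling is not supported")
    if target_rate == eeg.sample_rate or eeg.n_samples == 0:
        return eeg.copy()
    frac = Fraction(target_rate / eeg.sample_rate).limit_denominator(1000)
    out = signal.resample_poly(eeg.data, frac.numerator, frac.denominator, axis=1)
    return RawEEG(eeg.channel_labels, target_rate, out, eeg.t0_hours)


def detect_artifacts(eeg: RawEEG,
                     thresholds: ArtifactThresholds = ArtifactThresholds()
                     ) -> ArtifactMask:
    """Flag fixed-length windows per channel where any artifact rule fires.

    Rules (per channel, per window): (a) ``max |x| > amp_max``;
    (b) ``std(x) < sd_min`` (flatline); (c) ``max |diff(x)| > diff_max``
    (rapid change).  The trailing partial window is judged on its samples.
    """
    win = int(round(thresholds.window_s * eeg.sample_rate))
    if win > eeg.n_samples:
        raise ValueError("artifact window longer than the record")
    n_win = math.ceil(eeg.n_samples / win)
    mask = np.zeros((eeg.n_channels, n_win), dtype=bool)
    for w in range(n_win):
        block = eeg.data[:, w * win:(w + 1) * win]
        amp = np.max(np.abs(block), axis=1) > thresholds.amp_max_uv
        flat = np.std(block, axis=1) < thresholds.sd_min_uv
        if block.shape[1] > 1:
            jump = np.max(np.abs(np.diff(block, axis=1)), axis=1) > thresholds.diff_max_uv
        else:
            jump = np.zeros(eeg.n_channels, dtype=bool)
        mask[:, w] = amp | flat | jump
    return ArtifactMask(mask, thresholds.window_s)


def artifact_rule_table(eeg: RawEEG,
                        thresholds: ArtifactThresholds = ArtifactThresholds()
                        ) -> list:
    """(channel, window_start_s, rule) rows for every flagged window.

    A window appears once per rule that fires on it.
    """
    win = int(round(thresholds.window_s * eeg.sample_rate))
    if win > eeg.n_samples:
        raise ValueError("artifact window longer than the record")
    rows = []
    n_win = math.ceil(eeg.n_samples / win)
    for w in range(n_win):
        block = eeg.data[:, w * win:(w + 1) * win]
        start_s = w * thresholds.window_s
        for c, label in enumerate(eeg.channel_labels):
            if np.max(np.abs(block[c])) > thresholds.amp_max_uv:
                rows.append((label, start_s, "high_amplitude"))
            if np.std(block[c]) < thresholds.sd_min_uv:
                rows.append((label, start_s, "low_variance"))
            if block.shape[1] > 1 and \
                    np.max(np.abs(np.diff(block[c]))) > thresholds.diff_max_uv:
                rows.append((label, start_s, "rapid_change"))
    return rows


def _cut(eeg: RawEEG, start_h: float, end_h: float) -> RawEEG:
    """Samples of ``eeg`` inside the half-open arrest-relative window."""
    fs = eeg.sample_rate
    i0 = max(0, int(math.ceil((start_h - eeg.t0_hours) * 3600.0 * fs - 1e-9)))
    i1 = min(eeg.n_samples, int(math.ceil((end_h - eeg.t0_hours) * 3600.0 * fs - 1e-9)))
    i1 = max(i0, i1)
    data = eeg.data[:, i0:i1]
    return RawEEG(eeg.channel_labels, fs, data, eeg.t0_hours + i0 / fs / 3600.0)


def extract_window(eeg: RawEEG, start_h: float, end_h: float) -> Segment:
    """Intersect the recording with ``[start_h, end_h)`` and report coverage."""
    if end_h <= start_h:
        raise ValueError("window must have positive duration")
    lo = max(start_h, eeg.t0_hours)
    hi = min(end_h, eeg.end_hours)
    if hi <= lo:
        empty = RawEEG(eeg.channel_labels, eeg.sample_rate,
                       np.empty((eeg.n_channels, 0)), start_h)
        return Segment(empty, start_h, end_h - start_h, 0.0)
    cut = _cut(eeg, lo, hi)
    coverage = (hi - lo) / (end_h - start_h)
    return Segment(cut, start_h, end_h - start_h, float(coverage))


def extract_segment(eeg: RawEEG, start_h: float = 24.0,
                    duration_h: float = 4.0) -> Segment:
    """Detection-task segment: ``[start_h, start_h + duration_h)`` post-arrest.

    Early-EEG variants use ``start_h=0`` with a window inside the first 24 h.
    Empty coverage yields an empty segment (flagged for downstream
    imputation), never an error.
    """
    return extract_window(eeg, start_h, start_h + duration_h)


def extract_pre_recognition_segment(eeg: RawEEG, t_edema: float,
                                    duration_h: float = 8.0,
                                    enforce_eligibility: bool = True,
                                    min_hours: float = MIN_PRE_RECOGNITION_HOURS
                                    ) -> Segment:
    """Prediction-task window ending at radiographic edema recognition.

    The window ends at ``min(t_edema, record end)`` and extends backward
    ``duration_h`` hours; partial coverage is allowed.  Cases must have
    strictly more than ``min_hours`` of EEG before recognition, otherwise
    :class:`IneligibleCaseError` is raised.
    """
    available = min(t_edema, eeg.end_hours) - eeg.t0_hours
    if enforce_eligibility and not (available > min_hours):
        raise IneligibleCaseError(
            f"case has {max(available, 0.0):.2f} h of pre-recognition EEG "
            f"(> {min_hours} h required)")
    end = min(t_edema, eeg.end_hours)
    return extract_window(eeg, end - duration_h, end)
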