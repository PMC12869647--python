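"""Shared containers and conventions for the edema-EEG pipeline.

Signals are stored in microvolts, time is measured in decimal hours since
return of spontaneous circulation (ROSC), and analysis windows are half-open
intervals ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RawEEG",
    "ArtifactMask",
    "FeatureTensor",
    "PatientRecord",
    "Segment",
    "FEATURE_NAMES",
    "TEN_TWENTY_19",
    "DOUBLE_BANANA",
    "LEFT_DERIVATIONS",
    "RIGHT_DERIVATIONS",
    "MIDLINE_DERIVATIONS",
    "MissingChannelError",
    "UnimputableFeatureError",
]


class MissingChannelError(KeyError):
    """An electrode required by a montage is absent from the recording."""


class UnimputableFeatureError(ValueError):
    """A feature has no observed value anywhere in the cohort."""


#: Canonical order of the nine quantitative EEG features.
FEATURE_NAMES = (
    "ShannonEntropy",
    "Regularity",
    "DeltaPower",
    "ThetaPower",
    "AlphaPower",
    "BetaPower",
    "AlphaDeltaRatio",
    "SpikeFrequency",
    "BurstSuppressionRatio",
)

#: 19-electrode international 10-20 set.
TEN_TWENTY_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: Standard longitudinal-bipolar ("double banana") montage: 18 derivations.
DOUBLE_BANANA = (
    ("Fp1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("Fp2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("Fp1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("Fp2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
)

LEFT_DERIVATIONS = tuple(
    f"{a}-{b}" for a, b in DOUBLE_BANANA if a[-1].isdigit() and int(a[-1]) % 2 == 1
)
RIGHT_DERIVATIONS = tuple(
    f"{a}-{b}" for a, b in DOUBLE_BANANA if a[-1].isdigit() and int(a[-1]) % 2 == 0
)
MIDLINE_DERIVATIONS = tuple(
    f"{a}-{b}" for a, b in DOUBLE_BANANA if a[-1] == "z" or b[-1] == "z"
)


@dataclass
class RawEEG:
    """Multichannel referential or bipolar EEG.

    Attributes
    ----------
    channel_labels : sequence of str
        10-20 electrode names (referential) or "A-B" derivation names.
    sample_rate : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    t0_hours : float
        Hours since arrest (ROSC) at the first sample.
    """

    channel_labels: tuple
    sample_rate: float
    data: np.ndarray
    t0_hours: float = 0.0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    @property
    def end_hours(self) -> float:
        return self.t0_hours + self.duration_h

    def copy(self) -> "RawEEG":
        return RawEEG(self.channel_labels, self.sample_rate, self.data.copy(),
                      self.t0_hours)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as exc:
            raise MissingChannelError(label) from exc


@dataclass
class ArtifactMask:
    """Per-channel boolean mask over fixed-length windows (True = artifact)."""

    mask: np.ndarray  # (n_channels, n_windows) bool
    window_length_s: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be channels x windows")

    @property
    def n_windows(self) -> int:
        return self.mask.shape[1]

    @classmethod
    def empty(cls, n_channels: int, n_samples: int, sample_rate: float,
              window_length_s: float) -> "ArtifactMask":
        n_win = int(np.ceil(n_samples / (window_length_s * sample_rate)))
        return cls(np.zeros((n_channels, n_win), dtype=bool), window_length_s)


@dataclass
class Segment:
    """An arrest-relative analysis window cut from a recording.

    ``eeg`` holds only the covered part of the requested window; ``coverage``
    is the covered fraction of ``[start_h, start_h + duration_h)``.
    """

    eeg: RawEEG
    start_h: float
    duration_h: float
    coverage: float

    @property
    def empty(self) -> bool:
        return self.eeg.n_samples == 0

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


@dataclass
class FeatureTensor:
    """Per-patient sequence of per-epoch, per-derivation qEEG features.

    values has shape (n_epochs, n_derivations, 9) in the fixed
    :data:`FEATURE_NAMES` order; masked entries are NaN until imputed.
    """

    patient_id: str
    epoch_length_s: float
    values: np.ndarray
    missing_mask: np.ndarray
    derivation_labels: tuple = ()
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        if self.values.ndim != 3 or self.values.shape[2] != len(self.feature_names):
            raise ValueError("values must be epochs x derivations x 9")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_derivations(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTensor":
        return FeatureTensor(self.patient_id, self.epoch_length_s,
                             self.values.copy(), self.missing_mask.copy(),
                             self.derivation_labels, self.feature_names)


@dataclass
class PatientRecord:
    """Clinical covariates and edema adjudication for one patient."""

    id: str
    age: float
    sex: str  # "M" / "F"
    witnessed: bool
    ohca: bool
    edema_label: str  # "edema" / "none" / "indeterminate"
    t_eeg_start: float  # hours post-arrest
    t_edema: Optional[float] = None  # hours post-arrest; None unless edema

    def __post_init__(self) -> None:
        if self.edema_label not in ("edema", "none", "indeterminate"):
            raise ValueError(f"unknown edema label {self.edema_label!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if (self.edema_label == "edema") != (self.t_edema is not None):
            raise ValueError("t_edema present iff edema_label == 'edema'")
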