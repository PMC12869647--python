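"""Training-set expansion: controlled noise addition, channel shuffling,
and smooth time masking, plus class balancing.

The canonical transforms operate on raw EEG segments before feature
extraction.  A feature-space "fast mode" applies analogous perturbations
directly to feature tensors (noise at a target SNR on feature values,
within-hemisphere derivation permutation, raised-cosine blending of an
epoch run toward feature means); it exists so large replicated experiments
stay tractable on one CPU and is a documented approximation.

Augmented copies never change a sample's label and always carry provenance
to their source patient so split hygiene can exclude them from test sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    LEFT_DERIVATIONS,
    MIDLINE_DERIVATIONS,
    RIGHT_DERIVATIONS,
    FeatureTensor,
    RawEEG,
)

__all__ = [
    "AugmentPlan",
    "add_noise",
    "channel_shuffle",
    "smooth_time_mask",
    "augment_feature_tensor",
    "balance_training_set",
]


@dataclass(frozen=True)
class AugmentPlan:
    """Settings for one augmentation draw."""

    noise_snr_db: float = 20.0
    mask_length_s: float = 60.0
    mask_taper_s: float = 5.0
    shuffle_scope: str = "within-hemisphere"  # or "all"
    copies_per_patient: int = 0  # extra copies on top of balancing
    mode: str = "raw"  # "raw" | "feature"
    # feature-mode analogue of the time mask, in epochs
    mask_epochs: int = 4

    def __post_init__(self) -> None:
        if not np.isfinite(self.noise_snr_db):
            raise ValueError("noise_snr_db must be finite")
        if self.copies_per_patient < 0:
            raise ValueError("copies_per_patient must be >= 0")
        if self.shuffle_scope not in ("within-hemisphere", "all"):
            raise ValueError(f"unknown shuffle scope {self.shuffle_scope!r}")
        if self.mode not in ("raw", "feature"):
            raise ValueError(f"unknown augmentation mode {self.mode!r}")


def add_noise(eeg: RawEEG, snr_db: float, seed: int,
              zero_power_floor_uv: float = 0.1) -> RawEEG:
    """Add white Gaussian noise at a per-channel target SNR (dB)."""
    rng = np.random.default_rng(seed)
    out = eeg.copy()
    rms = np.sqrt(np.mean(eeg.data ** 2, axis=1))
    noise_rms = rms / (10.0 ** (snr_db / 20.0))
    noise_rms[rms == 0] = zero_power_floor_uv
    out.data += noise_rms[:, None] * rng.standard_normal(eeg.data.shape)
    return out


def _hemisphere_groups(labels: Sequence[str]) -> List[List[int]]:
    groups: Dict[str, List[int]] = {"left": [], "right": [], "mid": []}
    for i, lab in enumerate(labels):
        if lab in LEFT_DERIVATIONS:
            groups["left"].append(i)
        elif lab in RIGHT_DERIVATIONS:
            groups["right"].append(i)
        else:
            groups["mid"].append(i)
    return [g for g in groups.values() if g]


def channel_shuffle(eeg: RawEEG, scope: str = "within-hemisphere",
                    seed: int = 0) -> RawEEG:
    """Permute derivation signals among channel positions.

    The multiset of channel signals is unchanged; only their positions
    move.  ``within-hemisphere`` permutes left, right, and midline chains
    separately.
    """
    if scope == "all":
        groups = [list(range(eeg.n_channels))]
    else:
        groups = _hemisphere_groups(eeg.channel_labels)
    if max(len(g) for g in groups) < 2 and len(groups) == 1:
        raise ValueError("need at least 2 channels in scope")
    rng = np.random.default_rng(seed)
    perm = np.arange(eeg.n_channels)
    for g in groups:
        perm[g] = rng.permutation(np.asarray(g))
    return RawEEG(eeg.channel_labels, eeg.sample_rate, eeg.data[perm],
                  eeg.t0_hours)


def smooth_time_mask(eeg: RawEEG, mask_length_s: float = 60.0,
                     taper_s: float = 5.0, seed: int = 0) -> RawEEG:
    """Multiply all channels by a randomly placed raised-cosine notch.

    The envelope equals 1 outside the masked interval, descends to 0 over
    ``taper_s`` (raised cosine), stays 0 for ``mask_length_s``, and
    ascends back; record length is preserved.
    """
    fs = eeg.sample_rate
    n = eeg.n_samples
    m = int(round(mask_length_s * fs))
    t = int(round(taper_s * fs))
    if m + 2 * t >= n:
        raise ValueError("mask plus tapers must be shorter than the record")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n - m - 2 * t + 1))
    env = np.ones(n)
    ramp = 0.5 * (1.0 + np.cos(np.linspace(0, np.pi, t))) if t else np.empty(0)
    env[start:start + t] = ramp
    env[start + t:start + t + m] = 0.0
    env[start + t + m:start + 2 * t + m] = ramp[::-1]
    out = eeg.copy()
    out.data *= env
    return out


def augment_feature_tensor(tensor: FeatureTensor, plan: AugmentPlan,
                           seed: int,
                           feature_sd: Optional[np.ndarray] = None,
                           feature_mean: Optional[np.ndarray] = None
                           ) -> FeatureTensor:
    """Feature-space analogue of the three raw transforms (fast mode)."""
    rng = np.random.default_rng(seed)
    out = tensor.copy()
    obs = ~out.missing_mask
    if feature_sd is None:
        feature_sd = np.array([
            out.values[..., f][obs[..., f]].std() if obs[..., f].any() else 1.0
            for f in range(out.values.shape[2])])
    if feature_mean is None:
        feature_mean = np.array([
            out.values[..., f][obs[..., f]].mean() if obs[..., f].any() else 0.0
            for f in range(out.values.shape[2])])
    # noise at the configured SNR on the feature scale
    amp = feature_sd / (10.0 ** (plan.noise_snr_db / 20.0))
    out.values += amp * rng.standard_normal(out.values.shape)
    # derivation shuffle
    if plan.shuffle_scope == "all":
        groups = [list(range(out.n_derivations))]
    else:
        groups = _hemisphere_groups(out.derivation_labels) \
            if out.derivation_labels else [list(range(out.n_derivations))]
    perm = np.arange(out.n_derivations)
    for g in groups:
        perm[g] = rng.permutation(np.asarray(g))
    out.values = out.values[:, perm, :]
    out.missing_mask = out.missing_mask[:, perm, :]
    # raised-cosine blend of an epoch run toward the feature means
    k = min(plan.mask_epochs, max(out.n_epochs - 1, 0))
    if k > 0:
        start = int(rng.integers(0, out.n_epochs - k + 1))
        w = 0.5 * (1.0 - np.cos(np.linspace(0, 2 * np.pi, k)))  # 0..1..0
        for j, e in enumerate(range(start, start + k)):
            out.values[e] = (1 - w[j]) * out.values[e] + w[j] * feature_mean
    out.values[out.missing_mask] = np.nan
    return out


@dataclass
class AugmentedSample:
    """A (possibly augmented) cohort member ready for feature extraction."""

    tensor: FeatureTensor
    label: int
    source_id: str
    augmented: bool


def balance_training_set(train: Sequence[Tuple[FeatureTensor, int, str]],
                         plan: AugmentPlan, seed: int,
                         make_copy=None) -> List[AugmentedSample]:
    """Equalize class counts with augmented copies (originals retained).

    ``train`` holds (feature tensor, label, patient id) triples.  The
    minority class is upsampled to the majority count; ``copies_per_patient``
    adds that many extra augmented copies for every patient of both classes.

    ``make_copy(tensor, pid, seed) -> FeatureTensor`` produces one augmented
    copy; the default is the feature-space transform.  Raw-mode pipelines
    pass a callback that re-draws noise/shuffle/mask on the patient's raw
    segment and re-extracts features.
    """
    labels = {label for _, label, _ in train}
    if labels != {0, 1}:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    out = [AugmentedSample(t, label, pid, False) for t, label, pid in train]
    by_class: Dict[int, List[Tuple[FeatureTensor, int, str]]] = {0: [], 1: []}
    for item in train:
        by_class[item[1]].append(item)
    n0, n1 = len(by_class[0]), len(by_class[1])
    minority = 0 if n0 < n1 else 1
    deficit = abs(n1 - n0)
    todo: List[Tuple[FeatureTensor, int, str]] = []
    if deficit:
        pool = by_class[minority]
        picks = rng.integers(0, len(pool), size=deficit)
        todo.extend(pool[i] for i in picks)
    for item in train:
        todo.extend([item] * plan.copies_per_patient)
    for tensor, label, pid in todo:
        sub = int(rng.integers(2 ** 31))
        if make_copy is not None:
            aug = make_copy(tensor, pid, sub)
        else:
            aug = augment_feature_tensor(tensor, plan, seed=sub)
        out.append(AugmentedSample(aug, label, pid, True))
    return out
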