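"""Formats, configuration, logging, and the experiment drivers.

This module ties the stages together: synthetic-cohort (or EDF) input ->
preprocessing -> feature extraction -> augmentation (train only) ->
sequence-model training -> replicated evaluation, for both the detection
task (EEG from 24 h post-arrest, no censoring at recognition) and the
prediction task (EEG windows ending before first radiographic evidence,
matched referents, fine-tuned model).

EDF is the sole raw-signal interchange format: a minimal 16-bit EDF writer
lives here, and reading goes through :mod:`mne`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import augment as aug
from . import evaluate as ev
from . import features as ft
from . import models as md
from . import preprocess as pp
from . import synth as sy
from .core import FEATURE_NAMES, FeatureTensor, PatientRecord, RawEEG, Segment

__all__ = [
    "RunConfig",
    "read_edf",
    "write_edf",
    "export_cohort",
    "tensor_to_csv",
    "tensor_from_csv",
    "tensor_to_npz",
    "tensor_from_npz",
    "prepare_detection_cohort",
    "run_detection",
    "build_prediction_cohort",
    "run_prediction",
    "run_experiment",
]

logger = logging.getLogger("edemaeeg")


# --------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce an experiment from a seed."""

    task: str = "detection"  # detection | prediction | both
    band_low_hz: float = 0.1
    band_high_hz: float = 40.0
    target_rate_hz: float = 100.0
    artifact: pp.ArtifactThresholds = field(default_factory=pp.ArtifactThresholds)
    segment_start_h: float = 24.0
    segment_hours: float = 4.0
    prediction_hours: float = 8.0
    epoch_length_s: float = 300.0
    time_scale: float = 1.0
    augment_enabled: bool = True
    augment: aug.AugmentPlan = field(default_factory=lambda: aug.AugmentPlan(
        mode="feature"))
    model: md.ModelConfig = field(default_factory=md.ModelConfig)
    n_replications: int = 30
    test_fraction: float = 0.16
    prediction_train_fraction: float = 0.58
    attribution_samples: int = 16
    seed: int = 0

    def scaled(self, hours: float) -> float:
        return hours * self.time_scale

    def validate(self) -> None:
        if self.task not in ("detection", "prediction", "both"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task in ("prediction", "both") and self.prediction_hours <= 0:
            raise ValueError("prediction task requires prediction_hours > 0")
        self.model.validate()

    # ---- lossless round trip through YAML, unknown keys rejected ----
    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        def build(dc_type, data: Dict):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(names)
            if unknown:
                raise ValueError(f"unknown config keys for "
                                 f"{dc_type.__name__}: {sorted(unknown)}")
            kwargs = {}
            for k, v in data.items():
                f_type = names[k].type
                if k == "artifact":
                    v = build(pp.ArtifactThresholds, v)
                elif k == "augment":
                    v = build(aug.AugmentPlan, v)
                elif k == "model":
                    v = build(md.ModelConfig, v)
                kwargs[k] = v
            return dc_type(**kwargs)

        return build(cls, d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# EDF input/output


def write_edf(eeg: RawEEG, path: str, patient_id: str = "X") -> None:
    """Minimal EDF writer: 1-s data records, 16-bit samples, uV units.

    The sample rate must be a whole number; the trailing partial second is
    dropped (EDF stores whole data records).
    """
    fs = eeg.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    spr = int(round(fs))
    n_rec = eeg.n_samples // spr
    nch = eeg.n_channels
    phys_max = max(float(np.max(np.abs(eeg.data))), 1.0) * 1.0001
    dig_max = 32767

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad(f"{patient_id} X X X", 80))
        fh.write(pad("Startdate 01-JAN-2020 X X X", 80))
        fh.write(pad("01.01.20", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (nch + 1)), 8))
        fh.write(pad("", 44))
        fh.write(pad(str(n_rec), 8))
        fh.write(pad("1", 8))
        fh.write(pad(str(nch), 4))
        for lab in eeg.channel_labels:
            fh.write(pad(f"EEG {lab}", 16))
        fh.write(pad("", 80) * nch)          # transducer
        fh.write(pad("uV", 8) * nch)         # physical dimension
        fh.write(pad(f"{-phys_max:.6g}"[:8], 8) * nch)
        fh.write(pad(f"{phys_max:.6g}"[:8], 8) * nch)
        fh.write(pad(str(-dig_max), 8) * nch)
        fh.write(pad(str(dig_max), 8) * nch)
        fh.write(pad("", 80) * nch)          # prefiltering
        fh.write(pad(str(spr), 8) * nch)
        fh.write(pad("", 32) * nch)
        scale = dig_max / phys_max
        for r in range(n_rec):
            block = eeg.data[:, r * spr:(r + 1) * spr]
            dig = np.clip(np.round(block * scale), -dig_max, dig_max)
            fh.write(dig.astype("<i2").tobytes())


def read_edf(path: str, t0_hours: float = 0.0) -> RawEEG:
    """Read an EDF file into :class:`RawEEG` (uV), via mne.

    ``t0_hours`` (hours since arrest at the first sample) comes from the
    cohort metadata table, not from the file.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volt -> uV
    labels = []
    for name in raw.ch_names:
        labels.append(name[4:] if name.startswith("EEG ") else name)
    return RawEEG(tuple(labels), float(raw.info["sfreq"]), data, t0_hours)


def export_cohort(config: sy.SynthConfig, out_dir: str) -> pd.DataFrame:
    """Write one EDF per patient plus metadata CSV and config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = sy.generate_cohort(config, with_eeg=False)
    rows = []
    for p, eeg, _truth in sy.iter_cohort_eeg(config, patients):
        write_edf(eeg, str(out / f"{p.record.id}.edf"), p.record.id)
        r = p.record
        rows.append({"id": r.id, "class": r.edema_label, "age": r.age,
                     "sex": r.sex, "witnessed": r.witnessed, "ohca": r.ohca,
                     "t_eeg_start_h": r.t_eeg_start, "t_edema_h": r.t_edema})
    meta = pd.DataFrame(rows)
    meta.to_csv(out / "metadata.csv", index=False)
    with open(out / "synth_config.yaml", "w") as fh:
        yaml.safe_dump(_synth_config_dict(config), fh, sort_keys=True)
    return meta


def _synth_config_dict(config: sy.SynthConfig) -> Dict:
    d = asdict(config)
    return d


def tensor_to_csv(tensor: FeatureTensor, path: str) -> None:
    """Flat CSV serialization (one row per epoch x derivation x feature)."""
    e, d, f = np.meshgrid(np.arange(tensor.n_epochs),
                          np.arange(tensor.n_derivations),
                          np.arange(9), indexing="ij")
    derivs = (list(tensor.derivation_labels) if tensor.derivation_labels
              else [str(i) for i in range(tensor.n_derivations)])
    df = pd.DataFrame({
        "patient_id": tensor.patient_id,
        "epoch_index": e.ravel(),
        "derivation": np.array(derivs)[d.ravel()],
        "feature": np.array(FEATURE_NAMES)[f.ravel()],
        "value": tensor.values.ravel(),
        "missing": tensor.missing_mask.ravel(),
    })
    df.to_csv(path, index=False)


def tensor_to_npz(tensor: FeatureTensor, path: str) -> None:
    """Compact binary container; lossless round trip."""
    np.savez_compressed(
        path, values=tensor.values, missing=tensor.missing_mask,
        epoch_length_s=np.array(tensor.epoch_length_s),
        patient_id=np.array(tensor.patient_id),
        derivations=np.array(list(tensor.derivation_labels), dtype=object))


def tensor_from_npz(path: str) -> FeatureTensor:
    with np.load(path, allow_pickle=True) as z:
        return FeatureTensor(str(z["patient_id"]), float(z["epoch_length_s"]),
                             z["values"], z["missing"],
                             tuple(z["derivations"].tolist()))


def tensor_from_csv(path: str, epoch_length_s: float) -> FeatureTensor:
    df = pd.read_csv(path)
    derivs = list(dict.fromkeys(df["derivation"].astype(str)))
    n_e = int(df["epoch_index"].max()) + 1
    values = np.full((n_e, len(derivs), 9), np.nan)
    missing = np.ones_like(values, dtype=bool)
    d_idx = {d: i for i, d in enumerate(derivs)}
    f_idx = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for row in df.itertuples(index=False):
        i, j, k = int(row.epoch_index), d_idx[str(row.derivation)], f_idx[row.feature]
        values[i, j, k] = row.value
        missing[i, j, k] = bool(row.missing)
    return FeatureTensor(str(df["patient_id"].iloc[0]), epoch_length_s,
                         values, missing, tuple(derivs))


# --------------------------------------------------------------------------
# per-patient feature extraction


def _preprocess(eeg: RawEEG, cfg: RunConfig) -> RawEEG:
    if eeg.channel_labels != tuple(f"{a}-{b}" for a, b in pp.DOUBLE_BANANA):
        eeg = pp.to_bipolar(eeg)
    eeg = pp.bandpass(eeg, cfg.band_low_hz, cfg.band_high_hz)
    target = min(cfg.target_rate_hz, eeg.sample_rate)
    return pp.resample(eeg, target)


def _segment_tensor(eeg: RawEEG, cfg: RunConfig, start_h: float,
                    duration_h: float, pid: str) -> FeatureTensor:
    seg = pp.extract_window(eeg, start_h, start_h + duration_h)
    mask = None
    if not seg.empty:
        mask = pp.detect_artifacts(seg.eeg, cfg.artifact)
    return ft.build_feature_tensor(seg, mask, cfg.epoch_length_s * cfg.time_scale,
                                   patient_id=pid)


_FILTER_PAD_H = 30.0 / 3600.0  # absorb zero-phase filter edge transients


def detection_tensor(eeg: RawEEG, cfg: RunConfig, pid: str) -> FeatureTensor:
    """Preprocess one recording and extract the detection-segment features.

    Filtering runs on a padded cut around the segment rather than the whole
    recording; the pad absorbs the filter's edge transients.
    """
    start = cfg.scaled(cfg.segment_start_h)
    dur = cfg.scaled(cfg.segment_hours)
    padded = pp.extract_window(eeg, start - _FILTER_PAD_H,
                               start + dur + _FILTER_PAD_H)
    if padded.empty:
        return _segment_tensor(eeg, cfg, start, dur, pid)
    clean = _preprocess(padded.eeg, cfg)
    return _segment_tensor(clean, cfg, start, dur, pid)


def prepare_detection_cohort(synth_cfg: sy.SynthConfig, cfg: RunConfig
                             ) -> Tuple[List[PatientRecord], Dict[str, FeatureTensor]]:
    """Stream the synthetic cohort through preprocessing + features."""
    patients = sy.generate_cohort(synth_cfg, with_eeg=False)
    tensors: Dict[str, FeatureTensor] = {}
    records: List[PatientRecord] = []
    for p, eeg, _ in sy.iter_cohort_eeg(synth_cfg, patients):
        tensors[p.record.id] = detection_tensor(eeg, cfg, p.record.id)
        records.append(p.record)
    return records, tensors


# --------------------------------------------------------------------------
# training-set assembly


def _flatten(z: np.ndarray) -> np.ndarray:
    # (epochs, derivations, 9) -> (epochs, derivations*9)
    return z.reshape(z.shape[0], -1)


def _build_samples(ids: Sequence[str], tensors: Dict[str, FeatureTensor],
                   labels: Dict[str, int], cfg: RunConfig, seed: int,
                   augmented: bool
                   ) -> Tuple[List[md.TrainSample], ft.StandardizationStats]:
    train = [(tensors[i], labels[i], i) for i in ids]
    if augmented:
        balanced = aug.balance_training_set(train, cfg.augment, seed)
    else:
        balanced = [aug.AugmentedSample(t, lab, pid, False)
                    for t, lab, pid in train]
    stats = ft.fit_standardization([s.tensor for s in balanced
                                    if not s.augmented])
    samples = [md.TrainSample(_flatten(ft.apply_standardization(s.tensor, stats)),
                              s.label, s.source_id, s.augmented)
               for s in balanced]
    return samples, stats


# --------------------------------------------------------------------------
# detection experiment


def run_detection(records: Sequence[PatientRecord],
                  tensors: Dict[str, FeatureTensor], cfg: RunConfig,
                  architecture: Optional[str] = None,
                  augmented: Optional[bool] = None,
                  with_attribution: bool = False,
                  splits: Optional[List[ev.SplitPlan]] = None
                  ) -> Tuple[List[ev.ReplicationResult], Dict]:
    """The replicated detection experiment on extracted feature tensors."""
    cfg.validate()
    arch = architecture or cfg.model.architecture
    use_aug = cfg.augment_enabled if augmented is None else augmented
    labels = {r.id: 1 if r.edema_label == "edema" else 0 for r in records}
    if splits is None:
        splits = ev.make_detection_splits(records, cfg.test_fraction,
                                          cfg.n_replications, seed=cfg.seed)
    results: List[ev.ReplicationResult] = []
    for plan in splits:
        rep_seed = (cfg.seed * 100003 + plan.replication_index) % (2 ** 31)
        samples, stats = _build_samples(plan.train_ids, tensors, labels, cfg,
                                        seed=rep_seed, augmented=use_aug)
        mcfg = dataclasses.replace(cfg.model, architecture=arch, seed=rep_seed)
        model = md.build_model(mcfg)
        trained = md.train(model, samples, mcfg)
        test_x = np.stack([_flatten(ft.apply_standardization(tensors[i], stats))
                           for i in plan.test_ids])
        test_y = np.array([labels[i] for i in plan.test_ids])
        probs = md.predict_proba(trained, test_x)
        metrics = ev.compute_metrics(test_y, probs)
        attributions = None
        if with_attribution:
            raw = np.stack([np.where(tensors[i].missing_mask, np.nan,
                                     tensors[i].values)
                            for i in plan.test_ids])
            bg = np.stack([tensors[i].values for i in plan.train_ids])
            bg_mean = np.nanmean(np.where(
                np.stack([tensors[i].missing_mask for i in plan.train_ids]),
                np.nan, bg), axis=0)
            bg_mean = np.where(np.isfinite(bg_mean), bg_mean, 0.0)
            raw = np.where(np.isfinite(raw), raw, bg_mean[None])

            def fn(x_flat: np.ndarray) -> np.ndarray:
                # attribute on the logit scale: stable rankings even when
                # the probability saturates on well-separated cohorts
                from .autodiff import no_grad
                shp = (-1,) + tensors[plan.test_ids[0]].values.shape
                z = (x_flat.reshape(shp) - stats.mean) / stats.sd
                with no_grad():
                    return trained.model.logits(_flatten_batch(z)).data

            attributions = ev.attribute_features(
                fn, raw, bg_mean,
                n_coalition_samples=cfg.attribution_samples,
                seed=rep_seed)
        results.append(ev.ReplicationResult(plan.replication_index, metrics,
                                            attributions,
                                            {"architecture": arch,
                                             "augmented": use_aug}))
    summary = ev.summarize_replications(results)
    if with_attribution:
        stacked = np.stack([r.attributions for r in results
                            if r.attributions is not None])
        summary["attribution_mean_abs"] = {
            name: float(v) for name, v in zip(FEATURE_NAMES,
                                              stacked.mean(axis=0))}
    return results, summary


def _flatten_batch(z: np.ndarray) -> np.ndarray:
    return z.reshape(z.shape[0], z.shape[1], -1)


# --------------------------------------------------------------------------
# prediction experiment


@dataclass
class PredictionCohort:
    """Matched case-referent cohort with pre-recognition feature tensors."""

    pairs: List[ev.MatchedPair]
    records: Dict[str, PatientRecord]
    tensors: Dict[str, FeatureTensor]
    exclusions: List[Dict[str, str]] = field(default_factory=list)


def build_prediction_cohort(synth_cfg: sy.SynthConfig,
                            records: Sequence[PatientRecord],
                            cfg: RunConfig) -> PredictionCohort:
    """Select eligible cases, match referents, and extract pre-recognition
    windows (referent windows placed at the matched case's arrest-relative
    times).  Missing feature entries are imputed from cohort means."""
    min_h = cfg.scaled(pp.MIN_PRE_RECOGNITION_HOURS)
    dur = cfg.scaled(cfg.prediction_hours)
    exclusions: List[Dict[str, str]] = []
    by_id = {r.id: r for r in records}
    record_end = {r.id: r.t_eeg_start
                  + synth_cfg.record_hours * synth_cfg.time_scale
                  for r in records}
    cases = []
    for r in records:
        if r.edema_label != "edema":
            continue
        available = min(r.t_edema, record_end[r.id]) - r.t_eeg_start
        if available > min_h:
            cases.append(r)
        else:
            reason = "<%.3g h pre-recognition EEG" % min_h
            exclusions.append({"id": r.id, "reason": reason})
            logger.info("excluded %s: %s", r.id, reason)
    pool = [r for r in records if r.edema_label == "none"]
    pairs = ev.match_referents(cases, pool, seed=cfg.seed)
    windows: Dict[str, Tuple[float, float]] = {}
    for pair in pairs:
        case = by_id[pair.case_id]
        end = min(case.t_edema, record_end[case.id])
        windows[pair.case_id] = (end - dur, end)
        windows[pair.referent_id] = (end - dur, end)
    tensors: Dict[str, FeatureTensor] = {}
    wanted = set(windows)
    patients = [p for p in sy.generate_cohort(synth_cfg, with_eeg=False)
                if p.record.id in wanted]
    for p, eeg, _ in sy.iter_cohort_eeg(synth_cfg, patients):
        pid = p.record.id
        lo, hi = windows[pid]
        padded = pp.extract_window(eeg, lo - _FILTER_PAD_H, hi + _FILTER_PAD_H)
        clean = _preprocess(padded.eeg if not padded.empty else eeg, cfg)
        tensors[pid] = _segment_tensor(clean, cfg, lo, hi - lo, pid)
    imputed = ft.impute_missing([tensors[i] for i in sorted(tensors)])
    tensors = {t.patient_id: t for t in imputed}
    recs = {pid: by_id[pid] for pid in tensors}
    return PredictionCohort(pairs, recs, tensors, exclusions)


def run_prediction(cohort: PredictionCohort, cfg: RunConfig,
                   source_model: Optional[md.TrainedModel] = None,
                   detection_pool: Optional[Tuple[Sequence[PatientRecord],
                                                  Dict[str, FeatureTensor]]] = None
                   ) -> Tuple[List[ev.ReplicationResult], Dict]:
    """Replicated prediction experiment with optional fine-tuning.

    When ``detection_pool`` is given, a detection model is first trained per
    replication on the full detection cohort minus the replication's test
    patients, then fine-tuned on the prediction training pairs.  When
    ``source_model`` is given it is used as the shared starting point.
    Without either, models are trained from scratch on the pairs.
    """
    cfg.validate()
    labels = {pid: 1 if r.edema_label == "edema" else 0
              for pid, r in cohort.records.items()}
    splits = ev.make_prediction_splits(cohort.pairs,
                                       cfg.prediction_train_fraction,
                                       cfg.n_replications, seed=cfg.seed + 7)
    results = []
    for plan in splits:
        rep_seed = (cfg.seed * 100003 + 500 + plan.replication_index) % (2 ** 31)
        samples, stats = _build_samples(plan.train_ids, cohort.tensors, labels,
                                        cfg, seed=rep_seed,
                                        augmented=cfg.augment_enabled)
        mcfg = dataclasses.replace(cfg.model, seed=rep_seed)
        if source_model is not None:
            mcfg = dataclasses.replace(mcfg,
                                       architecture=source_model.architecture)
            trained = md.fine_tune(source_model, samples, mcfg)
        else:
            trained = md.train(md.build_model(mcfg), samples, mcfg)
        test_x = np.stack([_flatten(ft.apply_standardization(
            cohort.tensors[i], stats)) for i in plan.test_ids])
        test_y = np.array([labels[i] for i in plan.test_ids])
        probs = md.predict_proba(trained, test_x)
        results.append(ev.ReplicationResult(plan.replication_index,
                                            ev.compute_metrics(test_y, probs)))
    return results, ev.summarize_replications(results)


# --------------------------------------------------------------------------
# top-level driver


def run_experiment(cfg: RunConfig, synth_cfg: sy.SynthConfig,
                   out_dir: Optional[str] = None) -> Dict:
    """Execute the configured experiment end to end; optionally persist.

    Outputs (when ``out_dir`` is given) land in ``<out_dir>/run-<hash>/``
    where ``<hash>`` digests the config, so a changed configuration never
    silently overwrites an earlier run.
    """
    cfg.validate()
    from . import __version__

    summary: Dict = {"config_hash": cfg.config_hash(),
                     "tool_version": __version__,
                     "timestamp": _dt.datetime.now().isoformat(),
                     "tasks": {}}
    records, tensors = prepare_detection_cohort(synth_cfg, cfg)
    all_results: Dict[str, List[ev.ReplicationResult]] = {}
    if cfg.task in ("detection", "both"):
        results, det_summary = run_detection(records, tensors, cfg)
        summary["tasks"]["detection"] = det_summary
        all_results["detection"] = results
    if cfg.task in ("prediction", "both"):
        pred_cohort = build_prediction_cohort(synth_cfg, records, cfg)
        source = None
        if cfg.task == "both":
            # one detection model (first split) as the fine-tuning source
            det_splits = ev.make_detection_splits(records, cfg.test_fraction,
                                                  1, seed=cfg.seed)
            labels = {r.id: 1 if r.edema_label == "edema" else 0
                      for r in records}
            samples, _ = _build_samples(det_splits[0].train_ids, tensors,
                                        labels, cfg, seed=cfg.seed,
                                        augmented=cfg.augment_enabled)
            source = md.train(md.build_model(cfg.model), samples, cfg.model)
        results, pred_summary = run_prediction(pred_cohort, cfg, source)
        pred_summary["n_pairs"] = len(pred_cohort.pairs)
        pred_summary["exclusions"] = pred_cohort.exclusions
        summary["tasks"]["prediction"] = pred_summary
        all_results["prediction"] = results
    if out_dir is not None:
        run_dir = Path(out_dir) / f"run-{cfg.config_hash()}"
        run_dir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(str(run_dir / "config.yaml"))
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        rows = []
        for task, results in all_results.items():
            for r in results:
                for metric, value in r.metrics.items():
                    rows.append({"task": task,
                                 "replication": r.replication_index,
                                 "metric": metric, "value": value})
        pd.DataFrame(rows).to_csv(run_dir / "replications.csv", index=False)
        with open(run_dir / "log.jsonl", "a") as fh:
            fh.write(json.dumps({"event": "run_complete",
                                 "config_hash": cfg.config_hash()}) + "\n")
    return summary
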