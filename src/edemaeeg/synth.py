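"""Seeded synthetic post-arrest EEG cohorts.

The generator emulates the statistical structure the analysis assumes, not
physiologically faithful EEG: the *edema* class has a globally suppressed,
delta-dominant, burst-suppressed background; the *no-edema* class has a
continuous mixed-frequency background.  Backgrounds are sums of Gaussian
noise band-passed into the conventional delta/theta/alpha/beta bands, with
a slow random amplitude envelope and (for edema) a two-state semi-Markov
burst/suppression envelope shared across channels.  Cohort covariates are
drawn per class so edema patients are younger, less often witnessed, more
often out-of-hospital arrests, and reach EEG sooner.

A single global ``time_scale`` shortens every arrest-relative clock
(recording span, EEG start delays, recognition delays) for desk-scale runs
while leaving waveform morphology (band content, burst/suppression dwell
times) in real seconds, so every feature operates on physiological signals.

Determinism: the cohort seed streams into per-patient sub-seeds by stable
hashing of the patient id, so a patient's record does not depend on cohort
size or generation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import DOUBLE_BANANA, TEN_TWENTY_19, PatientRecord, RawEEG

__all__ = [
    "ClassParams",
    "ArtifactRates",
    "CovariateModel",
    "SynthConfig",
    "SynthPatient",
    "ArtifactInterval",
    "default_class_params",
    "generate_background",
    "generate_patient_eeg",
    "inject_artifacts",
    "generate_cohort",
    "iter_cohort_eeg",
    "patient_seed",
]

_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass(frozen=True)
class ClassParams:
    """Background-synthesis settings for one class.

    ``band_rms_uv`` sets each band component's RMS amplitude during bursts
    (or throughout, when the suppression fraction is 0).
    """

    band_rms_uv: Dict[str, float]
    suppression_fraction: float = 0.0
    # 1.5 uV RMS keeps the suppressed envelope reliably below the 5 uV
    # detection threshold despite delta-dominant peak factors
    suppression_rms_uv: float = 1.5
    burst_dwell_s: float = 2.0
    supp_dwell_s: float = 5.0
    envelope_mod_depth: float = 0.15
    channel_correlation: float = 0.6
    # between-patient heterogeneity: per-patient log-normal gain on each
    # band weight, and a per-patient multiplier on the suppression dwell
    band_gain_jitter_sd: float = 0.25
    dwell_jitter_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must be in [0, 1]")
        if any(w < 0 for w in self.band_rms_uv.values()):
            raise ValueError("band weights must be non-negative")


def default_class_params(truth_class: str, separation: float = 1.0) -> ClassParams:
    """Default per-class generator settings.

    ``separation`` in [0, 1] linearly interpolates the edema class toward
    the no-edema class; 0 makes the classes identical (null cohort).
    """
    none = ClassParams(
        band_rms_uv={"delta": 5.0, "theta": 6.0, "alpha": 8.0, "beta": 4.0},
        suppression_fraction=0.0, envelope_mod_depth=0.15)
    if truth_class == "none":
        return none
    if truth_class != "edema":
        raise ValueError(f"unknown class {truth_class!r}")
    # Delta-dominant bursts; non-delta burst weights are scaled up by
    # 1/sqrt(1 - suppression fraction) so their *time-averaged* power
    # matches the no-edema class — the class signal then lives in delta
    # power and the suppression structure (entropy, regularity, BSR),
    # mirroring the physiology the features target, instead of leaking
    # into every band through the duty cycle.
    f_supp = 0.6
    duty = math.sqrt(1.0 / (1.0 - f_supp))
    edema = ClassParams(
        band_rms_uv={"delta": 25.0, "theta": 6.0 * duty,
                     "alpha": 8.0 * duty, "beta": 4.0 * duty},
        suppression_fraction=f_supp, envelope_mod_depth=0.10)
    s = float(separation)
    if not 0.0 <= s <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    bands = {b: s * edema.band_rms_uv[b] + (1 - s) * none.band_rms_uv[b]
             for b in none.band_rms_uv}
    return replace(edema, band_rms_uv=bands,
                   suppression_fraction=s * edema.suppression_fraction,
                   envelope_mod_depth=s * edema.envelope_mod_depth
                   + (1 - s) * none.envelope_mod_depth)


@dataclass(frozen=True)
class ArtifactRates:
    """Injected artifact events per hour of recording, per kind."""

    transient_per_h: float = 0.0
    flatline_per_h: float = 0.0
    step_per_h: float = 0.0

    def __post_init__(self) -> None:
        if min(self.transient_per_h, self.flatline_per_h, self.step_per_h) < 0:
            raise ValueError("artifact rates must be non-negative")


@dataclass(frozen=True)
class CovariateModel:
    """Per-class covariate distributions (cohort-table structure)."""

    age_mean_none: float = 56.0
    age_sd: float = 13.0
    age_shift_edema: float = -8.0
    male_prop: float = 0.597
    witnessed_prop: Dict[str, float] = field(
        default_factory=lambda: {"edema": 0.415, "none": 0.661})
    ohca_prop: Dict[str, float] = field(
        default_factory=lambda: {"edema": 0.923, "none": 0.707})
    # log-normal EEG start delays; medians in hours post-arrest, truncated
    # so monitoring is always running before the 24-h analysis window opens
    eeg_delay_median_h: Dict[str, float] = field(
        default_factory=lambda: {"edema": 17.8, "none": 22.1})
    eeg_delay_sigma: float = 0.45
    eeg_delay_range_h: Tuple[float, float] = (4.0, 22.0)
    # recognition delay: exponential, truncated
    recognition_mean_h: float = 20.3
    recognition_range_h: Tuple[float, float] = (1.0, 240.0)
    pre_recognition_fraction: float = 0.6


@dataclass
class SynthConfig:
    """Full description of one synthetic cohort."""

    n_patients: int = 124
    edema_prevalence: float = 0.524
    sample_rate: float = 100.0
    record_hours: float = 30.0  # recording duration from EEG start, pre-scale
    class_params: Dict[str, ClassParams] = field(
        default_factory=lambda: {"edema": default_class_params("edema"),
                                 "none": default_class_params("none")})
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    montage: str = "referential"  # "referential" (19 ch) or "bipolar" (18)
    time_scale: float = 1.0
    seed: int = 0

    def validate(self, segment_hours: float = 4.0) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.edema_prevalence <= 1.0:
            raise ValueError("edema_prevalence must be in [0, 1]")
        if self.sample_rate <= 2 * 30.0:
            raise ValueError("sample_rate must exceed twice the beta band edge")
        if self.record_hours < segment_hours + 24.0:
            raise ValueError("record_hours must cover the analysis segment "
                             "(segment length + 24 h)")
        if self.montage not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage mode {self.montage!r}")
        if not 0.0 < self.time_scale <= 1.0:
            raise ValueError("time_scale must be in (0, 1]")


@dataclass(frozen=True)
class ArtifactInterval:
    """Ground-truth location of an injected artifact."""

    channel: int
    kind: str  # "transient" / "flatline" / "step"
    start_s: float
    end_s: float


@dataclass
class SynthPatient:
    """One simulated patient: covariates, truth class, and recording."""

    record: PatientRecord
    truth_class: str
    eeg: Optional[RawEEG] = None
    artifact_truth: List[ArtifactInterval] = field(default_factory=list)


def patient_seed(seed: int, patient_id: str) -> int:
    """Stable per-patient sub-seed (independent of cohort size/order)."""
    return zlib.crc32(f"{seed}:{patient_id}".encode()) & 0x7FFFFFFF


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band_rms: Dict[str, float]) -> np.ndarray:
    """Gaussian noise band-limited into the named bands, by exact
    frequency-domain shaping (one inverse FFT).

    Each band component's expected RMS equals its configured weight: with
    ``m`` bins in a band, bin amplitudes are complex Gaussian with
    ``E|X_k|^2 = (rms * n)^2 / (2 m)``, giving time-domain variance
    ``2 m E|X_k|^2 / n^2 = rms^2``.
    """
    spec = np.zeros(n // 2 + 1, dtype=complex)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    for band, (lo, hi) in _BAND_EDGES.items():
        rms = band_rms.get(band, 0.0)
        if rms == 0.0:
            continue
        sel = (freqs >= lo) & (freqs <= min(hi, 0.499 * fs))
        m = int(sel.sum())
        if m == 0:
            continue
        sigma = rms * n / math.sqrt(2.0 * m)
        spec[sel] += sigma * (rng.standard_normal(m)
                              + 1j * rng.standard_normal(m)) / math.sqrt(2.0)
    return np.fft.irfft(spec, n)


def _slow_envelope(rng: np.random.Generator, n: int, fs: float,
                   depth: float) -> np.ndarray:
    if depth == 0.0:
        return np.ones(n)
    # random walk low-passed at ~0.05 Hz, clipped to keep amplitude physical
    coarse = rng.standard_normal(max(int(n / fs * 0.1), 2))
    env = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, coarse.size), coarse)
    env = 1.0 + depth * env
    return np.clip(env, 0.5, 1.5)


def _burst_state(rng: np.random.Generator, n: int, fs: float,
                 params: ClassParams) -> np.ndarray:
    """Two-state semi-Markov burst(1)/suppression(0) indicator.

    Mean dwell times are adjusted so the long-run suppression fraction
    equals the configured value while keeping the suppression dwell scale.
    """
    f = params.suppression_fraction
    if f <= 0.0:
        return np.ones(n)
    if f >= 1.0:
        return np.zeros(n)
    supp_dwell = params.supp_dwell_s
    burst_dwell = supp_dwell * (1.0 - f) / f
    state = np.empty(n)
    pos = 0
    cur = 1 if rng.random() > f else 0
    while pos < n:
        mean = burst_dwell if cur == 1 else supp_dwell
        dwell = max(int(round(rng.exponential(mean) * fs)), 1)
        state[pos:pos + dwell] = cur
        pos += dwell
        cur = 1 - cur
    return state


def _smooth_state(state: np.ndarray, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    w = max(int(round(ramp_s * fs)), 1)
    kernel = np.ones(w) / w
    return np.convolve(state, kernel, mode="same")


def _background(rng: np.random.Generator, params: ClassParams, n: int,
                fs: float, state: Optional[np.ndarray] = None,
                slow_env: Optional[np.ndarray] = None) -> np.ndarray:
    base = _band_noise(rng, n, fs, params.band_rms_uv)
    total_rms = float(np.sqrt(sum(w * w for w in params.band_rms_uv.values())))
    if slow_env is None:
        slow_env = _slow_envelope(rng, n, fs, params.envelope_mod_depth)
    if state is None:
        state = _burst_state(rng, n, fs, params)
    if np.any(state < 1):
        # fixed-amplitude suppression floor; slow modulation only in bursts
        supp_gain = (params.suppression_rms_uv / total_rms
                     if total_rms > 0 else 0.0)
        smooth = _smooth_state(state, fs)
        return base * (supp_gain + (1.0 - supp_gain) * smooth * slow_env)
    return base * slow_env


def generate_background(class_params: ClassParams, duration_s: float,
                        sample_rate: float, seed: int) -> np.ndarray:
    """Single-channel class background of ``duration_s`` seconds, in uV."""
    if duration_s <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    return _background(rng, class_params, n, sample_rate)


def generate_patient_eeg(truth_class: str, config: SynthConfig, seed: int,
                         t0_hours: float = 0.0) -> RawEEG:
    """Multichannel recording for one patient.

    Channels share the class process (burst/suppression state and slow
    envelope, plus a common background component at the configured
    channel correlation) with independent per-channel band noise on top.
    """
    if truth_class not in config.class_params:
        raise ValueError(f"unknown class {truth_class!r}")
    params = config.class_params[truth_class]
    fs = config.sample_rate
    n = int(round(config.record_hours * config.time_scale * 3600.0 * fs))
    rng = np.random.default_rng(seed)
    # patient-level heterogeneity: band gains and burst/suppression tempo
    if params.band_gain_jitter_sd > 0:
        bands = {b: w * float(np.exp(rng.normal(0, params.band_gain_jitter_sd)))
                 for b, w in params.band_rms_uv.items()}
        params = replace(params, band_rms_uv=bands)
    if params.dwell_jitter_sd > 0 and 0 < params.suppression_fraction < 1:
        mult = float(np.exp(rng.normal(0, params.dwell_jitter_sd)))
        params = replace(params, supp_dwell_s=params.supp_dwell_s * mult,
                         burst_dwell_s=params.burst_dwell_s * mult)
    state = _burst_state(rng, n, fs, params)
    slow = _slow_envelope(rng, n, fs, params.envelope_mod_depth)
    rho = params.channel_correlation
    if config.montage == "bipolar":
        labels = tuple(f"{a}-{b}" for a, b in DOUBLE_BANANA)
    else:
        labels = TEN_TWENTY_19
    n_ch = len(labels)
    # one shared + n_ch independent flat backgrounds
    shared = _band_noise(rng, n, fs, params.band_rms_uv)
    data = np.empty((n_ch, n))
    mix = math.sqrt(max(1.0 - rho * rho, 0.0))
    for c in range(n_ch):
        data[c] = rho * shared + mix * _band_noise(rng, n, fs,
                                                   params.band_rms_uv)
    total_rms = float(np.sqrt(sum(w * w for w in params.band_rms_uv.values())))
    if np.any(state < 1):
        supp_gain = (params.suppression_rms_uv / total_rms if total_rms > 0 else 0.0)
        env = supp_gain + (1.0 - supp_gain) * _smooth_state(state, fs) * slow
    else:
        env = slow
    data *= env
    return RawEEG(labels, fs, data, t0_hours)


def inject_artifacts(eeg: RawEEG, rates: ArtifactRates, seed: int,
                     transient_amp_uv: float = 600.0,
                     step_amp_uv: float = 250.0
                     ) -> Tuple[RawEEG, List[ArtifactInterval]]:
    """Insert the three artifact kinds and return their true intervals.

    Kinds: high-amplitude raised-cosine transients (0.3 s), near-zero
    flatline runs (20-40 s, so every run fully blankets at least one 10-s
    artifact-detection window regardless of alignment), and step
    discontinuities (one-sample jumps
    of ``step_amp_uv``, held 2-5 s).  Counts are Poisson with the configured
    per-hour rates over the whole record; each event lands on one random
    channel; intervals never overlap within a channel.
    """
    out = eeg.copy()
    fs = eeg.sample_rate
    hours = eeg.duration_s / 3600.0
    rng = np.random.default_rng(seed)
    intervals: List[ArtifactInterval] = []

    def _free(ch: int, s0: float, s1: float) -> bool:
        for iv in intervals:
            if iv.channel == ch and s0 < iv.end_s and iv.start_s < s1:
                return False
        return True

    def _place(kind: str, dur_s: float) -> Optional[ArtifactInterval]:
        for _ in range(50):
            ch = int(rng.integers(eeg.n_channels))
            start = float(rng.uniform(0, max(eeg.duration_s - dur_s, 0)))
            if _free(ch, start, start + dur_s):
                iv = ArtifactInterval(ch, kind, start, start + dur_s)
                intervals.append(iv)
                return iv
        return None

    for _ in range(rng.poisson(rates.transient_per_h * hours)):
        iv = _place("transient", 0.3)
        if iv is None:
            continue
        i0, i1 = int(iv.start_s * fs), int(iv.end_s * fs)
        t = np.linspace(0, np.pi, max(i1 - i0, 2))
        out.data[iv.channel, i0:i1] += transient_amp_uv * np.sin(t) ** 2
    for _ in range(rng.poisson(rates.flatline_per_h * hours)):
        iv = _place("flatline", float(rng.uniform(20.0, 40.0)))
        if iv is None:
            continue
        i0, i1 = int(iv.start_s * fs), int(iv.end_s * fs)
        out.data[iv.channel, i0:i1] = 0.01 * rng.standard_normal(i1 - i0)
    for _ in range(rng.poisson(rates.step_per_h * hours)):
        iv = _place("step", float(rng.uniform(2.0, 5.0)))
        if iv is None:
            continue
        i0, i1 = int(iv.start_s * fs), int(iv.end_s * fs)
        out.data[iv.channel, i0:i1] += step_amp_uv
    return out, intervals


def _draw_record(rng: np.random.Generator, pid: str, truth_class: str,
                 config: SynthConfig) -> PatientRecord:
    cov = config.covariates
    ts = config.time_scale
    age_mean = cov.age_mean_none + (cov.age_shift_edema
                                    if truth_class == "edema" else 0.0)
    age = float(np.clip(rng.normal(age_mean, cov.age_sd), 18.0, 95.0))
    sex = "M" if rng.random() < cov.male_prop else "F"
    witnessed = bool(rng.random() < cov.witnessed_prop[truth_class])
    ohca = bool(rng.random() < cov.ohca_prop[truth_class])
    lo_d, hi_d = cov.eeg_delay_range_h
    t_eeg = float(np.clip(
        np.exp(rng.normal(np.log(cov.eeg_delay_median_h[truth_class]),
                          cov.eeg_delay_sigma)), lo_d, hi_d)) * ts
    t_edema = None
    if truth_class == "edema":
        lo, hi = cov.recognition_range_h
        rec_end = t_eeg + config.record_hours * ts
        # the eligibility boundary downstream is strictly > 1 h of EEG
        # before recognition, scaled with the cohort clock
        elig_lo = t_eeg + 1.05 * ts
        if rng.random() < cov.pre_recognition_fraction and elig_lo < rec_end:
            t_edema = float(rng.uniform(elig_lo, min(rec_end, hi * ts)))
        else:
            t_edema = float(rng.uniform(lo * ts, min(t_eeg + 0.95 * ts, hi * ts)))
        t_edema = float(np.clip(t_edema, lo * ts, hi * ts))
    return PatientRecord(id=pid, age=age, sex=sex, witnessed=witnessed,
                         ohca=ohca, edema_label=truth_class,
                         t_eeg_start=t_eeg, t_edema=t_edema)


def generate_cohort(config: SynthConfig, with_eeg: bool = True,
                    validate: bool = True) -> List[SynthPatient]:
    """Draw the full cohort; class counts are the rounded prevalence split."""
    if validate:
        config.validate()
    elif config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    n_edema = int(round(config.n_patients * config.edema_prevalence))
    classes = ["edema"] * n_edema + ["none"] * (config.n_patients - n_edema)
    patients: List[SynthPatient] = []
    width = max(len(str(config.n_patients)), 3)
    for i, cls in enumerate(classes):
        pid = f"P{i + 1:0{width}d}"
        sub = patient_seed(config.seed, pid)
        rng = np.random.default_rng(sub)
        record = _draw_record(rng, pid, cls, config)
        patient = SynthPatient(record=record, truth_class=cls)
        if with_eeg:
            patient.eeg, patient.artifact_truth = _patient_eeg_with_artifacts(
                cls, config, sub, record.t_eeg_start)
        patients.append(patient)
    return patients


def _patient_eeg_with_artifacts(cls: str, config: SynthConfig, sub_seed: int,
                                t0: float) -> Tuple[RawEEG, List[ArtifactInterval]]:
    eeg = generate_patient_eeg(cls, config, seed=sub_seed + 1, t0_hours=t0)
    rates = config.artifact_rates
    if rates.transient_per_h or rates.flatline_per_h or rates.step_per_h:
        return inject_artifacts(eeg, rates, seed=sub_seed + 2)
    return eeg, []


def iter_cohort_eeg(config: SynthConfig, patients: Sequence[SynthPatient]
                    ) -> Iterator[Tuple[SynthPatient, RawEEG, List[ArtifactInterval]]]:
    """Stream recordings one patient at a time (memory-bounded pipelines)."""
    for p in patients:
        if p.eeg is not None:
            yield p, p.eeg, p.artifact_truth
        else:
            sub = patient_seed(config.seed, p.record.id)
            eeg, truth = _patient_eeg_with_artifacts(
                p.truth_class, config, sub, p.record.t_eeg_start)
            yield p, eeg, truth
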