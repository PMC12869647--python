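"""Shared fixtures: scaled study conditions and (expensive) end-to-end runs.

The scaled conditions shrink every arrest-relative clock by 20x (epochs of
15 s instead of 300 s, a 0.2-h segment standing for the 4-h one) and lower
the sampling rate to 64 Hz, while waveform morphology stays in real
seconds.  The expensive separable/null cohort runs are session-scoped so
the end-to-end and attribution checks share one computation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from edemaeeg import models as md
from edemaeeg import pipeline as pl
from edemaeeg import synth as sy

#: scaled study conditions used by all end-to-end tests
TIME_SCALE = 0.05
SAMPLE_RATE = 64.0
BAND_HIGH = 31.0


def scaled_run_config(**overrides) -> pl.RunConfig:
    base = dict(time_scale=TIME_SCALE, band_high_hz=BAND_HIGH,
                target_rate_hz=SAMPLE_RATE, n_replications=10,
                model=md.ModelConfig(n_iterations=30, seed=1), seed=5)
    base.update(overrides)
    return pl.RunConfig(**base)


def scaled_synth_config(**overrides) -> sy.SynthConfig:
    base = dict(n_patients=124, sample_rate=SAMPLE_RATE,
                time_scale=TIME_SCALE, seed=42)
    base.update(overrides)
    return sy.SynthConfig(**base)


@pytest.fixture(scope="session")
def separable_cohort():
    """124-patient cohort with wide class separation, features extracted."""
    cfg = scaled_run_config()
    synth_cfg = scaled_synth_config()
    records, tensors = pl.prepare_detection_cohort(synth_cfg, cfg)
    return {"records": records, "tensors": tensors, "cfg": cfg,
            "synth_cfg": synth_cfg}


@pytest.fixture(scope="session")
def separable_detection_runs(separable_cohort):
    """Transformer detection with and without augmentation, with attribution."""
    cfg = separable_cohort["cfg"]
    res_aug, sum_aug = pl.run_detection(
        separable_cohort["records"], separable_cohort["tensors"], cfg,
        augmented=True, with_attribution=True)
    res_no, sum_no = pl.run_detection(
        separable_cohort["records"], separable_cohort["tensors"], cfg,
        augmented=False)
    return {"aug": (res_aug, sum_aug), "noaug": (res_no, sum_no)}


@pytest.fixture(scope="session")
def null_detection_run():
    """Same conditions with class separation set to zero."""
    cfg = scaled_run_config()
    null_params = {"edema": sy.default_class_params("edema", separation=0.0),
                   "none": sy.default_class_params("none")}
    synth_cfg = scaled_synth_config(class_params=null_params, seed=43)
    records, tensors = pl.prepare_detection_cohort(synth_cfg, cfg)
    return pl.run_detection(records, tensors, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
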