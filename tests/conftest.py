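import numpy as np
import pytest

from ckd_cea.meta import EffectEstimate, TrialRecord
from ckd_cea.microsim import CohortSpec
from ckd_cea.egfr import invert_mdrd


@pytest.fixture
def two_effects():
    """The hand-computable two-study instance: effects 0 and 2, both se 1."""
    return [EffectEstimate(md=0.0, se=1.0), EffectEstimate(md=2.0, se=1.0)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(study_id="t", n=100, mean_trt=-20.0, mean_ctl=0.0,
               sd=10.0, **cov):
    return TrialRecord(
        study_id=study_id, n_trt=n, mean_trt=mean_trt, sd_trt=sd,
        n_ctl=n, mean_ctl=mean_ctl, sd_ctl=sd, covariates=cov,
    )


@pytest.fixture
def degenerate_cohort_spec():
    """Zero-variance cohort: every patient male, 60y, eGFR exactly 35
    (stage 3) / 20 (stage 4), declining 1.7 per year."""
    return CohortSpec(
        n_patients=50,
        male_prop=1.0,
        age={"family": "constant", "value": 60.0},
        scr_stage3={"family": "constant", "value": invert_mdrd(35.0, 60.0, False)},
        scr_stage4={"family": "constant", "value": invert_mdrd(20.0, 60.0, False)},
        gfr_decline={"family": "constant", "value": 1.7},
        seed=0,
    )
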