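import numpy as np
import pytest

from cvdmicrosim import default_parameters
from cvdmicrosim.population import Cohort


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def econ(params):
    return params.economics


def make_cohort(n, age=45.0, ses=3, smoking=0, diabetes=False,
                sbp=120.0, tc=5.0, hdl=1.5, ids=None):
    """Hand-built homogeneous cohort for engine tests."""
    return Cohort(
        id=np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids, np.int64),
        age=np.full(n, age, dtype=float),
        ses_quintile=np.full(n, ses, dtype=np.int8),
        smoking=np.full(n, smoking, dtype=np.int8),
        diabetes=np.full(n, diabetes, dtype=bool),
        sbp=np.full(n, sbp, dtype=float),
        tc=np.full(n, tc, dtype=float),
        hdl=np.full(n, hdl, dtype=float),
    )


def no_cvd_params(params, mortality_p=0.0):
    """No CVD risk (baseline survival 1) and flat non-CVD mortality."""
    return params.mutated(**{
        "risk_first_ever.baseline_survival": 1.0,
        "risk_recurrent.baseline_survival": 1.0,
        "mortality.rows": [{"age": 30, "p": float(mortality_p)}],
    })


def zero_drift_params(params):
    return params.mutated(**{
        "population.sbp_annual_increment_by_age": [{"lo": 30, "hi": 120, "d": 0.0}],
        "population.tc_annual_increment_by_age": [{"lo": 30, "hi": 120, "d": 0.0}],
        "population.hdl_annual_increment_by_age": [{"lo": 30, "hi": 120, "d": 0.0}],
    })
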