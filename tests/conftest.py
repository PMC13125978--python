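import numpy as np
import pandas as pd
import pytest

from prognostack import Cohort, PatientRecord, default_config, generate_cohort, load_params


def make_record(i, **kw):
    base = dict(id=f"p{i}", age=60.0, time_years=6.0, event="censored",
                nodes=0, laterality="left", er_positive=True, pr_positive=True,
                size_mm=15.0, grade=1, radiotherapy=False, chemotherapy=False,
                trastuzumab=False)
    base.update(kw)
    return PatientRecord(**base)


def make_cohort(n=10, n_events=2, **kw):
    recs = [make_record(i, event="bc_death" if i < n_events else "censored",
                        time_years=2.0 if i < n_events else 6.0, **kw)
            for i in range(n)]
    return Cohort.from_records(recs)


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture(scope="session")
def ma27_small():
    """A moderately sized default synthetic cohort shared across tests."""
    return generate_cohort(default_config("ma27_like", n=2000, seed=101))


@pytest.fixture(scope="session")
def ma27_complete():
    """Default cohort with missingness switched off (complete records)."""
    cfg = default_config("ma27_like", n=2000, seed=102)
    cfg.missingness = {}
    return generate_cohort(cfg)


@pytest.fixture
def uncensored_calibrated():
    """Outcomes drawn exactly from known per-record 5-year probabilities,
    with follow-up long enough that no record is censored before year 5."""
    rng = np.random.default_rng(7)
    n = 5000
    p = rng.beta(1.3, 30, n)
    lam = -np.log(1.0 - p) / 5.0
    T = rng.exponential(1.0 / np.maximum(lam, 1e-12))
    time = np.minimum(T, 30.0)
    event = np.where(T <= 30.0, "bc_death", "censored")
    return p, time, event
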