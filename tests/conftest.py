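import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import abcrasch as abc
from abcrasch.data_io import ResponseMatrix

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_rm(values, person_ids=None, item_ids=None, covariates=None) -> ResponseMatrix:
    """Build a ResponseMatrix from a plain nested list (None = missing)."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in values]
    )
    n, L = arr.shape
    pids = person_ids or [f"p{i + 1}" for i in range(n)]
    iids = item_ids or [f"i{j + 1}" for j in range(L)]
    X = pd.DataFrame(arr, index=pd.Index(pids, name="person_id"), columns=iids)
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=X.index)
    return ResponseMatrix(X=X, covariates=cov)


def simulate_rasch(n_persons, difficulties, seed, **kwargs):
    """Plain unit-discrimination simulation, screened and ready to calibrate."""
    difficulties = np.asarray(difficulties, dtype=float)
    cfg = abc.SimConfig(
        n_persons=n_persons,
        item_difficulties=difficulties,
        item_discriminations=np.ones(len(difficulties)),
        seed=seed,
        **kwargs,
    )
    data, truth = abc.simulate(cfg)
    screened, _, _ = abc.screen_extremes(data)
    return screened, truth


@pytest.fixture(scope="session")
def abc_instrument():
    return abc.packaged_abc()


@pytest.fixture(scope="session")
def calibrated_medium():
    """One shared 500-person, 20-item model-true calibration."""
    screened, truth = simulate_rasch(500, np.linspace(-2, 2, 20), seed=42)
    fit = abc.estimate_jml(screened)
    return screened, truth, fit
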