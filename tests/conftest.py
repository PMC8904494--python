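import numpy as np
import pandas as pd
import pytest

from exposcan import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_participants=400, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def toy_visits():
    """Ten participants, two visits each, with hand-set flags and traits."""
    rows = []
    for j in range(10):
        for v in (1, 2):
            rows.append(
                {
                    "pid": f"P{j}",
                    "visit": v,
                    "age": 40 + 10 * (v - 1),
                    "sex": j % 2,
                    "education": 2,
                    "fasting_status": 1,
                    "ffq_version": 0,
                    "diabetes": int(j in (0, 1) and v == 2),
                    "cvd": 0,
                    "non_reference_origin": 0,
                    "lipid_med": 0,
                    "bp_med": 0,
                    "triglycerides": 1.0,
                    "total_cholesterol": 5.0,
                    "hdl": 1.0,
                    "ldl": 3.0,
                    "sbp": 120.0,
                    "dbp": 80.0,
                }
            )
    return pd.DataFrame(rows)


def ols_slope(y, X):
    """Plain least-squares coefficients and classical SEs (test oracle)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    return beta, se
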