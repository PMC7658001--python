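import numpy as np
import pytest

from ewasnet import ModuleBlock, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort small enough for per-test reuse: 120 samples,
    300 probes, 30 causal with one 20-probe coregulated block."""
    config = SimulationConfig(
        n_samples=120,
        n_probes=300,
        n_causal=30,
        module_blocks=(ModuleBlock(20, 0.9),),
        smoking_comorbid=False,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def medium_cohort():
    """n=300 cohort used by network / mediation / endophenotype tests."""
    config = SimulationConfig(
        n_samples=300,
        n_probes=800,
        n_causal=96,
        smoking_comorbid=False,
        seed=5,
    )
    return generate_cohort(config)


# --- closed-form OLS oracle shared by several test modules ---------------


def ols_oracle(x: np.ndarray, y: np.ndarray):
    """Classical OLS by explicit matrix algebra: coefficients, SEs, t, and
    two-sided p from the t distribution.  Independent of the implementation
    path (statsmodels)."""
    from scipy import stats

    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, pvals, df
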