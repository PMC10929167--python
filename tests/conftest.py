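import numpy as np
import pandas as pd
import pytest

from mrscreen.estimators import EstimatorConfig
from mrscreen.summary_data import HarmonizedSet


def make_harmonized(beta_exp, se_exp, beta_out, se_out,
                    exposure="exposure", outcome="outcome", snps=None):
    beta_exp = np.asarray(beta_exp, dtype=float)
    if snps is None:
        snps = np.array([f"rs{i}" for i in range(len(beta_exp))], dtype=object)
    audit = pd.DataFrame({"snp": snps, "disposition": "kept", "note": ""})
    return HarmonizedSet(exposure, outcome, snps, beta_exp, se_exp,
                         beta_out, se_out, audit)


def random_harmonized(rng, J=10, theta=0.5):
    """Small random instance with strong instruments (|gamma| >= 6 se)."""
    sx = rng.uniform(0.005, 0.02, J)
    sy = rng.uniform(0.02, 0.1, J)
    sign = rng.choice([-1.0, 1.0], J)
    gamma = sign * sx * rng.uniform(6.0, 12.0, J)
    bx = rng.normal(gamma, sx)
    by = rng.normal(theta * gamma, sy)
    bx = np.where(bx == 0, 1e-6, bx)
    return make_harmonized(bx, sx, by, sy)


@pytest.fixture
def fast_cfg():
    """Deterministic estimator config with the minimum allowed bootstrap."""
    return EstimatorConfig(ivw_mode="fixed", n_boot=100, seed=7)


@pytest.fixture
def three_snp_set():
    """The hand-checked 3-instrument worked example."""
    return make_harmonized(
        [0.1, 0.2, 0.15], [0.01, 0.01, 0.01],
        [0.05, 0.11, 0.06], [0.05, 0.05, 0.1],
    )
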