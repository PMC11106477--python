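import numpy as np
import pytest

from bloodmr import SyntheticGwasConfig, generate_summary_stats, harmonize


def single_cause_theta(k: int, index: int, value: float) -> np.ndarray:
    theta = np.zeros(k)
    theta[index] = value
    return theta


@pytest.fixture(scope="session")
def small_hset():
    """A deterministic 8-exposure harmonized instrument set with one causal
    exposure (index 0, effect 0.4) used across estimator tests."""
    cfg = SyntheticGwasConfig(
        n_snps=200, n_exposures=8,
        causal_effects=single_cause_theta(8, 0, 0.4),
        missing_frac=0.0, pleiotropy_frac=0.0, seed=11,
    )
    panels, outcome = generate_summary_stats(cfg)
    return harmonize(panels, outcome)


@pytest.fixture(scope="session")
def noiseless_hset():
    """Noiseless, pleiotropy-free single-exposure set: every Wald ratio is
    exactly the causal effect 0.4."""
    cfg = SyntheticGwasConfig(
        n_snps=60, n_exposures=1, sparsity=1.0,
        causal_effects=np.array([0.4]),
        noise_scale=0.0, pleiotropy_frac=0.0, missing_frac=0.0,
        seed=3,
    )
    panels, outcome = generate_summary_stats(cfg)
    return harmonize(panels, outcome)
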