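import numpy as np
import pytest

from natalmeth import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A small but fully structured cohort with one injected effect of each
    kind, shared by read-only tests."""
    cfg = SimConfig(
        n_samples=200,
        n_variants=80,
        n_cpgs=300,
        seed=11,
        mqtl_effects=[(10, 20, 0.05)],
        prs_effect_sites=[(5, -0.0014)],
        smoking_effect_sites=[(30, 0.02)],
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def probe_map(small_bundle):
    return [(int(i), v) for i, v in small_bundle.truth["snp_probe_map"]]


def correlated_pair(x: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """A vector with exact sample correlation rho with x (Gram-Schmidt)."""
    e = rng.standard_normal(len(x))
    xs = (x - x.mean()) / x.std()
    e = e - e.mean()
    e = e - (e @ xs) / (xs @ xs) * xs
    e = e / e.std()
    return rho * xs + np.sqrt(1 - rho**2) * e
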