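import numpy as np
import pytest

from twinmeth.simulate import SimulationConfig, simulate_twin_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100 MZ / 80 DZ pairs, 30 sites, moderate heritability."""
    cfg = SimulationConfig(n_mz=100, n_dz=80, n_sites=30,
                           a_true=0.4, c_true=0.2, e_true=0.4,
                           mu_beta=0.5, total_sd=0.05, seed=42)
    return simulate_twin_cohort(cfg)


@pytest.fixture(scope="session")
def big_pair_cohort():
    """2000 pairs per zygosity, few sites: for moment-convergence checks."""
    cfg = SimulationConfig(n_mz=2000, n_dz=2000, n_sites=6,
                           a_true=0.6, c_true=0.2, e_true=0.2,
                           mu_beta=0.5, total_sd=0.05, seed=7)
    return simulate_twin_cohort(cfg)


def moment_matched_pairs(n, rho, rng, mu=0.0, sd=1.0):
    """Pairs whose MLE (divisor n) sample moments are exactly
    (mu, sd^2, rho): used to make likelihood routes comparable."""
    z = rng.standard_normal((n, 2))
    z = z - z.mean(axis=0)
    cov = z.T @ z / n
    w = z @ np.linalg.inv(np.linalg.cholesky(cov)).T
    target = np.array([[1.0, rho], [rho, 1.0]])
    y = w @ np.linalg.cholesky(target).T
    return mu + sd * y
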