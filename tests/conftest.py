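import numpy as np
import pytest

from mriq.phantoms import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """A compact cohort: 3 databases x 4 subjects, 24x12x12 grids."""
    return PhantomConfig(
        n_databases=3,
        subjects_per_database=4,
        grid_shape=(24, 12, 12),
        structure_size=5,
        seed=7,
    )


@pytest.fixture
def fixed_age_config():
    """Noise-only phantom: one age, no slopes, no database spread."""
    return PhantomConfig(
        n_databases=2,
        subjects_per_database=3,
        grid_shape=(24, 12, 12),
        structure_size=5,
        age_range_years=(50.0, 50.0),
        age_slope_mean=0.0,
        age_slope_noise=0.0,
        database_intercept_sd=0.0,
        seed=13,
    )


def two_pass_mean_sd(values):
    """Independent brute-force mean / sample-SD oracle."""
    values = list(float(v) for v in values)
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    return mean, (ss / (n - 1)) ** 0.5


def jzs_bf10_bruteforce(t, n_eff, df, r=2**0.5 / 2, n_grid=400_001):
    """Fine-grid trapezoid integration of the JZS g-mixture on a log grid.

    Deliberately independent of the package's adaptive quadrature:
    integrates exp(h(g)) * g over x = log g on a wide fixed grid.
    """
    x = np.linspace(-20.0, 20.0, n_grid)
    g = np.exp(x)
    nu = float(df)
    t2 = float(t) ** 2
    log_prior = np.log(r) - 0.5 * np.log(2 * np.pi) - 1.5 * np.log(g) - r * r / (2 * g)
    log_lik = -0.5 * np.log1p(n_eff * g) - 0.5 * (nu + 1) * np.log1p(t2 / ((1 + n_eff * g) * nu))
    log_null = -0.5 * (nu + 1) * np.log1p(t2 / nu)
    integrand = np.exp(log_lik - log_null + log_prior + x)  # * g from the log substitution
    return float(np.trapezoid(integrand, x))
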