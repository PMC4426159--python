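import numpy as np
import pytest

from concindex.core_index import (
    AggregatedRegisterTable,
    SEGProfile,
    StandardPopulation,
    midpoint_ranks,
)
from concindex.synthetic_register import (
    default_standard_population,
    generate_table,
    preset_config,
)


def make_table(deaths, person_years, ages=None, segs=None):
    deaths = np.atleast_2d(np.asarray(deaths))
    person_years = np.atleast_2d(np.asarray(person_years))
    I, G = deaths.shape
    ages = tuple(ages) if ages is not None else tuple(f"age_{i}" for i in range(I))
    segs = tuple(segs) if segs is not None else tuple(f"seg_{g}" for g in range(G))
    return AggregatedRegisterTable(ages, segs, deaths, person_years)


def uniform_stdpop(n_ages):
    return StandardPopulation(
        tuple(f"age_{i}" for i in range(n_ages)), np.ones(n_ages)
    )


def profile_from_rates(y, f=None, p=None, n=None):
    """Build a SEGProfile directly from group rates (single implied age band)."""
    y = np.asarray(y, dtype=float)
    G = len(y)
    f = np.full(G, 1.0 / G) if f is None else np.asarray(f, float)
    f = f / f.sum()
    p = f * 1e6 if p is None else np.asarray(p, float)
    n = np.maximum(np.round(y * p / 1e5), 1) if n is None else np.asarray(n)
    R = midpoint_ranks(f)
    return SEGProfile(
        seg_groups=tuple(f"seg_{g}" for g in range(G)),
        f=f,
        R=R,
        y=y,
        n=n,
        p=p,
        y_mean=float(f @ y),
        sigma2_R=float(f @ (R - 0.5) ** 2),
    )


@pytest.fixture(scope="session")
def stdpop_default():
    return default_standard_population()


@pytest.fixture(scope="session")
def preset_synthetic():
    """One register-scale synthetic table from the calibrated preset."""
    cfg = preset_config("finland-1996-men")
    return generate_table(cfg, np.random.default_rng(20250901))
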