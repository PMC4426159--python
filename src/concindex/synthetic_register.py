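"""Synthetic aggregated register tables with a known inequality structure.

Generates count tables shaped like an annual national mortality register
aggregated by income vigintile: equal person-year shares across G groups
(default 20), age bands from 1-4 up to 70-74, and Poisson death counts with
a log-linear rate gradient across the socioeconomic ranks,

    rate_ig = baseline_i * exp(gradient * R_g),

so that the true expected-rate concentration index is known in closed form
from the group rate multipliers.  A negative gradient concentrates the
outcome among the disadvantaged groups and yields a negative index.

``preset_config("finland-1996-men")`` calibrates the gradient, the overall
level and the age-pyramid tilt by numerical search so that the generated
table matches register-scale targets: a true index of about -0.27, an
overall age-standardized rate of about 102 per 100,000 person-years, and
roughly 2,100 expected deaths in about 2.4 million person-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.optimize import brentq

from .core_index import (
    AggregatedRegisterTable,
    StandardPopulation,
    ValidationError,
    midpoint_ranks,
)
from .interval_montecarlo import MultiYearRates

__all__ = [
    "SyntheticConfig",
    "SyntheticTable",
    "DEFAULT_AGE_BANDS",
    "default_standard_population",
    "default_age_pyramid",
    "default_baseline_shape",
    "true_concentration_index",
    "generate_table",
    "generate_panel",
    "random_table",
    "preset_config",
    "PRESETS",
]

# ages 1-4, then five-year bands through 70-74
DEFAULT_AGE_BANDS: tuple[str, ...] = ("1-4",) + tuple(
    f"{a}-{a + 4}" for a in range(5, 71, 5)
)

_AGE_MIDPOINTS = np.array(
    [2.5] + [a + 2.0 for a in range(5, 71, 5)], dtype=float
)


def default_standard_population() -> StandardPopulation:
    """The packaged illustrative European-style weight vector.

    An approximation in the spirit of the classic European standard
    population, restricted to ages 1-74; it is a placeholder, not an
    official vector, and is normalized to sum to 100,000 on load.
    """
    text = (
        resources.files("concindex")
        .joinpath("data", "standard_population_european.csv")
        .read_text()
    )
    labels, weights = [], []
    for line in text.strip().splitlines()[1:]:
        label, weight = line.split(",")
        labels.append(label)
        weights.append(float(weight))
    return StandardPopulation(tuple(labels), np.array(weights))


def default_age_pyramid(tilt: float = 0.0) -> np.ndarray:
    """Population shares per age band; ``tilt`` > 0 skews the pyramid young.

    The base vector is a smooth mid-1990s-style Northern European profile
    for ages 1-74.  ``tilt`` multiplies shares by ``exp(-tilt * age)`` and
    renormalizes, giving the calibration one knob for the crude-vs-
    standardized rate ratio.
    """
    base = np.array(
        [0.055, 0.068, 0.066, 0.063, 0.062, 0.065, 0.070, 0.075,
         0.078, 0.085, 0.070, 0.060, 0.055, 0.050, 0.045]
    )
    shares = base * np.exp(-tilt * _AGE_MIDPOINTS)
    return shares / shares.sum()


def default_baseline_shape(slope: float = 0.085) -> np.ndarray:
    """Relative mortality hazard by age band (exponential rise with age)."""
    return np.exp(slope * _AGE_MIDPOINTS)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; array fields default to the shipped profiles."""

    G: int = 20
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    total_person_years: float = 4_789_000.0
    gradient: float = -1.6
    baseline_rates: np.ndarray | None = None  # hazard per person-year, per band
    age_pyramid: np.ndarray | None = None  # shares per band, sums to 1
    group_shares: np.ndarray | None = None  # f_g; equal shares if None
    years: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValidationError("need at least 2 socioeconomic groups")
        if self.total_person_years <= 0:
            raise ValidationError("total_person_years must be positive")
        if not np.isfinite(self.gradient):
            raise ValidationError("gradient must be finite")
        n_bands = len(self.age_bands)
        if self.baseline_rates is None:
            # level chosen to give register-like overall rates out of the box
            shape = default_baseline_shape()
            base = shape * (80.0 / (shape @ default_standard_population().weights))
            object.__setattr__(self, "baseline_rates", base)
        else:
            object.__setattr__(
                self, "baseline_rates", np.asarray(self.baseline_rates, dtype=float)
            )
        if self.age_pyramid is None:
            object.__setattr__(self, "age_pyramid", default_age_pyramid())
        else:
            pyr = np.asarray(self.age_pyramid, dtype=float)
            object.__setattr__(self, "age_pyramid", pyr / pyr.sum())
        if self.group_shares is None:
            object.__setattr__(self, "group_shares", np.full(self.G, 1.0 / self.G))
        else:
            fs = np.asarray(self.group_shares, dtype=float)
            if len(fs) != self.G or np.any(fs <= 0):
                raise ValidationError("group_shares must be G positive numbers")
            object.__setattr__(self, "group_shares", fs / fs.sum())
        if len(self.baseline_rates) != n_bands or len(self.age_pyramid) != n_bands:
            raise ValidationError(
                "baseline_rates and age_pyramid must have one entry per age band"
            )


@dataclass(frozen=True)
class SyntheticTable:
    """A generated table together with the truth that produced it."""

    table: AggregatedRegisterTable
    true_rates: np.ndarray  # expected standardized rate per group, per 100,000
    true_C: float
    expected_deaths: float


def true_concentration_index(config: SyntheticConfig) -> float:
    """Closed-form index of the expected rates.

    The age profile is shared across groups, so expected standardized rates
    are proportional to ``exp(gradient * R_g)`` and the index depends only
    on the gradient and the group shares.
    """
    f = config.group_shares
    R = midpoint_ranks(f)
    y = np.exp(config.gradient * R)
    return float(2.0 * (y @ (f * R)) / (f @ y) - 1.0)


def _expected_counts(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expected deaths per (age, group) cell and the fixed person-years."""
    f = config.group_shares
    R = midpoint_ranks(f)
    p = config.total_person_years * np.outer(config.age_pyramid, f)
    rate = np.outer(config.baseline_rates, np.exp(config.gradient * R))
    return p * rate, p


def generate_table(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticTable:
    """Draw one annual table: Poisson counts around the expected cells."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lam, p = _expected_counts(config)
    deaths = rng.poisson(lam)
    seg_labels = tuple(f"income_{g + 1:02d}" for g in range(config.G))
    table = AggregatedRegisterTable(config.age_bands, seg_labels, deaths, p)
    w = default_standard_population().aligned_to(config.age_bands)
    true_rates = (lam / p).T @ w
    return SyntheticTable(
        table=table,
        true_rates=true_rates,
        true_C=true_concentration_index(config),
        expected_deaths=float(lam.sum()),
    )


def generate_panel(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    stdpop: StandardPopulation | None = None,
) -> MultiYearRates:
    """Independent yearly tables, reduced to standardized rates per group."""
    if config.years < 3:
        raise ValidationError("a panel needs at least 3 years")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    stdpop = stdpop or default_standard_population()
    w = stdpop.aligned_to(config.age_bands)
    lam, p = _expected_counts(config)
    rates = np.empty((config.G, config.years))
    for j in range(config.years):
        deaths = rng.poisson(lam)
        rates[:, j] = (deaths / p).T @ w
    seg_labels = tuple(f"income_{g + 1:02d}" for g in range(config.G))
    years = tuple(str(2000 + j) for j in range(config.years))
    return MultiYearRates(seg_labels, years, rates)


def random_table(
    rng: np.random.Generator,
    max_groups: int = 20,
    max_age_bands: int = 15,
) -> tuple[AggregatedRegisterTable, StandardPopulation]:
    """A random valid table (plus matching weights) for property sweeps.

    Group count, age-band count, cell person-years (log-uniform), the
    age-specific baseline hazards and the socioeconomic gradient are all
    randomized; deaths are Poisson.  At least one death is guaranteed so the
    index is always defined.
    """
    G = int(rng.integers(2, max_groups + 1))
    I = int(rng.integers(1, max_age_bands + 1))
    p = 10.0 ** rng.uniform(2.0, 5.0, size=(I, G))
    baseline = 10.0 ** rng.uniform(-4.5, -2.5, size=I)
    gradient = float(rng.normal(0.0, 2.0))
    score = (np.arange(G) + 0.5) / G
    lam = p * baseline[:, None] * np.exp(gradient * score)
    deaths = rng.poisson(lam)
    if deaths.sum() == 0:
        deaths[rng.integers(I), rng.integers(G)] = 1
    ages = tuple(f"age_{i}" for i in range(I))
    segs = tuple(f"seg_{g}" for g in range(G))
    table = AggregatedRegisterTable(ages, segs, deaths, p)
    stdpop = StandardPopulation(ages, rng.uniform(0.5, 2.0, size=I))
    return table, stdpop


def _solve_gradient(target_c: float, G: int) -> float:
    f = np.full(G, 1.0 / G)
    R = midpoint_ranks(f)

    def c_of(gamma: float) -> float:
        y = np.exp(gamma * R)
        return float(2.0 * (y @ (f * R)) / (f @ y) - 1.0)

    return float(brentq(lambda g: c_of(g) - target_c, -30.0, 30.0, xtol=1e-12))


@lru_cache(maxsize=None)
def _calibrated_preset(
    target_c: float,
    target_std_rate: float,
    target_deaths: float,
    total_person_years: float,
    G: int,
) -> SyntheticConfig:
    gradient = _solve_gradient(target_c, G)
    f = np.full(G, 1.0 / G)
    mult_mean = float(f @ np.exp(gradient * midpoint_ranks(f)))
    w = default_standard_population().aligned_to(DEFAULT_AGE_BANDS)
    shape = default_baseline_shape()
    # scale the hazard level to the standardized-rate target
    baseline = shape * (target_std_rate / (shape @ w) / mult_mean)

    def deaths_at(tilt: float) -> float:
        pyr = default_age_pyramid(tilt)
        return total_person_years * float(pyr @ baseline) * mult_mean

    # tilt the pyramid so expected deaths (the crude rate) hit their target
    tilt = float(brentq(lambda t: deaths_at(t) - target_deaths, -0.2, 0.2))
    return SyntheticConfig(
        G=G,
        total_person_years=total_person_years,
        gradient=gradient,
        baseline_rates=baseline,
        age_pyramid=default_age_pyramid(tilt),
    )


PRESETS = {
    # register-scale calibration: true C, standardized rate per 100,000,
    # expected deaths, person-years
    "finland-1996-men": (-0.27, 102.0, 2100.0, 2_394_500.0, 20),
}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    """A calibrated register-scale configuration by preset name."""
    try:
        args = PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    config = _calibrated_preset(*args)
    if overrides:
        from dataclasses import replace

        config = replace(config, **overrides)
    return config
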