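"""Monte Carlo confidence intervals for the concentration index.

Five simulation procedures, differing in what is perturbed and under which
distribution.  In all of them the group structure — population shares f_g,
ranks R_g, the rank variance sigma_R^2, person-years p_ig and the
standard-population weights w_i — is held fixed; only the health outcome is
resimulated:

MC
    Perturbs the dependent variable of the convenience WLS regression,
    ``2 sigma_R^2 y_g / y_bar ~ N(mu_g, sigma_g^2)`` with mu_g the observed
    value and ``sigma_g = 2 sigma_R^2 y_g / (y_bar sqrt(n_g))``, then refits
    the slope.  Defined only for the wls estimator.
MC_RATE
    Perturbs the age-standardized rates, ``y_g* ~ N(y_g, y_g^2 / n_g)``,
    rebuilds the weighted mean, and recomputes C.
BIN
    Redraws cell counts ``d_ig* ~ Binomial(D_i, rho_ig)`` independently per
    cell, with D_i the observed age-group total and rho_ig = d_ig / D_i, so
    the total event count may vary between replicates.
POIS
    Redraws cell counts ``d_ig* ~ Poisson(d_ig)``.
MN
    Redraws each age-group row ``(X_i1..X_iG) ~ Multinomial(D_i, rho_i)``,
    so every replicate preserves the observed age-group totals exactly.

Each procedure yields N replicate values of C; the confidence interval is
the empirical (alpha/2, 1 - alpha/2) percentile band of that distribution,
computed with linear order-statistic interpolation (numpy's default,
"type 7").  Normal-model draws are deliberately not truncated at zero —
truncation would break the symmetry and the median-equals-observed-C
property — and replicates with a non-positive simulated mean rate are
excluded and counted, never silently mixed in.

The per-group variance divisor n_g (the observed event count) can be
overridden to inflate the assumed uncertainty: a smaller divisor means
fewer effective events, hence wider intervals with an unchanged median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_index import (
    AggregatedRegisterTable,
    SEGProfile,
    StandardPopulation,
    ValidationError,
    build_seg_profile,
    concentration_index_formula,
    wls_slope,
)
from .interval_regression import IntervalEstimate

__all__ = [
    "SimulationConfig",
    "ReplicateSet",
    "MultiYearRates",
    "SIMULATION_METHODS",
    "percentile_interval",
    "draw_mc",
    "draw_mc_rate",
    "draw_bin",
    "draw_pois",
    "draw_mn",
    "empirical_rate_variance",
    "run_interval",
]

SIMULATION_METHODS = ("MC", "MC_RATE", "BIN", "POIS", "MN")


@dataclass(frozen=True)
class SimulationConfig:
    """Settings shared by all simulation interval procedures.

    ``estimator`` may be left as None to use the method's natural default
    (wls for MC, formula otherwise).  ``variance_divisor`` replaces the
    observed per-group event counts n_g in the MC / MC_RATE variances; a
    scalar applies to every group.
    """

    method: str
    n_replicates: int = 10_000
    seed: int | None = None
    alpha: float = 0.05
    estimator: str | None = None
    variance_divisor: float | np.ndarray | None = None
    max_failure_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in SIMULATION_METHODS:
            raise ValidationError(
                f"unknown simulation method {self.method!r}; "
                f"expected one of {SIMULATION_METHODS}"
            )
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.estimator not in (None, "formula", "wls"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.method == "MC" and self.estimator == "formula":
            raise ValidationError(
                "MC perturbs the regression's dependent variable and is only "
                "defined for estimator='wls'"
            )
        if self.variance_divisor is not None:
            div = np.asarray(self.variance_divisor, dtype=float)
            if np.any(div <= 0) or not np.all(np.isfinite(div)):
                raise ValidationError("variance_divisor entries must be positive")

    @property
    def resolved_estimator(self) -> str:
        if self.estimator is not None:
            return self.estimator
        return "wls" if self.method == "MC" else "formula"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ReplicateSet:
    """Simulated concentration-index values plus bookkeeping.

    ``values`` holds only the finite, well-defined replicates; replicates
    where C was undefined are counted in ``n_failed``.  ``extras`` carries
    diagnostics such as the count of negative normal draws.
    """

    values: np.ndarray
    n_failed: int = 0
    method: str = ""
    estimator: str = "formula"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValidationError("replicate values must be a 1-d array")
        if not np.all(np.isfinite(v)):
            raise ValidationError("replicate values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MultiYearRates:
    """Panel of age-standardized group rates: one column per year."""

    seg_groups: tuple[str, ...]
    years: tuple[str, ...]
    rates: np.ndarray  # (G, J)

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (len(self.seg_groups), len(self.years)):
            raise ValidationError(
                f"rates must have shape (groups, years) = "
                f"({len(self.seg_groups)}, {len(self.years)}); got {r.shape}"
            )
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValidationError("rates must be finite and non-negative")
        object.__setattr__(self, "years", tuple(str(y) for y in self.years))
        object.__setattr__(self, "rates", r)


def percentile_interval(
    replicates: ReplicateSet,
    alpha: float = 0.05,
    point_estimate: float | None = None,
) -> IntervalEstimate:
    """Empirical (alpha/2, 1 - alpha/2) percentile interval of the replicates.

    Quantiles use linear interpolation between order statistics.  If no
    observed-data point estimate is supplied the replicate median is used
    as the reported C.
    """
    values = replicates.values
    if values.size == 0:
        raise ValidationError("no successful replicates to summarize")
    lower, upper = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    median = float(np.median(values))
    return IntervalEstimate(
        method=replicates.method or "MC",
        C=median if point_estimate is None else float(point_estimate),
        lower=float(lower),
        upper=float(upper),
        alpha=alpha,
        n_replicates=int(values.size) + replicates.n_failed,
        replicate_median=median,
        n_failed=replicates.n_failed,
        estimator=replicates.estimator,
    )


def _variance_divisor(profile: SEGProfile, config: SimulationConfig) -> np.ndarray:
    """Per-group divisor standing in for n_g in the normal-model variances."""
    if config.variance_divisor is None:
        n = profile.n.astype(float)
        if np.any(n <= 0):
            g = profile.seg_groups[int(np.argmin(n))]
            raise ValidationError(
                f"group {g!r} has zero events; supply variance_divisor to "
                "override the per-group variance denominator"
            )
        return n
    return np.broadcast_to(
        np.asarray(config.variance_divisor, dtype=float), profile.f.shape
    ).astype(float)


def _check_failures(n_failed: int, n_total: int, config: SimulationConfig) -> None:
    if n_failed / n_total > config.max_failure_rate:
        raise ValidationError(
            f"{n_failed}/{n_total} replicates had an undefined index, above "
            f"the tolerated failure rate {config.max_failure_rate:.2%}"
        )


def draw_mc(
    profile: SEGProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Normal perturbation of the WLS dependent variable; slope per replicate."""
    if config.method != "MC":
        raise ValidationError(f"config.method is {config.method!r}, expected 'MC'")
    rng = rng or config.rng()
    div = _variance_divisor(profile, config)
    mu = 2.0 * profile.sigma2_R * profile.y / profile.y_mean
    sd = mu / np.sqrt(div)
    z = rng.normal(mu, sd, size=(config.n_replicates, profile.n_seg_groups))
    slopes = wls_slope(z, profile.R, profile.p)
    return ReplicateSet(
        values=slopes,
        n_failed=0,
        method="MC",
        estimator="wls",
        extras={"n_negative_draws": int(np.sum(z < 0))},
    )


def _c_from_rates(
    y_star: np.ndarray, profile: SEGProfile, estimator: str
) -> tuple[np.ndarray, int]:
    """Replicate C values from simulated rates (N, G); fixed group structure.

    The weighted mean rate is recomputed per replicate, so the formula and
    wls routes agree replicate by replicate.  Replicates whose mean rate is
    not strictly positive are dropped and counted.
    """
    f, R, p = profile.f, profile.R, profile.p
    y_mean_star = y_star @ f
    ok = y_mean_star > 0
    n_failed = int(np.sum(~ok))
    y_ok = y_star[ok]
    mean_ok = y_mean_star[ok]
    if estimator == "formula":
        values = 2.0 * (y_ok @ (f * R)) / mean_ok - 1.0
    elif estimator == "wls":
        z = 2.0 * profile.sigma2_R * y_ok / mean_ok[:, None]
        values = wls_slope(z, R, p)
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValidationError(f"unknown estimator {estimator!r}")
    return values, n_failed


def draw_mc_rate(
    profile: SEGProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Normal perturbation of the age-standardized rates, y* ~ N(y, y^2/n)."""
    if config.method != "MC_RATE":
        raise ValidationError(f"config.method is {config.method!r}, expected 'MC_RATE'")
    rng = rng or config.rng()
    div = _variance_divisor(profile, config)
    sd = profile.y / np.sqrt(div)
    y_star = rng.normal(profile.y, sd, size=(config.n_replicates, profile.n_seg_groups))
    values, n_failed = _c_from_rates(y_star, profile, config.resolved_estimator)
    _check_failures(n_failed, config.n_replicates, config)
    return ReplicateSet(
        values=values,
        n_failed=n_failed,
        method="MC_RATE",
        estimator=config.resolved_estimator,
        extras={"n_negative_draws": int(np.sum(y_star < 0))},
    )


def _counts_to_replicates(
    d_star: np.ndarray,
    table: AggregatedRegisterTable,
    stdpop: StandardPopulation,
    profile: SEGProfile,
    config: SimulationConfig,
    method: str,
) -> ReplicateSet:
    """Age-standardize simulated counts and evaluate C per replicate."""
    w = stdpop.aligned_to(table.age_groups)
    # y*_ng = sum_i d*_nig / p_ig * w_i
    y_star = np.einsum("nig,ig->ng", d_star, (w[:, None] / table.person_years))
    values, n_failed = _c_from_rates(y_star, profile, config.resolved_estimator)
    _check_failures(n_failed, config.n_replicates, config)
    return ReplicateSet(
        values=values,
        n_failed=n_failed,
        method=method,
        estimator=config.resolved_estimator,
        extras={"total_events": d_star.sum(axis=(1, 2))},
    )


def _age_totals_and_probs(
    table: AggregatedRegisterTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed age-group totals D_i and cell probabilities rho_ig = d_ig / D_i.

    Rows with D_i = 0 get rho = 0 everywhere and contribute no events in any
    replicate.  Zero probabilities are permitted by construction.
    """
    D = table.deaths.sum(axis=1)
    rho = np.zeros_like(table.deaths, dtype=float)
    nz = D > 0
    rho[nz] = table.deaths[nz] / D[nz, None]
    return D.astype(np.int64), rho


def draw_bin(
    table: AggregatedRegisterTable,
    stdpop: StandardPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Independent binomial redraw of every cell count, d* ~ B(D_i, rho_ig).

    The G binomials within an age group share the total D_i as their index
    but are drawn independently, so the simulated total event count varies
    between replicates (unlike MN).
    """
    if config.method != "BIN":
        raise ValidationError(f"config.method is {config.method!r}, expected 'BIN'")
    D, rho = _age_totals_and_probs(table)
    if np.all(D == 0):
        raise ValidationError("no events in any age group: nothing to simulate")
    rng = rng or config.rng()
    d_star = rng.binomial(
        D[:, None], rho, size=(config.n_replicates, *table.deaths.shape)
    )
    profile = build_seg_profile(table, stdpop)
    return _counts_to_replicates(d_star, table, stdpop, profile, config, "BIN")


def draw_pois(
    table: AggregatedRegisterTable,
    stdpop: StandardPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Poisson redraw of every cell count with the observed count as mean."""
    if config.method != "POIS":
        raise ValidationError(f"config.method is {config.method!r}, expected 'POIS'")
    rng = rng or config.rng()
    d_star = rng.poisson(
        table.deaths, size=(config.n_replicates, *table.deaths.shape)
    )
    profile = build_seg_profile(table, stdpop)
    return _counts_to_replicates(d_star, table, stdpop, profile, config, "POIS")


def draw_mn(
    table: AggregatedRegisterTable,
    stdpop: StandardPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReplicateSet:
    """Multinomial redraw per age group; age totals D_i hold exactly."""
    if config.method != "MN":
        raise ValidationError(f"config.method is {config.method!r}, expected 'MN'")
    D, rho = _age_totals_and_probs(table)
    if np.all(D == 0):
        raise ValidationError("no events in any age group: nothing to simulate")
    rng = rng or config.rng()
    N = config.n_replicates
    d_star = np.zeros((N, *table.deaths.shape), dtype=np.int64)
    for i in range(table.n_age_groups):
        if D[i] > 0:
            d_star[:, i, :] = rng.multinomial(D[i], rho[i], size=N)
    profile = build_seg_profile(table, stdpop)
    return _counts_to_replicates(d_star, table, stdpop, profile, config, "MN")


def empirical_rate_variance(
    panel: MultiYearRates, window: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Per-group sample variance of rates over a window of years.

    Uses the n-1 denominator.  The result can replace the model variance
    ``y_g^2 / n_g`` in the MC_RATE procedure (via ``variance_divisor =
    y_g^2 / var_g``) to check the parametric assumption against the panel.
    """
    window = tuple(str(y) for y in window)
    if len(window) < 2:
        raise ValidationError("empirical variance needs a window of >= 2 years")
    missing = [y for y in window if y not in panel.years]
    if missing:
        raise ValidationError(f"years missing from the panel: {missing}")
    cols = [panel.years.index(y) for y in window]
    return np.var(panel.rates[:, cols], axis=1, ddof=1)


_DRAW_BY_METHOD = {
    "BIN": draw_bin,
    "POIS": draw_pois,
    "MN": draw_mn,
}


def run_interval(
    table: AggregatedRegisterTable,
    stdpop: StandardPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> IntervalEstimate:
    """Run one simulation procedure end to end.

    The reported point estimate is always the concentration index of the
    observed data; the interval comes from the replicate distribution.
    """
    profile = build_seg_profile(table, stdpop)
    c_observed = concentration_index_formula(profile).C
    rng = rng if rng is not None else config.rng()
    if config.method == "MC":
        reps = draw_mc(profile, config, rng)
    elif config.method == "MC_RATE":
        reps = draw_mc_rate(profile, config, rng)
    else:
        reps = _DRAW_BY_METHOD[config.method](table, stdpop, config, rng)
    return percentile_interval(reps, config.alpha, point_estimate=c_observed)
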