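"""Concentration index for aggregated count data.

Implements the building blocks for measuring socioeconomic inequality in a
health outcome from a table of event counts and person-years cross-classified
by age group and socioeconomic group (SEG):

* population shares and midpoint relative ranks per SEG,
* direct age-standardization of group rates against a standard population,
* the concentration index, computed both by the arithmetic formula

      C = (2 / y_bar) * sum_g y_g * f_g * R_g  -  1

  and by the computationally equivalent weighted-least-squares regression of
  the transformed outcome ``2 * sigma_R^2 * y_g / y_bar`` on the rank ``R_g``
  with person-year weights,
* the concentration curve L(s).

SEG ordering is always caller-declared (least -> most advantaged); it is never
inferred from labels, because a silently flipped ordering negates the index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "AggregatedRegisterTable",
    "StandardPopulation",
    "SEGProfile",
    "ConcentrationEstimate",
    "WLSFit",
    "ValidationError",
    "AlignmentError",
    "UndefinedIndexError",
    "SingularFitError",
    "build_seg_profile",
    "age_standardize",
    "concentration_index_formula",
    "concentration_index_wls",
    "concentration_curve",
]

STANDARD_POPULATION_TOTAL = 100_000.0


class ValidationError(ValueError):
    """Input table or weight vector violates a structural invariant."""


class AlignmentError(ValidationError):
    """Age-group labels of two inputs do not match one-to-one."""


class UndefinedIndexError(ValueError):
    """The concentration index is undefined (mean outcome rate is zero)."""


class SingularFitError(ValueError):
    """The WLS design matrix is singular (degenerate ranks)."""


@dataclass(frozen=True)
class AggregatedRegisterTable:
    """Dense table of event counts and person-years by age group x SEG.

    Parameters
    ----------
    age_groups
        Ordered age-band labels (rows), length I.
    seg_groups
        Ordered SEG labels (columns), length G, ordered from the least to the
        most advantaged group.  The order is authoritative.
    deaths
        (I, G) array of non-negative integer event counts.
    person_years
        (I, G) array of strictly positive person-years at risk.
    """

    age_groups: tuple[str, ...]
    seg_groups: tuple[str, ...]
    deaths: np.ndarray
    person_years: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_groups", tuple(str(a) for a in self.age_groups))
        object.__setattr__(self, "seg_groups", tuple(str(s) for s in self.seg_groups))
        d = np.asarray(self.deaths, dtype=float)
        p = np.asarray(self.person_years, dtype=float)
        I, G = len(self.age_groups), len(self.seg_groups)
        if G < 2:
            raise ValidationError(f"need at least 2 socioeconomic groups, got {G}")
        if I < 1:
            raise ValidationError("need at least 1 age group")
        if d.shape != (I, G) or p.shape != (I, G):
            raise ValidationError(
                f"deaths/person_years must have shape ({I}, {G}); "
                f"got {d.shape} and {p.shape}"
            )
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValidationError("deaths must be finite and non-negative")
        if np.any(d != np.round(d)):
            bad = np.argwhere(d != np.round(d))[0]
            raise ValidationError(
                f"deaths must be integers; cell (age={self.age_groups[bad[0]]}, "
                f"seg={self.seg_groups[bad[1]]}) is {d[tuple(bad)]}"
            )
        if not np.all(np.isfinite(p)) or np.any(p <= 0):
            bad = np.argwhere(~(np.isfinite(p) & (p > 0)))[0]
            raise ValidationError(
                f"person_years must be positive; cell (age={self.age_groups[bad[0]]}, "
                f"seg={self.seg_groups[bad[1]]}) is {p[tuple(bad)]}"
            )
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "person_years", p)

    @property
    def n_age_groups(self) -> int:
        return len(self.age_groups)

    @property
    def n_seg_groups(self) -> int:
        return len(self.seg_groups)

    def reversed_seg(self) -> "AggregatedRegisterTable":
        """Return the table with the socioeconomic ordering reversed."""
        return AggregatedRegisterTable(
            self.age_groups,
            tuple(reversed(self.seg_groups)),
            self.deaths[:, ::-1].copy(),
            self.person_years[:, ::-1].copy(),
        )


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights normalized so that they sum to exactly 100,000.

    Any positive weight vector is accepted; it is rescaled at construction so
    that ``weights.sum() == 100_000`` to full floating precision, the
    convention under which standardized rates read as events per 100,000
    person-years.
    """

    age_groups: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "age_groups", tuple(str(a) for a in self.age_groups))
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.age_groups):
            raise ValidationError("one weight per age group is required")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValidationError("standard-population weights must be positive")
        w = w * (STANDARD_POPULATION_TOTAL / w.sum())
        # force the exact total by folding the rounding residual into one
        # weight at a time, smallest first; a single element can oscillate
        # around a rounding tie of the summation, so move on if it does
        for k in np.argsort(w):
            for _ in range(60):
                residual = STANDARD_POPULATION_TOTAL - w.sum()
                if residual == 0.0:
                    break
                w[k] += residual
            if STANDARD_POPULATION_TOTAL - w.sum() == 0.0:
                break
        object.__setattr__(self, "weights", w)

    def aligned_to(self, age_groups: tuple[str, ...]) -> np.ndarray:
        """Weights reordered to match ``age_groups``; labels must correspond 1:1."""
        if sorted(self.age_groups) != sorted(age_groups):
            missing = set(age_groups) - set(self.age_groups)
            extra = set(self.age_groups) - set(age_groups)
            raise AlignmentError(
                "standard-population age groups do not match the table "
                f"(missing: {sorted(missing)}, unmatched: {sorted(extra)})"
            )
        index = {a: k for k, a in enumerate(self.age_groups)}
        return self.weights[[index[a] for a in age_groups]]


@dataclass(frozen=True)
class SEGProfile:
    """Per-SEG summary underlying every estimator and interval method.

    Attributes
    ----------
    f : population (person-year) share per group, sums to 1.
    R : midpoint relative rank, ``R_g = sum_{gamma<g} f_gamma + 0.5 f_g``.
    y : age-standardized rate per 100,000 person-years.
    n : total event count per group.
    p : total person-years per group.
    y_mean : f-weighted mean of y.
    sigma2_R : f-weighted variance of the rank, ``sum_g f_g (R_g - 0.5)^2``.
    """

    seg_groups: tuple[str, ...]
    f: np.ndarray
    R: np.ndarray
    y: np.ndarray
    n: np.ndarray
    p: np.ndarray
    y_mean: float
    sigma2_R: float

    @property
    def n_seg_groups(self) -> int:
        return len(self.seg_groups)

    def with_rates(self, y: np.ndarray) -> "SEGProfile":
        """Same group structure with substituted rates (y_mean recomputed)."""
        y = np.asarray(y, dtype=float)
        return SEGProfile(
            self.seg_groups, self.f, self.R, y, self.n, self.p,
            float(self.f @ y), self.sigma2_R,
        )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Concentration index plus the concentration-curve vertices."""

    C: float
    curve_s: np.ndarray
    curve_L: np.ndarray
    estimator: str  # "formula" | "wls"


@dataclass(frozen=True)
class WLSFit:
    """Weighted least-squares fit whose slope is the concentration index."""

    beta0: float
    beta1: float
    residuals: np.ndarray = field(repr=False)
    se_beta1: float
    weights: np.ndarray = field(repr=False)
    df_resid: int


def age_standardize(
    table: AggregatedRegisterTable, stdpop: StandardPopulation
) -> np.ndarray:
    """Directly age-standardized rate per group, per 100,000 person-years.

    ``y_g = sum_i (d_ig / p_ig) * w_i`` with the weights summing to 100,000.
    """
    w = stdpop.aligned_to(table.age_groups)
    return (table.deaths / table.person_years).T @ w


def midpoint_ranks(f: np.ndarray) -> np.ndarray:
    """Relative ranks at the population midpoint of each group interval."""
    f = np.asarray(f, dtype=float)
    return np.cumsum(f) - 0.5 * f


def build_seg_profile(
    table: AggregatedRegisterTable, stdpop: StandardPopulation
) -> SEGProfile:
    """Derive per-group shares, ranks, standardized rates and totals."""
    y = age_standardize(table, stdpop)
    p = table.person_years.sum(axis=0)
    n = table.deaths.sum(axis=0)
    f = p / p.sum()
    R = midpoint_ranks(f)
    sigma2_R = float(f @ (R - 0.5) ** 2)
    return SEGProfile(
        seg_groups=table.seg_groups,
        f=f,
        R=R,
        y=y,
        n=n,
        p=p,
        y_mean=float(f @ y),
        sigma2_R=sigma2_R,
    )


def concentration_curve(profile: SEGProfile) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-curve vertices ``(s_k, L(s_k))``, prefixed with (0, 0).

    ``s_k`` is the cumulative population share up to group k and ``L(s_k)``
    the cumulative share of the (rate-weighted) outcome, with groups in the
    declared least -> most advantaged order.
    """
    if profile.y_mean <= 0:
        raise UndefinedIndexError(
            "concentration curve undefined: mean rate is zero (no events)"
        )
    s = np.concatenate([[0.0], np.cumsum(profile.f)])
    L = np.concatenate([[0.0], np.cumsum(profile.f * profile.y) / profile.y_mean])
    s[-1] = 1.0  # kill cumulative rounding at the endpoint
    L[-1] = 1.0
    return s, L


def concentration_index_formula(profile: SEGProfile) -> ConcentrationEstimate:
    """Concentration index by the arithmetic formula.

    ``C = (2 / y_mean) * sum_g y_g f_g R_g - 1``; zero under complete
    equality, negative when the outcome is concentrated among the
    disadvantaged, bounded by [-1, 1] for non-binary rate outcomes.
    """
    if profile.y_mean <= 0:
        raise UndefinedIndexError(
            "concentration index undefined: mean rate is zero (no events anywhere)"
        )
    C = 2.0 / profile.y_mean * float(profile.y @ (profile.f * profile.R)) - 1.0
    s, L = concentration_curve(profile)
    return ConcentrationEstimate(C=C, curve_s=s, curve_L=L, estimator="formula")


def wls_dependent(profile: SEGProfile) -> np.ndarray:
    """Transformed dependent variable ``2 * sigma_R^2 * y_g / y_mean``."""
    if profile.y_mean <= 0:
        raise UndefinedIndexError("WLS transform undefined: mean rate is zero")
    return 2.0 * profile.sigma2_R * profile.y / profile.y_mean


def concentration_index_wls(profile: SEGProfile) -> WLSFit:
    """Concentration index as the slope of a convenience WLS regression.

    Regresses ``2 sigma_R^2 y_g / y_mean`` on ``R_g`` with person-year
    weights ``p_g`` (equivalently, OLS on the sqrt(p_g)-premultiplied
    design).  The slope equals the arithmetic-formula C; the slope standard
    error feeds the conventional REG interval.
    """
    G = profile.n_seg_groups
    if G < 2:
        raise ValidationError("WLS slope needs at least 2 groups")
    if np.ptp(profile.R) == 0:
        raise SingularFitError("all group ranks identical: singular design")
    z = wls_dependent(profile)
    X = sm.add_constant(profile.R)
    fit = sm.WLS(z, X, weights=profile.p).fit()
    se = float(fit.bse[1]) if G >= 3 else float("nan")
    return WLSFit(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        residuals=np.asarray(fit.resid, dtype=float),
        se_beta1=se,
        weights=profile.p.copy(),
        df_resid=G - 2,
    )


def wls_slope(z: np.ndarray, R: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closed-form weighted LS slope of ``z`` on ``R`` with weights ``p``.

    Vectorized over leading axes of ``z`` so that simulation replicates can
    be refit in one pass; agrees with :func:`concentration_index_wls` (tested).
    """
    w = p / p.sum()
    dR = R - w @ R
    denom = w @ dR**2
    if denom == 0:
        raise SingularFitError("all group ranks identical: singular design")
    # sum_g w_g dR_g = 0, so centering z is unnecessary
    return z @ (w * dR) / denom
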