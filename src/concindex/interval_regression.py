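"""Analytic reference confidence intervals for the concentration index.

Two procedures widely used for sampled data, kept here as references against
which the simulation intervals are compared:

REG
    The conventional interval built from the WLS slope standard error of the
    convenience regression, ``C +/- q * se(beta1)``.  By default ``q`` is the
    Student-t quantile on G - 2 degrees of freedom, matching the output of
    standard statistical packages.

KWV
    A symmetric interval built from the serial-correlation-corrected variance
    estimator for grouped data,

        var(C) = (1/n) * [ sum_g f_g a_g^2 - (1 + C)^2 ],
        a_g    = (y_g / y_bar) (2 R_g - 1 - C) + 2 - q_{g-1} - q_g,

    where q_g is the concentration-curve ordinate at the upper end of group g
    (q_0 = 0).  The estimator is defined for samples of n observations; for
    register summaries there is no natural sample size, so ``n_obs`` defaults
    to the number of groups G (treating each group summary as one
    observation, which reproduces interval widths of the same order as REG)
    and is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_index import (
    SEGProfile,
    UndefinedIndexError,
    ValidationError,
    WLSFit,
    concentration_curve,
    concentration_index_formula,
)

__all__ = ["IntervalEstimate", "reg_interval", "kwv_interval", "kwv_variance"]


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate of C with a two-sided confidence interval.

    ``n_replicates`` is 0 and ``replicate_median`` None for the analytic
    methods; simulation methods fill both in. ``n_failed`` counts degenerate
    replicates that were excluded.
    """

    method: str  # REG | KWV | MC | MC_RATE | BIN | POIS | MN
    C: float
    lower: float
    upper: float
    alpha: float = 0.05
    n_replicates: int = 0
    replicate_median: float | None = None
    n_failed: int = 0
    estimator: str = "formula"

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.upper < self.lower:
            raise ValidationError("upper bound below lower bound")


def _two_sided_quantile(alpha: float, dist: str, df: int | None = None) -> float:
    if dist == "t":
        if df is None or df < 1:
            raise ValidationError("t quantile needs df >= 1")
        return float(stats.t.ppf(1 - alpha / 2, df))
    if dist == "normal":
        return float(stats.norm.ppf(1 - alpha / 2))
    raise ValidationError(f"unknown quantile distribution {dist!r}")


def reg_interval(fit: WLSFit, alpha: float = 0.05, quantile: str = "t") -> IntervalEstimate:
    """Conventional WLS-slope interval ``beta1 +/- q * se(beta1)``."""
    if fit.df_resid < 1 or not np.isfinite(fit.se_beta1):
        raise ValidationError(
            "REG interval needs a defined slope standard error (G >= 3)"
        )
    q = _two_sided_quantile(alpha, quantile, fit.df_resid)
    half = q * fit.se_beta1
    return IntervalEstimate(
        method="REG",
        C=fit.beta1,
        lower=fit.beta1 - half,
        upper=fit.beta1 + half,
        alpha=alpha,
        estimator="wls",
    )


def kwv_variance(profile: SEGProfile, n_obs: float | None = None) -> float:
    """Serial-correlation-corrected variance of C for a grouped profile."""
    if profile.y_mean <= 0:
        raise UndefinedIndexError("KWV variance undefined: mean rate is zero")
    n = float(n_obs) if n_obs is not None else float(profile.n_seg_groups)
    if n <= 0:
        raise ValidationError("n_obs must be positive")
    C = concentration_index_formula(profile).C
    _, L = concentration_curve(profile)
    q_prev = L[:-1]  # q_0 = 0
    q_curr = L[1:]
    a = (profile.y / profile.y_mean) * (2 * profile.R - 1 - C) + 2 - q_prev - q_curr
    var = (float(profile.f @ a**2) - (1 + C) ** 2) / n
    if var < 0:
        raise ValidationError(
            f"KWV variance came out negative ({var:.3e}); "
            f"C={C:.4f}, sum f a^2={float(profile.f @ a**2):.6f}"
        )
    return var


def kwv_interval(
    profile: SEGProfile,
    alpha: float = 0.05,
    n_obs: float | None = None,
    quantile: str = "normal",
) -> IntervalEstimate:
    """Symmetric interval from the corrected variance (asymptotic normal)."""
    C = concentration_index_formula(profile).C
    se = float(np.sqrt(kwv_variance(profile, n_obs)))
    df = profile.n_seg_groups - 2
    q = _two_sided_quantile(alpha, quantile, df if df >= 1 else None)
    return IntervalEstimate(
        method="KWV",
        C=C,
        lower=C - q * se,
        upper=C + q * se,
        alpha=alpha,
        estimator="formula",
    )
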