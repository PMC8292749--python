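"""Acclimation-response (plasticity) metrics.

An individual's acclimation response for a trait is the log₂ ratio of its
28°C to its 12°C value: 0 means perfect compensation (identical values at
both temperatures), 1 means a doubling at the warm acclimation.  The log₂
scale makes up- and down-regulation symmetric and approximately normal.

Group-level temperature sensitivity is summarized two ways: the fold
change of mass-corrected group means (28/12) and the Q₁₀,
(R₂/R₁)^(10/(T₂−T₁)), computed from raw group means.  Individuals are
classed as low / mid / high plasticity by the empirical 10th and 90th
percentiles of the log₂-ratio distribution, and the dependence of
plasticity on baseline (12°C) performance is quantified by OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import compute_cv
from .respirometry import empirical_quantile

logger = logging.getLogger(__name__)

__all__ = [
    "Q10Result",
    "RegressionResult",
    "compute_plasticity",
    "compute_q10_fold",
    "classify_plasticity_groups",
    "regress_plasticity_on_performance",
    "per_group_plasticity_regression",
]


@dataclass(frozen=True)
class Q10Result:
    trait: str
    t_low: float
    t_high: float
    fold_change: float  # ratio of mass-corrected means, 28/12
    q10: float  # (raw mean ratio)^(10/dT)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def compute_plasticity(
    pairs: pd.DataFrame,
    *,
    trait: str = "",
    value_12_col: str = "value_12",
    value_28_col: str = "value_28",
) -> pd.DataFrame:
    """Per-individual log₂(28°C / 12°C) ratios.

    ``pairs`` holds one row per individual with both temperature values;
    rows with a missing or non-positive value are excluded (counted in the
    log).  The returned frame keeps all other columns (e.g. acclimation
    order) alongside ``log2_ratio``.
    """
    v12 = pd.to_numeric(pairs[value_12_col], errors="coerce")
    v28 = pd.to_numeric(pairs[value_28_col], errors="coerce")
    ok = v12.notna() & v28.notna() & (v12 > 0) & (v28 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "trait %s: %d of %d individuals lack positive values at both "
            "temperatures; excluded from plasticity",
            trait,
            n_dropped,
            len(pairs),
        )
    out = pairs.loc[ok].copy()
    out["log2_ratio"] = np.log2(v28[ok] / v12[ok])
    if trait:
        out["trait"] = trait
    return out


def compute_q10_fold(
    raw_mean_12: float,
    raw_mean_28: float,
    corrected_mean_12: float,
    corrected_mean_28: float,
    *,
    t_low: float = 12.0,
    t_high: float = 28.0,
    trait: str = "",
) -> Q10Result:
    """Fold change (mass-corrected means) and Q₁₀ (raw means).

    The two statistics deliberately use different means: fold change is a
    size-independent effect size, while Q₁₀ is the conventional thermal
    sensitivity of the measured rates.
    """
    if t_high <= t_low:
        raise ValueError("t_high must exceed t_low")
    for name, v in {
        "raw_mean_12": raw_mean_12,
        "raw_mean_28": raw_mean_28,
        "corrected_mean_12": corrected_mean_12,
        "corrected_mean_28": corrected_mean_28,
    }.items():
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    fold = corrected_mean_28 / corrected_mean_12
    q10 = (raw_mean_28 / raw_mean_12) ** (10.0 / (t_high - t_low))
    return Q10Result(
        trait=trait, t_low=t_low, t_high=t_high, fold_change=fold, q10=q10
    )


def classify_plasticity_groups(
    records: pd.DataFrame,
    *,
    low_q: float = 0.10,
    high_q: float = 0.90,
    ratio_col: str = "log2_ratio",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Label individuals low / mid / high by plasticity-distribution cutpoints.

    Cutpoints are the empirical ``low_q`` and ``high_q`` quantiles (linear
    interpolation between order statistics).  Values strictly below the
    lower cutpoint are "low", strictly above the upper are "high"; ties at
    a cutpoint fall in "mid".  Requires at least 10 records for stable
    cutpoints.
    """
    ratios = records[ratio_col].to_numpy(dtype=float)
    if ratios.size < 10:
        raise ValueError(
            f"need >= 10 records for stable plasticity cutpoints, got {ratios.size}"
        )
    lo = empirical_quantile(ratios, low_q)
    hi = empirical_quantile(ratios, high_q)
    out = records.copy()
    out["group"] = np.where(
        ratios < lo, "low", np.where(ratios > hi, "high", "mid")
    )
    return out, (lo, hi)


def regress_plasticity_on_performance(
    records: pd.DataFrame,
    *,
    performance_col: str,
    ratio_col: str = "log2_ratio",
) -> RegressionResult:
    """OLS of the log₂ acclimation response on a baseline performance value.

    ``performance_col`` is typically the 12°C trait value (mass residual
    for metabolic traits, raw for CT_max).  A negative slope means the
    weakest performers at 12°C mount the largest responses.
    """
    sub = records[[performance_col, ratio_col]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete records, got {len(sub)}")
    x = sub[performance_col].to_numpy(dtype=float)
    y = sub[ratio_col].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        # perfectly uniform response: flat line, no evidence either way
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(sub))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(sub),
    )


def per_group_plasticity_regression(
    records: pd.DataFrame,
    *,
    performance_col: str,
    ratio_col: str = "log2_ratio",
    order_col: str = "acclimation_order",
) -> pd.DataFrame:
    """Plasticity regression and response CV within each acclimation-order group.

    The acclimation order (measured at 12°C first versus 28°C first)
    leaves a residual imprint on 12°C performance, so the
    plasticity-versus-baseline relationship is re-examined within each
    order group.  Groups with fewer than 3 complete records are omitted
    (logged).
    """
    rows = []
    for order, grp in records.groupby(order_col, sort=True):
        try:
            reg = regress_plasticity_on_performance(
                grp, performance_col=performance_col, ratio_col=ratio_col
            )
        except ValueError as exc:
            logger.info("order group %s omitted: %s", order, exc)
            continue
        ratios = grp[ratio_col].dropna().to_numpy(dtype=float)
        try:
            cv = compute_cv(ratios)
        except ValueError:
            cv = float("nan")
        rows.append(
            {
                "acclimation_order": order,
                "n": reg.n,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r_squared": reg.r_squared,
                "p_value": reg.p_value,
                "cv_log2_ratio": cv,
            }
        )
    return pd.DataFrame(rows)
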