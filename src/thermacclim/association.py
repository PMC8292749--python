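"""Trait-network statistics: partial correlations and variance partitioning.

Within one acclimation temperature, the pairwise association between two
mass-residual traits controlling for all the others is the partial
correlation, obtained from the inverse of the trait correlation matrix:

    r_ij·rest = −Ω_ij / sqrt(Ω_ii Ω_jj),   Ω = R⁻¹.

Two-sided p-values use t = r·sqrt((n−2−k)/(1−r²)) with k controlled
variables, and the family of unique trait pairs is Bonferroni-controlled.

``variance_explained`` provides a fixed-effects, sequential
(entry-order) sums-of-squares decomposition of a trait onto design terms
(mass, acclimation temperature, order, sex, population, ...), expressed
as percentages that sum to 100 with the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrelationMatrix",
    "partial_correlations",
    "bonferroni_adjust",
    "variance_explained",
]


@dataclass(frozen=True)
class PartialCorrelationMatrix:
    traits: tuple[str, ...]
    r: pd.DataFrame  # partial correlation coefficients, symmetric, diag 1
    p: pd.DataFrame  # two-sided p-values, symmetric, diag NaN
    n_complete: int
    bonferroni_alpha: float

    def to_table(self) -> pd.DataFrame:
        """Square table with r above the diagonal and p below it."""
        k = len(self.traits)
        out = pd.DataFrame(
            np.full((k, k), np.nan), index=self.traits, columns=self.traits
        )
        for i, ti in enumerate(self.traits):
            for j, tj in enumerate(self.traits):
                if i < j:
                    out.iloc[i, j] = self.r.iloc[i, j]
                elif i > j:
                    out.iloc[i, j] = self.p.iloc[i, j]
        return out


def partial_correlations(
    residuals: pd.DataFrame,
    *,
    traits: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> PartialCorrelationMatrix:
    """Partial correlation matrix over complete cases of ``residuals``.

    Each column is one trait's mass residuals; rows are individuals.
    Listwise deletion keeps only individuals with every trait measured.
    """
    if traits is None:
        traits = list(residuals.columns)
    data = residuals[list(traits)].dropna()
    k = len(traits)
    n = len(data)
    if n < k + 3:
        raise ValueError(
            f"{n} complete cases for {k} traits; need at least {k + 3}"
        )
    x = data.to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    # a (near-)singular correlation matrix means some traits are linear
    # combinations of others; name the offending pairs
    if np.linalg.cond(corr) > 1e12:
        dup = [
            (traits[i], traits[j])
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1.0 - 1e-10
        ]
        raise ValueError(
            f"trait correlation matrix is singular; collinear pairs: {dup or 'multivariate'}"
        )
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    r = -omega / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)

    n_controlled = k - 2
    df = n - 2 - n_controlled
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, np.nan)

    m = k * (k - 1) // 2
    return PartialCorrelationMatrix(
        traits=tuple(traits),
        r=pd.DataFrame(r, index=traits, columns=traits),
        p=pd.DataFrame(p, index=traits, columns=traits),
        n_complete=n,
        bonferroni_alpha=alpha / m,
    )


def bonferroni_adjust(
    p: pd.DataFrame | np.ndarray,
    m: int | None = None,
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame | np.ndarray, pd.DataFrame | np.ndarray, float]:
    """Bonferroni-adjusted p-values, significance flags and the threshold.

    ``m`` defaults to the number of unique off-diagonal pairs of a square
    symmetric matrix (15 for six traits).  Adjusted p is min(1, p·m);
    flags mark raw p below alpha/m.
    """
    arr = p.to_numpy() if isinstance(p, pd.DataFrame) else np.asarray(p, dtype=float)
    if m is None:
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("m must be given for non-square input")
        k = arr.shape[0]
        m = k * (k - 1) // 2
    if m <= 0:
        raise ValueError(f"number of tests must be positive, got {m}")
    adjusted = np.minimum(1.0, arr * m)
    threshold = alpha / m
    flags = arr < threshold
    if isinstance(p, pd.DataFrame):
        adjusted = pd.DataFrame(adjusted, index=p.index, columns=p.columns)
        flags = pd.DataFrame(flags, index=p.index, columns=p.columns)
    return adjusted, flags, threshold


def variance_explained(
    data: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    *,
    categorical: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Sequential (type I) sums-of-squares percentages for a fixed-effects model.

    Terms enter the model in the order given (logged), so each term's
    share is the variance it explains beyond the terms before it.
    Per-term F tests use the full model's residual mean square.  The
    returned table has one row per term plus a residual row; the
    ``pct_variance`` column sums to 100.  Terms adding no rank (aliased
    with earlier terms) are kept with zero share and a NaN p-value
    (logged).
    """
    import statsmodels.api as sm

    columns = list(dict.fromkeys(list(terms) + [t for ab in interactions for t in ab]))
    sub = data[[response, *columns]].dropna()
    y = sub[response].to_numpy(dtype=float)
    n = len(y)

    def block(term: str) -> np.ndarray:
        if term in categorical:
            return pd.get_dummies(
                sub[term].astype(str), drop_first=True, dtype=float
            ).to_numpy()
        return sub[term].to_numpy(dtype=float).reshape(-1, 1)

    named_blocks = [(t, block(t)) for t in terms]
    for a, b in interactions:
        ba, bb = block(a), block(b)
        cols = [ba[:, i] * bb[:, j] for i in range(ba.shape[1]) for j in range(bb.shape[1])]
        named_blocks.append((f"{a}:{b}", np.column_stack(cols)))
    logger.info(
        "variance_explained entry order: %s", [nb[0] for nb in named_blocks]
    )

    x = np.ones((n, 1))
    fits = [sm.OLS(y, x).fit()]
    ranks = [1]
    for _, b in named_blocks:
        x = np.column_stack([x, b])
        fits.append(sm.OLS(y, x).fit())
        ranks.append(int(np.linalg.matrix_rank(x)))
    full = fits[-1]
    df_resid = n - ranks[-1]
    mse = full.ssr / df_resid if df_resid > 0 else float("nan")
    total_ss = float(((y - y.mean()) ** 2).sum())
    if total_ss == 0.0:
        raise ValueError("response has zero variance; nothing to partition")

    rows = []
    for i, (name, _) in enumerate(named_blocks):
        ss = float(fits[i].ssr - fits[i + 1].ssr)
        df_term = ranks[i + 1] - ranks[i]
        if df_term == 0:
            logger.warning("term %s is aliased with earlier terms; dropped", name)
            p_val = float("nan")
        else:
            f = (ss / df_term) / mse if mse > 0 else np.inf
            p_val = float(stats.f.sf(f, df_term, df_resid))
        rows.append(
            {"term": name, "pct_variance": 100.0 * ss / total_ss, "p_value": p_val}
        )
    rows.append(
        {
            "term": "residual",
            "pct_variance": 100.0 * float(full.ssr) / total_ss,
            "p_value": float("nan"),
        }
    )
    return pd.DataFrame(rows)
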