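"""Whole-animal intermittent-flow respirometry processing.

Converts raw oxygen-concentration traces recorded in closed measurement
periods into per-individual standard metabolic rate (SMR).  The chain is:

1. ``fit_period_slope`` — ordinary least squares of O2 (µmol l⁻¹) on time
   within one measurement period; the consumption-positive magnitude of the
   decline is ``K`` (µmol O2 min⁻¹ l⁻¹).
2. ``filter_slopes`` — discard periods whose linear fit has R² below a
   quality threshold (default 0.9).
3. ``background_correct`` — subtract the chamber's microbial/background
   respiration slope estimated from blank runs.
4. ``compute_mo2`` — MO2 = K·V converted to mg O2 h⁻¹, where V is chamber
   volume minus organism volume (litres).
5. ``compute_smr`` — SMR is the 10th-percentile value read off the
   cumulative frequency distribution of an individual's replicate MO2
   values (linear interpolation between order statistics), requiring a
   minimum number of replicate rates (default 20).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SlopeFit",
    "RespirometryConfig",
    "MetabolicRate",
    "fit_period_slope",
    "fit_trace_slopes",
    "filter_slopes",
    "background_correct",
    "compute_mo2",
    "compute_smr",
    "empirical_quantile",
    "estimate_smr_from_traces",
]

#: grams of O2 per mole; configurable through RespirometryConfig.
O2_MOLAR_MASS_G_PER_MOL = 31.998


@dataclass(frozen=True)
class SlopeFit:
    """Linear decline fitted to one measurement period.

    ``k`` is the consumption-positive magnitude of the fitted O2 decline in
    µmol O2 min⁻¹ l⁻¹ (i.e. minus the per-minute OLS slope).  ``r_squared``
    is NaN for degenerate (zero-variance) periods, which always fail the
    quality filter.
    """

    period_id: str
    k: float
    r_squared: float
    n_points: int
    individual_id: str = ""
    chamber_id: str = ""


@dataclass(frozen=True)
class RespirometryConfig:
    min_r_squared: float = 0.9
    min_replicates: int = 20
    smr_percentile: float = 0.10
    chamber_volume_l: float = 1.5
    organism_density_g_per_ml: float = 1.0
    o2_molar_mass_g_per_mol: float = O2_MOLAR_MASS_G_PER_MOL
    #: background respiration slope per chamber (µmol O2 min⁻¹ l⁻¹); a
    #: scalar applies to every chamber.
    background_slope: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.smr_percentile < 1.0):
            raise ValueError(
                f"smr_percentile must lie in (0, 1), got {self.smr_percentile}"
            )
        if self.min_replicates <= 0:
            raise ValueError("min_replicates must be positive")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber_volume_l must be positive")

    def background_for(self, chamber_id: str) -> float:
        if isinstance(self.background_slope, Mapping):
            try:
                return float(self.background_slope[chamber_id])
            except KeyError:
                raise KeyError(
                    f"no background-slope estimate for chamber {chamber_id!r}"
                ) from None
        return float(self.background_slope)


@dataclass(frozen=True)
class MetabolicRate:
    individual_id: str
    mo2: float  # mg O2 h⁻¹
    n_replicates_used: int
    acclimation_temp: float = float("nan")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of y on x via the normal equations.

    R² is NaN when y has zero variance (a flat trace carries no goodness of
    fit information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x.mean()
    ym = y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("zero variance in time axis; cannot fit a slope")
    sxy = float(((x - xm) * (y - ym)).sum())
    syy = float(((y - ym) ** 2).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    if syy == 0.0:
        return slope, intercept, float("nan")
    ss_res = syy - slope * sxy
    return slope, intercept, max(0.0, 1.0 - ss_res / syy)


def fit_period_slope(
    time_s: Sequence[float],
    o2_umol_l: Sequence[float],
    *,
    period_id: str = "",
    individual_id: str = "",
    chamber_id: str = "",
) -> SlopeFit:
    """OLS decline of one measurement period.

    ``time_s`` is seconds from period start and must be strictly
    increasing; at least three samples are required.
    """
    t = np.asarray(time_s, dtype=float)
    o2 = np.asarray(o2_umol_l, dtype=float)
    if t.size < 3:
        raise ValueError(
            f"period {period_id!r}: need >= 3 samples to fit a slope, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"period {period_id!r}: time must be strictly increasing")
    if not np.all(np.isfinite(o2)):
        raise ValueError(f"period {period_id!r}: non-finite O2 values")
    slope_per_s, _, r2 = _ols_line(t, o2)
    k = -slope_per_s * 60.0  # consumption-positive, per minute
    return SlopeFit(
        period_id=period_id,
        k=k,
        r_squared=r2,
        n_points=int(t.size),
        individual_id=individual_id,
        chamber_id=chamber_id,
    )


def fit_trace_slopes(traces: pd.DataFrame) -> list[SlopeFit]:
    """Fit every (individual, period) group of a long-format trace table.

    Expects columns ``individual_id, chamber_id, period_id, time_s,
    o2_umol_per_l`` (extra columns are ignored).
    """
    fits: list[SlopeFit] = []
    for (ind, chamber, period), grp in traces.groupby(
        ["individual_id", "chamber_id", "period_id"], sort=True
    ):
        grp = grp.sort_values("time_s")
        fits.append(
            fit_period_slope(
                grp["time_s"].to_numpy(),
                grp["o2_umol_per_l"].to_numpy(),
                period_id=str(period),
                individual_id=str(ind),
                chamber_id=str(chamber),
            )
        )
    return fits


def filter_slopes(
    fits: Iterable[SlopeFit], config: RespirometryConfig
) -> list[SlopeFit]:
    """Retain fits with R² at or above the quality threshold.

    NaN R² (flat periods) never passes.  The per-individual minimum
    replicate count is enforced later, at the SMR stage, where the
    individual can be excluded as a whole.
    """
    fits = list(fits)
    kept = [f for f in fits if f.r_squared >= config.min_r_squared]
    n_dropped = len(fits) - len(kept)
    if n_dropped:
        logger.info(
            "R^2 filter (>= %.3g): retained %d of %d periods",
            config.min_r_squared,
            len(kept),
            len(fits),
        )
    return kept


def background_correct(
    fit: SlopeFit, config: RespirometryConfig
) -> SlopeFit | None:
    """Subtract the chamber's background respiration from ``k``.

    Returns None (flagged missing) when the corrected slope would be
    negative — the animal cannot consume less than nothing, so such
    periods are treated as unusable rather than clamped to zero.
    """
    bg = config.background_for(fit.chamber_id)
    k_corr = fit.k - bg
    if k_corr < 0.0:
        logger.warning(
            "period %s (individual %s): corrected slope %.4g below zero; flagged missing",
            fit.period_id,
            fit.individual_id,
            k_corr,
        )
        return None
    return replace(fit, k=k_corr)


def compute_mo2(
    k: float | SlopeFit, body_mass_g: float, config: RespirometryConfig
) -> float:
    """MO2 = K·V in mg O2 h⁻¹.

    V (litres) is the chamber volume minus the organism volume, the latter
    obtained from body mass assuming density ``organism_density_g_per_ml``
    (1 g ml⁻¹ by default).  K is in µmol O2 min⁻¹ l⁻¹, so
    MO2 = K · V · 60 min h⁻¹ · M(O2) / 1000 converts µmol h⁻¹ to mg h⁻¹.
    """
    if isinstance(k, SlopeFit):
        k = k.k
    organism_volume_l = body_mass_g / config.organism_density_g_per_ml / 1000.0
    v = config.chamber_volume_l - organism_volume_l
    if v <= 0.0:
        raise ValueError(
            f"non-positive effective volume: chamber {config.chamber_volume_l} l, "
            f"organism {organism_volume_l} l"
        )
    return k * v * 60.0 * config.o2_molar_mass_g_per_mol / 1000.0


def empirical_quantile(values: Sequence[float], q: float) -> float:
    """Quantile by linear interpolation between order statistics.

    The value at position 1 + (n−1)·q of the sorted sample — a point on
    the empirical cumulative frequency distribution curve, not an average
    of the tail.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    h = (v.size - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, v.size - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def compute_smr(
    rates: Sequence[float],
    config: RespirometryConfig,
    *,
    individual_id: str = "",
    acclimation_temp: float = float("nan"),
) -> MetabolicRate:
    """SMR as the configured percentile of replicate MO2 values.

    Raises if fewer than ``min_replicates`` rates survive filtering; the
    caller should exclude the individual and log the count.
    """
    rates = np.asarray(list(rates), dtype=float)
    if rates.size < config.min_replicates:
        raise ValueError(
            f"individual {individual_id!r}: only {rates.size} replicate rates, "
            f"minimum is {config.min_replicates}"
        )
    smr = empirical_quantile(rates, config.smr_percentile)
    return MetabolicRate(
        individual_id=individual_id,
        mo2=smr,
        n_replicates_used=int(rates.size),
        acclimation_temp=acclimation_temp,
    )


def estimate_smr_from_traces(
    traces: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RespirometryConfig,
) -> pd.DataFrame:
    """End-to-end SMR estimation for a long-format trace table.

    ``metadata`` needs one row per (individual_id, acclimation_temp) with a
    ``body_mass_g`` column; when traces carry an ``acclimation_temp``
    column the join respects it.  Returns a tidy table with one row per
    individual × temperature (excluded individuals are reported with NaN
    SMR and an ``exclusion_reason``).
    """
    meta_cols = ["individual_id", "body_mass_g"]
    has_temp = "acclimation_temp" in traces.columns and "acclimation_temp" in metadata.columns
    if has_temp:
        meta_cols.append("acclimation_temp")
    meta = metadata[meta_cols].drop_duplicates()

    group_keys = ["individual_id"] + (["acclimation_temp"] if has_temp else [])
    rows = []
    for key, grp in traces.groupby(group_keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        ind = str(key[0])
        temp = float(key[1]) if has_temp else float("nan")
        fits = fit_trace_slopes(grp)
        n_raw = len(fits)
        fits = filter_slopes(fits, config)
        corrected = [background_correct(f, config) for f in fits]
        corrected = [f for f in corrected if f is not None]

        sel = meta["individual_id"].astype(str) == ind
        if has_temp:
            sel &= meta["acclimation_temp"] == temp
        match = meta.loc[sel]
        if match.empty:
            raise KeyError(f"no metadata row for individual {ind!r}")
        mass = float(match["body_mass_g"].iloc[0])

        rates = [compute_mo2(f, mass, config) for f in corrected]
        row = {
            "individual_id": ind,
            "acclimation_temp": temp,
            "n_periods": n_raw,
            "n_filtered": n_raw - len(rates),
            "n_replicates": len(rates),
            "smr_mg_o2_h": float("nan"),
            "exclusion_reason": "",
        }
        try:
            mr = compute_smr(
                rates, config, individual_id=ind, acclimation_temp=temp
            )
            row["smr_mg_o2_h"] = mr.mo2
        except ValueError as exc:
            row["exclusion_reason"] = str(exc)
            logger.warning("%s", exc)
        rows.append(row)
    return pd.DataFrame(rows)
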