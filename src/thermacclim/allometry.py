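"""Allometric mass correction of physiological traits.

Body size inflates metabolic rates, so trait comparisons among individuals
use the residuals of a trait-versus-mass regression, re-centred at a
reference mass (10.2 g, the study-average individual):

    X_corrected = X_mean + Y

where X_mean is the regression's predicted trait value at the reference
mass and Y is the individual's residual.  Whole-animal metabolism scales as
a power law and is fitted on the log10–log10 scale; cardiac rates and
CT_max use a linear fit.  The heart-mass covariate path is identical, just
with a different mass column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .respirometry import _ols_line

logger = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_MASS_G",
    "AllometricFit",
    "fit_mass_regression",
    "mass_correct",
    "compute_cv",
    "cv_ratio_table",
    "default_transform",
    "mass_correct_trait_table",
]

REFERENCE_MASS_G = 10.2

TRANSFORMS = ("log10", "linear")


@dataclass(frozen=True)
class AllometricFit:
    trait: str
    transform: str  # "log10" (log10 trait on log10 mass) or "linear"
    intercept: float
    slope_b: float  # scaling exponent (log10) or linear slope
    slope_se: float
    r_squared: float
    n: int
    covariate: str = "body_mass"
    mass_min: float = float("nan")
    mass_max: float = float("nan")

    def predict(self, mass: float | np.ndarray) -> float | np.ndarray:
        """Predicted trait value on the *fitting* scale."""
        mass = np.asarray(mass, dtype=float)
        if self.transform == "log10":
            out = self.intercept + self.slope_b * np.log10(mass)
        else:
            out = self.intercept + self.slope_b * mass
        return float(out) if out.ndim == 0 else out


def default_transform(trait: str) -> str:
    """Whole-animal metabolic rate is power-law (log10–log10); cardiac
    rates and CT_max are fitted linearly."""
    return "log10" if trait.upper().startswith("WAM") else "linear"


def fit_mass_regression(
    values,
    masses,
    *,
    transform: str = "linear",
    trait: str = "",
    covariate: str = "body_mass",
) -> AllometricFit:
    """OLS of trait on mass, on the declared scale."""
    values = np.asarray(values, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if values.size != masses.size:
        raise ValueError("values and masses differ in length")
    if values.size < 3:
        raise ValueError(f"trait {trait!r}: need >= 3 observations, got {values.size}")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected {TRANSFORMS}")
    if np.any(masses <= 0):
        raise ValueError(f"trait {trait!r}: non-positive masses")
    if transform == "log10":
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise ValueError(
                f"trait {trait!r}: non-positive values under log transform "
                f"at indices {bad.tolist()}"
            )
        x = np.log10(masses)
        y = np.log10(values)
    else:
        x = masses
        y = values
    slope, intercept, r2 = _ols_line(x, y)
    if np.isnan(r2):  # constant trait: mass explains nothing
        r2 = 0.0
    resid = y - (intercept + slope * x)
    sxx = float(((x - x.mean()) ** 2).sum())
    dof = x.size - 2
    slope_se = math.sqrt(float((resid**2).sum()) / dof / sxx) if dof > 0 else float("nan")
    return AllometricFit(
        trait=trait,
        transform=transform,
        intercept=intercept,
        slope_b=slope,
        slope_se=slope_se,
        r_squared=r2,
        n=int(values.size),
        covariate=covariate,
        mass_min=float(masses.min()),
        mass_max=float(masses.max()),
    )


def mass_correct(
    fit: AllometricFit,
    values,
    masses,
    *,
    reference_mass_g: float = REFERENCE_MASS_G,
) -> pd.DataFrame:
    """Residuals and reference-mass corrected values for each individual.

    Residuals (``residual``) and corrected values (``corrected``) are on
    the fitting scale; for log10-transformed traits the back-transformed
    corrected value is also emitted (``corrected_backtransformed``) since
    summaries are usually reported in natural units.
    """
    values = np.asarray(values, dtype=float)
    masses = np.asarray(masses, dtype=float)
    lo, hi = fit.mass_min / 10.0, fit.mass_max * 10.0
    outside = (masses < lo) | (masses > hi)
    if np.any(outside):
        logger.warning(
            "%d masses lie outside 10x the fitted range [%.3g, %.3g] g; "
            "corrected values extrapolated",
            int(outside.sum()),
            fit.mass_min,
            fit.mass_max,
        )
    if fit.transform == "log10":
        obs = np.log10(values)
    else:
        obs = values
    residual = obs - fit.predict(masses)
    corrected = fit.predict(reference_mass_g) + residual
    out = pd.DataFrame({"residual": residual, "corrected": corrected})
    if fit.transform == "log10":
        out["corrected_backtransformed"] = 10.0 ** corrected
    return out


def compute_cv(values) -> float:
    """Coefficient of variation, 100 × sample SD / mean (percent).

    Sample SD uses the n−1 denominator.  Undefined (NaN) for n < 2;
    an error for zero mean, where the ratio has no meaning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def cv_ratio_table(cv_by_trait_temp: pd.DataFrame) -> pd.DataFrame:
    """Per-trait ratio of the 12°C CV to the 28°C CV.

    Input needs columns ``trait, acclimation_temp, cv``; traits missing
    either temperature are omitted (logged).  A ratio above 1 means more
    interindividual variation at the cold acclimation.
    """
    wide = cv_by_trait_temp.pivot_table(
        index="trait", columns="acclimation_temp", values="cv"
    )
    rows = []
    for trait, row in wide.iterrows():
        if 12 not in row.index or 28 not in row.index or row[[12, 28]].isna().any():
            logger.info("trait %s: CV missing at one temperature; ratio omitted", trait)
            continue
        rows.append(
            {
                "trait": trait,
                "cv_12": float(row[12]),
                "cv_28": float(row[28]),
                "cv_ratio_12_28": float(row[12] / row[28]),
            }
        )
    return pd.DataFrame(rows)


def mass_correct_trait_table(
    trait_table: pd.DataFrame,
    traits,
    *,
    covariate: str = "body_mass_g",
    reference_mass_g: float = REFERENCE_MASS_G,
    transforms: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[AllometricFit]]:
    """Fit and mass-correct each trait within each acclimation temperature.

    Regressions are fitted separately per temperature because the mass
    relationship itself changes with acclimation.  Returns the input table
    with ``<trait>_residual`` / ``<trait>_corrected`` columns added, plus
    the per-(trait, temperature) fits.  Rows with a missing trait or mass
    value are left NaN for that trait.
    """
    out = trait_table.copy()
    fits: list[AllometricFit] = []
    for trait in traits:
        transform = (transforms or {}).get(trait, default_transform(trait))
        res_col = f"{trait}_residual"
        cor_col = f"{trait}_corrected"
        out[res_col] = np.nan
        out[cor_col] = np.nan
        if transform == "log10":
            out[f"{trait}_corrected_backtransformed"] = np.nan
        for temp, grp in trait_table.groupby("acclimation_temp", sort=True):
            ok = grp[trait].notna() & grp[covariate].notna()
            grp = grp.loc[ok]
            if len(grp) < 3:
                logger.info(
                    "trait %s at %s degC: %d complete rows, skipping fit",
                    trait,
                    temp,
                    len(grp),
                )
                continue
            fit = fit_mass_regression(
                grp[trait].to_numpy(),
                grp[covariate].to_numpy(),
                transform=transform,
                trait=f"{trait}@{temp}",
                covariate=covariate,
            )
            fits.append(fit)
            corr = mass_correct(
                fit,
                grp[trait].to_numpy(),
                grp[covariate].to_numpy(),
                reference_mass_g=reference_mass_g,
            )
            out.loc[grp.index, res_col] = corr["residual"].to_numpy()
            out.loc[grp.index, cor_col] = corr["corrected"].to_numpy()
            if "corrected_backtransformed" in corr:
                out.loc[grp.index, f"{trait}_corrected_backtransformed"] = corr[
                    "corrected_backtransformed"
                ].to_numpy()
    return out, fits
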