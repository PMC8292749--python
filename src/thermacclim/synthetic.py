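"""Seeded synthetic cohorts, respirometry traces and cardiac runs.

The generator emulates a two-temperature (12 / 28 °C) acclimation study on
a small estuarine fish: per-individual trait tables for whole-animal
metabolic rate (WAM, mg O2 h⁻¹), four substrate-specific cardiac metabolic
rates (CaM, pmol O2 s⁻¹) and critical thermal maximum (CT_max, °C), plus
the raw oxygen traces from which the metabolic traits are re-derived by
the analysis modules.  Ground truth is stored alongside every output so
parameter-recovery tests have an answer key; analysis stages never read it.

Construction, per trait:

1. Mass-corrected 12 °C values are drawn first (lognormal for rates,
   Gaussian for CT_max), with a symmetric ±δ/2 acclimation-order shift
   whose variance is budgeted into the draw so configured moments hold.
2. The 28 °C value is ``value_12 × 2^plasticity`` with
   ``plasticity = intercept + slope × z(value_12) + noise``.  The
   intercept and the noise SD are calibrated in closed form against the
   realized cohort so the 28 °C mean and SD match their configured
   targets; the default slope (per trait) cancels the baseline's
   contribution to the 28 °C spread, reproducing the observed decoupling
   of warm-acclimation values from cold-acclimation performance.
3. Observed values add the body-mass dependence: a power law
   (mass/10.2)^b for WAM and linear slopes for CaM and CT_max.

Traces invert the analysis arithmetic: each clean measurement period
declines at the rate implied by the period's metabolic rate through
MO2 = K·V, plus chamber background drift and Gaussian sensor noise.
Per-period activity multipliers are placed so the population 10th
percentile of replicate rates equals the individual's true SMR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cardiac import SUBSTRATES, RUN_LENGTH_S, WINDOW_START_S
from .respirometry import O2_MOLAR_MASS_G_PER_MOL

logger = logging.getLogger(__name__)

__all__ = [
    "TRAITS",
    "DEFAULT_TRAIT_MOMENTS",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_respirometry_traces",
    "generate_cardiac_runs",
]

TRAITS = ("WAM", "CaM_GLU", "CaM_FA", "CaM_LKA", "CaM_END", "CT_max")

#: traits drawn with additive Gaussian noise (approximately symmetric,
#: small SD relative to mean); all others are lognormal to stay positive.
GAUSSIAN_TRAITS = frozenset({"CT_max"})

LN2 = math.log(2.0)
_Z90 = 1.2815515655446004  # standard-normal 90th percentile


@dataclass(frozen=True)
class TraitMoments:
    """Published study-scale moments for one trait × acclimation temperature."""

    n: int
    raw_mean: float
    raw_sd: float
    corrected_mean: float
    corrected_sd: float
    mass_r2: float


#: Reference cohort moments for Fundulus heteroclitus acclimated to 12 or
#: 28 °C: raw and mass-corrected (10.2 g reference) means and SDs.  These
#: are the generator's default emulation targets and the closed-form
#: inputs for fold-change / Q10 / CV summaries.
DEFAULT_TRAIT_MOMENTS: dict[tuple[str, int], TraitMoments] = {
    ("WAM", 12): TraitMoments(85, 1.86, 0.69, 1.82, 0.66, 0.1138),
    ("WAM", 28): TraitMoments(112, 4.27, 1.31, 4.23, 1.25, 0.0775),
    ("CaM_FA", 12): TraitMoments(50, 35.35, 21.87, 34.45, 18.73, 0.2664),
    ("CaM_FA", 28): TraitMoments(49, 32.82, 9.81, 33.31, 7.36, 0.4414),
    ("CaM_GLU", 12): TraitMoments(58, 42.77, 17.5, 42.52, 15.87, 0.1810),
    ("CaM_GLU", 28): TraitMoments(51, 48.84, 14.41, 47.11, 12.24, 0.3028),
    ("CaM_LKA", 12): TraitMoments(58, 29.64, 8.59, 29.47, 7.38, 0.2907),
    ("CaM_LKA", 28): TraitMoments(50, 28.85, 10.1, 28.82, 8.14, 0.4241),
    ("CaM_END", 12): TraitMoments(55, 28.2, 11.92, 27.73, 10.52, 0.2261),
    ("CaM_END", 28): TraitMoments(49, 18.12, 8.55, 17.98, 6.9, 0.3693),
    ("CT_max", 12): TraitMoments(114, 36.28, 0.81, 26.3, 0.79, 0.0555),
    ("CT_max", 28): TraitMoments(97, 42.47, 0.27, 32.48, 0.36, 0.0020),
}


def _default_trait_means() -> dict[str, dict[int, float]]:
    return {
        t: {12: DEFAULT_TRAIT_MOMENTS[(t, 12)].corrected_mean,
            28: DEFAULT_TRAIT_MOMENTS[(t, 28)].corrected_mean}
        for t in TRAITS
    }


def _default_trait_sds() -> dict[str, dict[int, float]]:
    return {
        t: {12: DEFAULT_TRAIT_MOMENTS[(t, 12)].corrected_sd,
            28: DEFAULT_TRAIT_MOMENTS[(t, 28)].corrected_sd}
        for t in TRAITS
    }


@dataclass
class SyntheticConfig:
    """All knobs of the cohort / trace / cardiac-run generators.

    Defaults reproduce the study conditions: ~160 fish from three
    populations, 10.2 g reference mass, the published trait moments,
    acclimation-order effects on 12 °C measures, at least 25 measurement
    periods per overnight respirometry run (12 min at 12 °C, 6 min at
    28 °C) and four 6-minute cardiac runs per heart in substrate order
    GLU → FA → LKA → END with ≥3 blank runs per chamber-day.
    """

    n_individuals: int = 160
    populations: Mapping[str, float] = field(
        default_factory=lambda: {"N.Ref": 1 / 3, "TE": 1 / 3, "S.Ref": 1 / 3}
    )
    sex_ratio: float = 0.5  # fraction female
    body_mass_mean_g: float = 10.2
    body_mass_cv: float = 0.30
    allometric_exponent_b: float = 0.80
    #: linear mass slopes for the linearly mass-dependent traits
    cam_mass_slope_pmol_per_g: float = 1.5
    ctmax_mass_slope_c_per_g: float = 0.05
    trait_means: dict[str, dict[int, float]] = field(default_factory=_default_trait_means)
    trait_sds: dict[str, dict[int, float]] = field(default_factory=_default_trait_sds)
    #: log2 plasticity change per SD of 12 °C performance; None selects,
    #: per trait, the slope that decouples 28 °C values from 12 °C
    #: performance; 0 gives a null (plasticity independent of baseline)
    plasticity_baseline_slope: float | None = None
    #: SD of the plasticity noise term; None auto-calibrates it so the
    #: 28 °C spread matches the configured SD
    plasticity_noise_sd: float | None = None
    #: additive 12 °C difference (order group 1 minus group 2), per trait
    acclimation_order_effect: dict[str, float] = field(
        default_factory=lambda: {"WAM": 0.3, "CT_max": -0.8}
    )
    #: lognormal SD of per-period activity above SMR; positioned so the
    #: population 10th percentile of replicate rates is the true SMR
    activity_sigma: float = 0.12
    n_periods: int = 25
    period_length_s: dict[int, float] = field(
        default_factory=lambda: {12: 720.0, 28: 360.0}
    )
    sample_interval_s: float = 5.0
    noise_sd_o2: float = 0.3  # µmol l⁻¹ sensor noise on traces
    background_slope: float = 0.02  # µmol O2 min⁻¹ l⁻¹ chamber drift
    fraction_noisy_periods: float = 0.08
    chamber_volume_l: float = 1.5
    o2_start_umol_l: float = 250.0
    # --- cardiac micro-respirometry ---
    cardiac_chamber_volume_l: float = 0.001
    cardiac_sample_interval_s: float = 5.0
    cardiac_noise_sd_o2: float = 0.2
    cardiac_background_slope_umol_l_s: float = 0.002
    n_blanks: int = 3
    individuals_per_day: int = 8
    #: cardiosomatic index (heart mass / body mass) per acclimation
    #: temperature; larger hearts after cold acclimation (remodeling)
    cardiosomatic_index: dict[int, float] = field(
        default_factory=lambda: {12: 0.0035, 28: 0.0028}
    )
    heart_mass_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"n_individuals must be >= 1, got {self.n_individuals}")
        if abs(sum(self.populations.values()) - 1.0) > 1e-9:
            raise ValueError("populations proportions must sum to 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError(f"sex_ratio must lie in [0, 1], got {self.sex_ratio}")
        for name in ("body_mass_cv", "activity_sigma", "noise_sd_o2",
                     "cardiac_noise_sd_o2", "heart_mass_cv"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not (0.0 <= self.fraction_noisy_periods <= 1.0):
            raise ValueError(
                f"fraction_noisy_periods must lie in [0, 1], "
                f"got {self.fraction_noisy_periods}"
            )
        if self.plasticity_noise_sd is not None and self.plasticity_noise_sd < 0:
            raise ValueError(
                f"plasticity_noise_sd must be non-negative, "
                f"got {self.plasticity_noise_sd}"
            )
        for trait, per_temp in self.trait_sds.items():
            for temp, sd in per_temp.items():
                if sd < 0:
                    raise ValueError(
                        f"trait_sds[{trait!r}][{temp}] must be non-negative, got {sd}"
                    )
        for trait, per_temp in self.trait_means.items():
            if trait not in GAUSSIAN_TRAITS:
                for temp, m in per_temp.items():
                    if m <= 0:
                        raise ValueError(
                            f"trait_means[{trait!r}][{temp}] must be positive "
                            f"for a lognormal trait, got {m}"
                        )


@dataclass
class GroundTruth:
    """Answer key for one generated cohort; never read by analysis stages.

    ``records`` has one row per individual × temperature with the true
    mass-corrected and observed (mass-dependent) value of every trait;
    the observed WAM is the true SMR (mg O2 h⁻¹) behind the traces and
    the observed CaM columns are the true cardiac rates (pmol O2 s⁻¹).
    ``plasticity`` has one row per individual with the true log2 28/12
    ratio of each trait's mass-corrected values.
    """

    records: pd.DataFrame
    plasticity: pd.DataFrame
    allometric_exponent_b: float
    background_slope: float
    cardiac_background_slope_umol_l_s: float


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log for a lognormal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _calibrate_plasticity(
    value_12: np.ndarray,
    z: np.ndarray,
    slope: float,
    target_mean: float,
    target_sd: float,
    noise_sd: float | None,
    trait: str,
) -> tuple[float, float]:
    """Intercept and noise SD of the plasticity term, matched to the
    realized cohort so 28 °C = 12 °C × 2^plasticity has the target moments.

    With w_i = ln(value_12_i) + u·z_i (u = ln2·slope), the 28 °C values are
    exp(w_i + ln2·(a + ε_i)); matching E[mean] and E[mean of squares] over
    ε to the targets gives closed forms for the noise variance (clamped at
    zero when the coupled baseline already exceeds the target spread) and
    then the intercept a.
    """
    u = LN2 * slope
    w = np.log(value_12) + u * z
    w0 = w.mean()  # factor out for numerical comfort
    v1 = float(np.mean(np.exp(w - w0)))
    v2 = float(np.mean(np.exp(2.0 * (w - w0))))
    ratio = (target_mean**2 + target_sd**2) / target_mean**2 * (v1**2 / v2)
    if noise_sd is None:
        if ratio < 1.0:
            logger.warning(
                "trait %s: baseline spread through the plasticity coupling "
                "already exceeds the 28 degC target SD; noise clamped to 0",
                trait,
            )
            noise_sd = 0.0
        else:
            noise_sd = math.sqrt(math.log(ratio)) / LN2
    g = math.exp(LN2**2 * noise_sd**2 / 2.0)
    intercept = (math.log(target_mean) - w0 - math.log(v1 * g)) / LN2
    return intercept, noise_sd


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort trait table (one row per individual × temperature).

    Returns the observed table the analysis consumes plus the ground
    truth.  Identical (seed, config) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_individuals
    ids = np.array([f"F{i + 1:04d}" for i in range(n)])

    pops = list(config.populations)
    probs = np.array([config.populations[p] for p in pops], dtype=float)
    population = rng.choice(pops, size=n, p=probs / probs.sum())
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    # half the cohort per acclimation order, randomly assigned
    order = np.array(["group1"] * n)
    order[rng.permutation(n)[: n // 2]] = "group2"

    mu_m, sig_m = _lognormal_params(config.body_mass_mean_g,
                                    config.body_mass_mean_g * config.body_mass_cv)
    mass = np.exp(rng.normal(mu_m, sig_m, size=n))

    corrected: dict[str, dict[int, np.ndarray]] = {}
    observed: dict[str, dict[int, np.ndarray]] = {}
    plasticity_true: dict[str, np.ndarray] = {}

    for trait in config.trait_means:
        m12 = config.trait_means[trait][12]
        s12 = config.trait_sds[trait][12]
        m28 = config.trait_means[trait][28]
        s28 = config.trait_sds[trait][28]
        delta = config.acclimation_order_effect.get(trait, 0.0)
        # budget the order-shift variance into the baseline draw
        s_base = math.sqrt(max(s12**2 - delta**2 / 4.0, (0.02 * s12) ** 2))
        if trait in GAUSSIAN_TRAITS:
            base = rng.normal(m12, s_base, size=n)
        else:
            mu, sig = _lognormal_params(m12, s_base)
            base = np.exp(rng.normal(mu, sig, size=n))
        shift = np.where(order == "group1", delta / 2.0, -delta / 2.0)
        v12 = np.maximum(base + shift, 1e-9)

        # standardized 12 degC performance: log scale for rates, raw for
        # the (narrow, symmetric) CT_max
        basis = v12 if trait in GAUSSIAN_TRAITS else np.log(v12)
        sd_basis = basis.std()
        z = (basis - basis.mean()) / sd_basis if sd_basis > 0 else np.zeros(n)

        if config.plasticity_baseline_slope is None:
            if trait in GAUSSIAN_TRAITS:
                slope = -(v12.std() / v12.mean()) / LN2 if v12.mean() != 0 else 0.0
            else:
                slope = -sd_basis / LN2
        else:
            slope = config.plasticity_baseline_slope

        intercept, noise_sd = _calibrate_plasticity(
            v12, z, slope, m28, s28, config.plasticity_noise_sd, trait
        )
        plast = intercept + slope * z + rng.normal(0.0, noise_sd, size=n)
        v28 = v12 * np.exp2(plast)

        corrected[trait] = {12: v12, 28: v28}
        plasticity_true[trait] = plast
        obs = {}
        for temp, v in ((12, v12), (28, v28)):
            if trait == "WAM":
                obs[temp] = v * (mass / config.body_mass_mean_g) ** config.allometric_exponent_b
            elif trait in GAUSSIAN_TRAITS:
                obs[temp] = v + config.ctmax_mass_slope_c_per_g * (mass - config.body_mass_mean_g)
            else:
                obs[temp] = v + config.cam_mass_slope_pmol_per_g * (mass - config.body_mass_mean_g)
        observed[trait] = obs

    rows = []
    truth_rows = []
    for temp in (12, 28):
        hsi = config.cardiosomatic_index[temp]
        heart = (
            hsi
            * mass
            * np.exp(rng.normal(0.0, math.sqrt(math.log(1 + config.heart_mass_cv**2)), n))
        )
        for i in range(n):
            row = {
                "individual_id": ids[i],
                "population": population[i],
                "sex": sex[i],
                "acclimation_order": order[i],
                "acclimation_temp": float(temp),
                "body_mass_g": mass[i],
                "heart_mass_g": heart[i],
            }
            truth = dict(row)
            for trait in config.trait_means:
                row[trait] = observed[trait][temp][i]
                truth[f"{trait}_observed_true"] = observed[trait][temp][i]
                truth[f"{trait}_corrected_true"] = corrected[trait][temp][i]
            rows.append(row)
            truth_rows.append(truth)

    cohort = pd.DataFrame(rows)
    truth_records = pd.DataFrame(truth_rows)
    plast_df = pd.DataFrame(
        {"individual_id": ids}
        | {f"log2_plasticity_{t}": plasticity_true[t] for t in config.trait_means}
    )
    truth = GroundTruth(
        records=truth_records,
        plasticity=plast_df,
        allometric_exponent_b=config.allometric_exponent_b,
        background_slope=config.background_slope,
        cardiac_background_slope_umol_l_s=config.cardiac_background_slope_umol_l_s,
    )
    return cohort, truth


def _true_rate_lookup(truth: GroundTruth, column: str) -> dict[tuple[str, float], float]:
    rec = truth.records
    return {
        (r["individual_id"], float(r["acclimation_temp"])): float(r[column])
        for _, r in rec.iterrows()
    }


def generate_respirometry_traces(
    cohort: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Long-format whole-animal O2 traces for every cohort row.

    Each individual × temperature gets ``n_periods`` measurement periods
    (12 min at 12 °C, 6 min at 28 °C).  Clean periods decline linearly at
    the rate implied by (true SMR × activity multiplier) through
    MO2 = K·V, plus background drift; contaminated periods additionally
    carry a sinusoidal excursion large enough to fail an R² ≥ 0.9 filter.
    The ``contaminated`` column is ground-truth annotation.
    """
    smr_of = _true_rate_lookup(truth, "WAM_observed_true")
    frames = []
    for idx, row in cohort.iterrows():
        key = (row["individual_id"], float(row["acclimation_temp"]))
        if key not in smr_of:
            raise ValueError(f"individual {key[0]!r} at {key[1]} degC has no true SMR")
    rng = np.random.default_rng([config.seed, 2])
    n_contam = int(round(config.fraction_noisy_periods * config.n_periods))
    for idx, row in cohort.reset_index(drop=True).iterrows():
        ind = row["individual_id"]
        temp = float(row["acclimation_temp"])
        smr = smr_of[(ind, temp)]
        mass = float(row["body_mass_g"])
        v = config.chamber_volume_l - mass / 1000.0
        if v <= 0:
            raise ValueError(f"individual {ind!r}: organism fills the chamber")
        chamber = f"C{idx % 8 + 1}"
        length = config.period_length_s[int(temp)]
        t = np.arange(0.0, length + 1e-9, config.sample_interval_s)
        contam_ids = set(
            rng.choice(config.n_periods, size=n_contam, replace=False).tolist()
        )
        for p in range(config.n_periods):
            activity = (
                math.exp(rng.normal(_Z90 * config.activity_sigma, config.activity_sigma))
                if config.activity_sigma > 0
                else 1.0
            )
            rate = smr * activity  # mg O2 h⁻¹ for this period
            k = rate / (v * 60.0 * O2_MOLAR_MASS_G_PER_MOL / 1000.0)
            slope_s = (k + config.background_slope) / 60.0
            o2 = config.o2_start_umol_l - slope_s * t
            if p in contam_ids:
                drop = (k / 60.0) * length
                amp = 0.6 * drop + 8.0 * config.noise_sd_o2
                o2 = o2 + amp * np.sin(2.0 * np.pi * 3.0 * t / length)
            if config.noise_sd_o2 > 0:
                o2 = o2 + rng.normal(0.0, config.noise_sd_o2, size=t.size)
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "acclimation_temp": temp,
                        "chamber_id": chamber,
                        "period_id": f"P{p + 1:03d}",
                        "time_s": t,
                        "o2_umol_per_l": o2,
                        "contaminated": p in contam_ids,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_cardiac_runs(
    cohort: pd.DataFrame, truth: GroundTruth, config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cardiac chamber runs (four substrates per heart) and blank runs.

    Each substrate has a dedicated chamber; individuals are batched into
    chamber-days with ``n_blanks`` blank runs per chamber-day whose slope
    is background leak only.  Runs settle during the first three minutes
    (slope 1.3× the true rate) and are exactly linear over the analysis
    window, so windowed slopes recover the truth at zero noise.
    """
    cam_of = {
        trait: _true_rate_lookup(truth, f"{trait}_observed_true")
        for trait in TRAITS
        if trait.startswith("CaM_")
    }
    rng = np.random.default_rng([config.seed, 3])
    t = np.arange(0.0, RUN_LENGTH_S + 1e-9, config.cardiac_sample_interval_s)
    settle = np.minimum(t, WINDOW_START_S)
    bg = config.cardiac_background_slope_umol_l_s

    run_frames = []
    blank_frames = []
    days_seen: set[tuple[str, str]] = set()
    for idx, row in cohort.reset_index(drop=True).iterrows():
        ind = row["individual_id"]
        temp = float(row["acclimation_temp"])
        day = f"T{int(temp)}-D{idx // config.individuals_per_day + 1:03d}"
        for s_i, substrate in enumerate(SUBSTRATES):
            trait = f"CaM_{substrate}"
            key = (ind, temp)
            if key not in cam_of[trait]:
                raise ValueError(
                    f"individual {ind!r} at {temp} degC has no true {trait}"
                )
            rate = cam_of[trait][key]  # pmol O2 s⁻¹
            slope_s = rate * 1e-6 / config.cardiac_chamber_volume_l + bg
            chamber = f"CC{s_i + 1}"
            # settling: 1.3x decline during the first three minutes, then
            # exactly the true slope inside the analysis window
            o2 = config.o2_start_umol_l - 1.3 * slope_s * settle - slope_s * (t - settle)
            if config.cardiac_noise_sd_o2 > 0:
                o2 = o2 + rng.normal(0.0, config.cardiac_noise_sd_o2, size=t.size)
            run_frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "acclimation_temp": temp,
                        "chamber_id": chamber,
                        "day": day,
                        "substrate": substrate,
                        "time_s": t,
                        "o2_umol_per_l": o2,
                    }
                )
            )
            if (chamber, day) not in days_seen:
                days_seen.add((chamber, day))
                for b in range(config.n_blanks):
                    o2b = config.o2_start_umol_l - bg * t
                    if config.cardiac_noise_sd_o2 > 0:
                        o2b = o2b + rng.normal(
                            0.0, config.cardiac_noise_sd_o2, size=t.size
                        )
                    blank_frames.append(
                        pd.DataFrame(
                            {
                                "chamber_id": chamber,
                                "day": day,
                                "blank_id": f"B{b + 1}",
                                "time_s": t,
                                "o2_umol_per_l": o2b,
                            }
                        )
                    )
    return (
        pd.concat(run_frames, ignore_index=True),
        pd.concat(blank_frames, ignore_index=True),
    )
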