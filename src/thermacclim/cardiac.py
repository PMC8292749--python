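"""Substrate-specific cardiac micro-respirometry (CaM).

Excised ventricles respire in 1 ml chambers for six minutes per substrate,
in a fixed substrate order: GLU (glucose), FA (fatty acids), LKA
(lactate + ketones + ethanol) and END (endogenous, no added fuel with
glycolysis inhibited).  The oxygen-consumption slope over the final three
minutes of each run, minus the mean slope of that chamber-day's blank
runs (≥3 required), times the chamber volume, gives CaM in pmol O2 s⁻¹.

Negative blank-corrected rates are retained but flagged so population
summaries stay unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .respirometry import _ols_line

logger = logging.getLogger(__name__)

__all__ = [
    "SUBSTRATES",
    "CaMRate",
    "cam_window_slope",
    "compute_cam",
    "compute_cam_table",
    "summarize_substrates",
]

#: assay order: glucose first, then glycolytic inhibitors are added and the
#: three glucose-independent substrates follow.
SUBSTRATES = ("GLU", "FA", "LKA", "END")

RUN_LENGTH_S = 360.0
WINDOW_START_S = 180.0

#: default micro-respiration chamber volume (1 ml).
CARDIAC_CHAMBER_VOLUME_L = 0.001

MIN_BLANKS = 3


@dataclass(frozen=True)
class CaMRate:
    individual_id: str
    substrate: str
    rate_pmol_s: float
    flagged: bool
    acclimation_temp: float = float("nan")


def cam_window_slope(
    time_s,
    o2_umol_l,
    *,
    window_start_s: float = WINDOW_START_S,
    window_end_s: float = RUN_LENGTH_S,
) -> float:
    """Consumption-positive O2 slope (µmol l⁻¹ s⁻¹) over the analysis window.

    Only samples with ``window_start_s <= t <= window_end_s`` enter the
    OLS fit; the run must cover the window with at least three samples.
    """
    t = np.asarray(time_s, dtype=float)
    o2 = np.asarray(o2_umol_l, dtype=float)
    if t.size and t.max() < window_start_s:
        raise ValueError(
            f"run ends at {t.max():.0f} s, before the analysis window "
            f"starting at {window_start_s:.0f} s"
        )
    mask = (t >= window_start_s) & (t <= window_end_s)
    if mask.sum() < 3:
        raise ValueError(
            f"analysis window [{window_start_s:.0f}, {window_end_s:.0f}] s "
            f"contains {int(mask.sum())} samples; need >= 3"
        )
    slope, _, _ = _ols_line(t[mask], o2[mask])
    return -slope


def compute_cam(
    run_slope_umol_l_s: float,
    blank_slopes_umol_l_s,
    *,
    chamber_volume_l: float = CARDIAC_CHAMBER_VOLUME_L,
    individual_id: str = "",
    substrate: str = "",
    acclimation_temp: float = float("nan"),
) -> CaMRate:
    """Blank-corrected cardiac metabolic rate in pmol O2 s⁻¹.

    rate = (run slope − mean blank slope) · V · 1e6, with slopes in
    µmol l⁻¹ s⁻¹ and V in litres (µmol s⁻¹ → pmol s⁻¹ is the 1e6).
    """
    blanks = np.asarray(list(blank_slopes_umol_l_s), dtype=float)
    if blanks.size < MIN_BLANKS:
        raise ValueError(
            f"need >= {MIN_BLANKS} blank runs for correction, got {blanks.size}"
        )
    rate = (run_slope_umol_l_s - blanks.mean()) * chamber_volume_l * 1e6
    flagged = rate <= 0.0
    if flagged:
        logger.warning(
            "individual %s substrate %s: blank-corrected CaM %.4g <= 0; flagged",
            individual_id,
            substrate,
            rate,
        )
    return CaMRate(
        individual_id=individual_id,
        substrate=substrate,
        rate_pmol_s=float(rate),
        flagged=bool(flagged),
        acclimation_temp=acclimation_temp,
    )


def compute_cam_table(
    runs: pd.DataFrame,
    blanks: pd.DataFrame,
    *,
    chamber_volume_l: float = CARDIAC_CHAMBER_VOLUME_L,
) -> pd.DataFrame:
    """CaM for every (individual, substrate) run, blank-corrected per chamber-day.

    ``runs`` is long format with columns ``individual_id, chamber_id, day,
    substrate, time_s, o2_umol_per_l`` (optionally ``acclimation_temp``);
    ``blanks`` has ``chamber_id, day, blank_id, time_s, o2_umol_per_l``.
    Blanks are matched by (chamber_id, day); all of a day's blanks are
    averaged when more than three were run.
    """
    blank_slopes: dict[tuple[str, str], list[float]] = {}
    for (chamber, day, _blank), grp in blanks.groupby(
        ["chamber_id", "day", "blank_id"], sort=True
    ):
        grp = grp.sort_values("time_s")
        blank_slopes.setdefault((str(chamber), str(day)), []).append(
            cam_window_slope(grp["time_s"].to_numpy(), grp["o2_umol_per_l"].to_numpy())
        )

    has_temp = "acclimation_temp" in runs.columns
    rows = []
    group_cols = ["individual_id", "chamber_id", "day", "substrate"]
    if has_temp:  # one assay event per temperature
        group_cols.append("acclimation_temp")
    for group_key, grp in runs.groupby(group_cols, sort=True):
        ind, chamber, day, substrate = group_key[:4]
        if substrate not in SUBSTRATES:
            raise ValueError(
                f"unknown substrate {substrate!r}; expected one of {SUBSTRATES}"
            )
        key = (str(chamber), str(day))
        if key not in blank_slopes or len(blank_slopes[key]) < MIN_BLANKS:
            n = len(blank_slopes.get(key, []))
            raise ValueError(
                f"chamber {chamber!r} day {day!r}: {n} blank runs, "
                f"need >= {MIN_BLANKS}"
            )
        grp = grp.sort_values("time_s")
        slope = cam_window_slope(
            grp["time_s"].to_numpy(), grp["o2_umol_per_l"].to_numpy()
        )
        cam = compute_cam(
            slope,
            blank_slopes[key],
            chamber_volume_l=chamber_volume_l,
            individual_id=str(ind),
            substrate=str(substrate),
            acclimation_temp=float(grp["acclimation_temp"].iloc[0])
            if has_temp
            else float("nan"),
        )
        rows.append(
            {
                "individual_id": cam.individual_id,
                "acclimation_temp": cam.acclimation_temp,
                "substrate": cam.substrate,
                "cam_pmol_s": cam.rate_pmol_s,
                "flagged": cam.flagged,
            }
        )
    return pd.DataFrame(rows)


def summarize_substrates(cam_table: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, n and within-temperature rank per substrate × temperature.

    Rank 1 is the substrate supporting the highest mean rate at that
    acclimation temperature.  Single-observation groups report NaN SD;
    empty groups are simply absent (logged).
    """
    rows = []
    for (temp, substrate), grp in cam_table.groupby(
        ["acclimation_temp", "substrate"], sort=True
    ):
        vals = grp["cam_pmol_s"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.info("substrate %s at %s degC: empty group omitted", substrate, temp)
            continue
        rows.append(
            {
                "acclimation_temp": temp,
                "substrate": substrate,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["rank"] = (
            out.groupby("acclimation_temp")["mean"]
            .rank(ascending=False, method="min")
            .astype(int)
        )
    return out
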