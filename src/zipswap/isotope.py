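"""Dual-isotope internal-competition transport assay analysis.

Cells expressing a transporter take up a mixture of radioactive 65Zn and
109Cd from the same well; a gamma counter reads two energy windows
(800-1500 keV for Zn, 30-150 keV for Cd) so both substrates are quantified
simultaneously.  Because both tracers share every well-level nuisance factor
(expression level, cell number, wash losses), the within-well Zn/Cd ratio is
invariant to those factors -- the point of internal competition.

65Zn also emits within the Cd window, so Zn-only standards calibrate a
linear crosstalk slope (Cd-window counts per Zn-window count) that is
subtracted from Cd-window readings.  Transport activity is the mean counts
of transporter-transfected wells minus the mean of empty-vector wells, per
experiment; relative quantities are expressed as percent of wild type
within the same experiment.

All count tables are tidy pandas DataFrames with columns::

    experiment_id, well_id, construct, zn_window_cpm, cd_window_cpm

Standards tables use ``standard_conc_uM, zn_window_cpm, cd_window_cpm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

WELL_COLUMNS = ["experiment_id", "well_id", "construct",
                "zn_window_cpm", "cd_window_cpm"]

#: Crosstalk slope measured for 65Zn spill-over into the Cd window
#: (Cd-window counts per Zn-window count); also the generator default.
DEFAULT_CROSSTALK_SLOPE = 0.235


@dataclass(frozen=True)
class CalibrationModel:
    """Linear Zn->Cd-window crosstalk calibration.

    The production fit forces the intercept through zero (well background is
    handled by empty-vector subtraction downstream, not by the calibration
    line); the free-intercept fit is carried as a diagnostic.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    free_slope: float
    free_intercept: float

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("crosstalk slope must be non-negative")
        if self.n_points < 2:
            raise ValueError("calibration requires >= 2 standards")


def fit_crosstalk(standards: pd.DataFrame) -> CalibrationModel:
    """Least-squares crosstalk slope from Zn-only standard wells.

    Regresses Cd-window counts on Zn-window counts with the intercept fixed
    at zero: ``s = sum(x*y) / sum(x**2)``.  Requires >= 2 standards spanning
    a non-zero range of Zn-window counts.
    """
    x = np.asarray(standards["zn_window_cpm"], dtype=float)
    y = np.asarray(standards["cd_window_cpm"], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 standard wells")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "all standards have identical Zn-window counts; slope is "
            "unidentifiable")
    sxx = float(x @ x)
    slope = float(x @ y) / sxx
    resid = y - slope * x
    syy = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    free_slope, free_intercept = np.polyfit(x, y, 1)
    return CalibrationModel(slope=max(slope, 0.0), intercept=0.0,
                            r_squared=r2, n_points=len(x),
                            free_slope=float(free_slope),
                            free_intercept=float(free_intercept))


def crosstalk_slope_se(standards: pd.DataFrame, slope: float) -> float:
    """Analytic standard error of the zero-intercept slope estimator."""
    x = np.asarray(standards["zn_window_cpm"], dtype=float)
    y = np.asarray(standards["cd_window_cpm"], dtype=float)
    resid = y - slope * x
    dof = len(x) - 1
    return float(np.sqrt((resid @ resid) / dof / (x @ x)))


def correct_cd_window(
    cd_window_cpm, zn_window_cpm, calib: CalibrationModel, *,
    clip_negative: bool = True,
):
    """Remove the 65Zn contribution from Cd-window counts.

    ``corrected = cd - slope * zn``.  Negative results are clipped to zero
    with a flag by default (``clip_negative=False`` keeps them, which is the
    right choice when the corrected counts feed unbiased averaging).
    Accepts scalars or arrays; returns ``(corrected, clipped_flag)``.
    """
    cd = np.asarray(cd_window_cpm, dtype=float)
    zn = np.asarray(zn_window_cpm, dtype=float)
    corrected = cd - calib.slope * zn
    clipped = corrected < 0
    if clip_negative:
        corrected = np.where(clipped, 0.0, corrected)
    if corrected.ndim == 0:
        return float(corrected), bool(clipped)
    return corrected, clipped


def well_zn_cd_ratio(zn_window_cpm, cd_window_cpm, calib: CalibrationModel):
    """Within-well Zn / (crosstalk-corrected Cd) count ratio.

    Because both windows are read from the same well, a common multiplicative
    nuisance factor (expression level, cell number) cancels exactly:
    ``c*zn / (c*cd - s*c*zn) = zn / (cd - s*zn)``.  This invariance is the
    rationale of the internal-competition design.
    """
    zn = np.asarray(zn_window_cpm, dtype=float)
    corrected, _ = correct_cd_window(cd_window_cpm, zn, calib,
                                     clip_negative=False)
    return zn / corrected


class TTestSummary(NamedTuple):
    mean: float
    sd: float
    t_statistic: float
    p_value: float


def aggregate_and_test(variant_values, wt_values, *,
                       welch: bool = False) -> TTestSummary:
    """Mean, SD and two-sided t-test p-value of variant vs wild-type arms.

    Classic equal-variance Student's t by default; ``welch=True`` switches to
    the unequal-variance form.  Identical zero-variance arms report t=0, p=1.
    """
    a = np.asarray(variant_values, dtype=float)
    b = np.asarray(wt_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per arm for a t-test")
    if np.array_equal(a, b) and np.std(a) == 0:
        return TTestSummary(float(np.mean(a)), 0.0, 0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestSummary(float(np.mean(a)), float(np.std(a, ddof=1)),
                        float(t), float(p))


def _check_wells(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    if (df["zn_window_cpm"] < 0).any() or (df["cd_window_cpm"] < 0).any():
        raise ValueError("negative counts in measurement table")
    return df


def compute_activity(
    measurements: pd.DataFrame,
    calib: CalibrationModel,
    *,
    wt_label: str = "WT",
    empty_label: str = "empty_vector",
    relative: bool = True,
    clip_negative_cd: bool = False,
) -> pd.DataFrame:
    """Background-subtracted transport activities per construct and metal.

    Per experiment: Cd-window counts are crosstalk-corrected per well, then
    activity = mean(construct wells) - mean(empty-vector wells) for each
    window.  With ``relative=True`` activities are also expressed as percent
    of the wild-type activity within the same experiment (WT = 100 by
    construction).  Returns tidy rows
    (experiment_id, construct, metal, activity_cpm, relative_activity_pct).
    """
    df = _check_wells(measurements).copy()
    corrected, _ = correct_cd_window(
        df["cd_window_cpm"], df["zn_window_cpm"], calib,
        clip_negative=clip_negative_cd)
    df["cd_corrected_cpm"] = corrected

    rows = []
    for exp, g in df.groupby("experiment_id", sort=True):
        empty = g[g["construct"] == empty_label]
        if empty.empty:
            raise ValueError(f"experiment {exp!r} has no "
                             f"{empty_label!r} wells")
        bg = {"Zn": empty["zn_window_cpm"].mean(),
              "Cd": empty["cd_corrected_cpm"].mean()}
        per_construct: dict[str, dict[str, float]] = {}
        for construct, gc in g[g["construct"] != empty_label].groupby(
                "construct", sort=True):
            per_construct[construct] = {
                "Zn": gc["zn_window_cpm"].mean() - bg["Zn"],
                "Cd": gc["cd_corrected_cpm"].mean() - bg["Cd"],
            }
        if relative and wt_label not in per_construct:
            raise ValueError(
                f"experiment {exp!r} lacks wild-type wells "
                f"({wt_label!r}) required for relative activities")
        for construct, acts in per_construct.items():
            for metal in ("Zn", "Cd"):
                rel = float("nan")
                if relative:
                    wt_act = per_construct[wt_label][metal]
                    rel = 100.0 * acts[metal] / wt_act if wt_act != 0 else float("nan")
                rows.append({
                    "experiment_id": exp,
                    "construct": construct,
                    "metal": metal,
                    "activity_cpm": acts[metal],
                    "relative_activity_pct": rel,
                })
    return pd.DataFrame(rows)


@dataclass
class SelectivityResult:
    """Per-experiment Zn/Cd selectivity ratios and the WT-relative summary."""

    per_experiment: pd.DataFrame   # experiment_id, construct, zn_cd_ratio,
                                   # relative_selectivity_pct
    summary: pd.DataFrame          # construct, mean ratio, mean relative
                                   # selectivity, n experiments, p vs WT
    excluded: pd.DataFrame         # experiments dropped (Cd activity <= 0)


def selectivity(activities: pd.DataFrame, *, wt_label: str = "WT",
                welch: bool = False) -> SelectivityResult:
    """Zn/Cd selectivity per experiment, expressed relative to wild type.

    The ratio is computed per experiment from that experiment's mean
    activities (Zn / corrected Cd), then relative selectivity is
    100 * ratio_variant / ratio_WT within the same experiment; the
    cross-experiment summary is the mean of per-experiment values, mirroring
    a per-experiment-dot presentation.  Experiments where a construct's Cd
    activity is <= 0 are excluded for that construct and reported.
    """
    wide = activities.pivot_table(index=["experiment_id", "construct"],
                                  columns="metal", values="activity_cpm",
                                  sort=True).reset_index()
    bad = wide[wide["Cd"] <= 0]
    wide = wide[wide["Cd"] > 0].copy()
    wide["zn_cd_ratio"] = wide["Zn"] / wide["Cd"]

    wt = wide[wide["construct"] == wt_label][["experiment_id", "zn_cd_ratio"]]
    wt = wt.rename(columns={"zn_cd_ratio": "wt_ratio"})
    merged = wide.merge(wt, on="experiment_id", how="left")
    merged["relative_selectivity_pct"] = (
        100.0 * merged["zn_cd_ratio"] / merged["wt_ratio"])

    per_exp = merged[["experiment_id", "construct", "zn_cd_ratio",
                      "relative_selectivity_pct"]]
    wt_ratios = per_exp[per_exp["construct"] == wt_label]["zn_cd_ratio"]

    rows = []
    for construct, g in per_exp.groupby("construct", sort=True):
        p = float("nan")
        if construct != wt_label and len(g) >= 2 and len(wt_ratios) >= 2:
            p = aggregate_and_test(g["zn_cd_ratio"], wt_ratios,
                                   welch=welch).p_value
        rows.append({
            "construct": construct,
            "zn_cd_ratio": g["zn_cd_ratio"].mean(),
            "relative_selectivity_pct": g["relative_selectivity_pct"].mean(),
            "n_experiments": len(g),
            "p_vs_wt": p,
        })
    return SelectivityResult(
        per_experiment=per_exp.reset_index(drop=True),
        summary=pd.DataFrame(rows),
        excluded=bad.reset_index(drop=True),
    )
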