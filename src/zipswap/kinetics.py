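"""Hill-model uptake kinetics, specificity constants, competition, ICP-MS ratios.

Uptake saturation curves are fitted with the Hill model

    v(S) = Vmax * S**n / (K**n + S**n)

by nonlinear least squares; K is the half-saturation constant (reported as
K_M for continuity with kinetic tables, although for n != 1 it is the Hill
half-saturation point) and n the Hill coefficient.  The specificity constant
Vmax/K compares low-substrate transport efficiency between substrates or
constructs.  Replicates are fitted as pooled points, not means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CURVE_COLUMNS = ["construct", "metal", "conc_uM", "rate"]

# g/mol; used to convert ICP-MS mass concentrations to molar ratios
ATOMIC_WEIGHTS = {"Mn": 54.938, "P": 30.974, "Zn": 65.38, "Cd": 112.414,
                  "Fe": 55.845}


def hill(S, vmax, k, n):
    """Hill saturation model v = Vmax * S^n / (K^n + S^n)."""
    S = np.asarray(S, dtype=float)
    return vmax * S**n / (k**n + S**n)


@dataclass
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors.

    ``specificity`` is Vmax/K; its SE comes from the delta method using the
    parameter covariance at the optimum.
    """

    vmax: float
    k: float
    n: float
    se_vmax: float = float("nan")
    se_k: float = float("nan")
    se_n: float = float("nan")
    specificity_se: float = float("nan")
    converged: bool = True
    rss: float = float("nan")
    n_points: int = 0
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.k <= 0 or self.n <= 0:
            raise ValueError("Hill parameters must be positive")

    @property
    def specificity(self) -> float:
        return self.vmax / self.k


class HillFitError(RuntimeError):
    """Raised when no start point converges; carries the best residual seen."""

    def __init__(self, message: str, best_rss: float):
        super().__init__(f"{message} (best residual sum of squares: {best_rss:g})")
        self.best_rss = best_rss


def _initial_k(S: np.ndarray, v: np.ndarray) -> float:
    """Concentration at half-max rate, interpolated on the mean curve."""
    df = pd.DataFrame({"S": S, "v": v}).groupby("S", sort=True)["v"].mean()
    half = df.max() / 2.0
    above = df[df >= half]
    if above.empty:
        return float(np.median(S[S > 0])) if np.any(S > 0) else 1.0
    k0 = float(np.interp(half, df.values, df.index.values))
    return k0 if k0 > 0 else float(above.index[0])


def fit_hill(
    curve: pd.DataFrame,
    *,
    fix_n: float | None = None,
    weights: str | None = None,
    bounds_vmax_factor: float = 10.0,
    bounds_k_factor: float = 100.0,
    n_bounds: tuple[float, float] = (0.3, 4.0),
) -> HillFit:
    """Fit the Hill model to an uptake curve by nonlinear least squares.

    ``curve`` needs columns ``conc_uM`` and ``rate`` (>= 4 distinct
    concentrations).  Initialisation: Vmax0 = max rate, K0 interpolated at
    half-max, n0 = 1 with a multi-start over n0 in {0.5, 1, 2} on failure.
    Bounds: Vmax in (0, 10*max rate], K in (0, 100*max S], n in [0.3, 4]
    (wider Hill coefficients are biologically uninterpretable here).
    ``weights='1/v2'`` enables relative weighting; default is unweighted.
    Raises :class:`HillFitError` instead of reporting a non-converged fit.
    """
    S = np.asarray(curve["conc_uM"], dtype=float)
    v = np.asarray(curve["rate"], dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("need >= 4 distinct concentration levels")
    if not (np.all(np.isfinite(S)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite values in uptake curve")
    if np.any(S < 0):
        raise ValueError("concentrations must be >= 0")

    vmax0 = float(np.max(v))
    if vmax0 <= 0:
        raise ValueError("all rates are <= 0; nothing to fit")
    k0 = _initial_k(S, v)
    sigma = None
    if weights == "1/v2":
        sigma = np.maximum(np.abs(v), 1e-12 * vmax0)
    elif weights is not None:
        raise ValueError(f"unknown weighting {weights!r}")

    if fix_n is not None:
        def model(S_, vmax, k):
            return hill(S_, vmax, k, fix_n)
        lower = [1e-12, 1e-12]
        upper = [bounds_vmax_factor * vmax0, bounds_k_factor * float(np.max(S))]
        starts = [[vmax0, k0]]
    else:
        model = hill
        lower = [1e-12, 1e-12, n_bounds[0]]
        upper = [bounds_vmax_factor * vmax0, bounds_k_factor * float(np.max(S)),
                 n_bounds[1]]
        starts = [[vmax0, k0, n0] for n0 in (1.0, 0.5, 2.0)]

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            popt, pcov = curve_fit(model, S, v, p0=p0, sigma=sigma,
                                   bounds=(lower, upper), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((v - model(S, *popt)) ** 2))
        if not np.all(np.isfinite(pcov)):
            continue
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
        if fix_n is not None:
            break
    if best is None:
        raise HillFitError("Hill fit failed to converge from any start point",
                           best_rss=float("inf"))
    rss, popt, pcov = best
    ses = np.sqrt(np.diag(pcov))
    if fix_n is not None:
        vmax, k = popt
        n = fix_n
        se_vmax, se_k = ses
        se_n = 0.0
        cov_vk = pcov[0, 1]
    else:
        vmax, k, n = popt
        se_vmax, se_k, se_n = ses
        cov_vk = pcov[0, 1]
    # delta method for Vmax/K
    spec_var = ((1.0 / k) ** 2 * se_vmax**2
                + (vmax / k**2) ** 2 * se_k**2
                - 2.0 * (vmax / k**3) * cov_vk)
    return HillFit(vmax=float(vmax), k=float(k), n=float(n),
                   se_vmax=float(se_vmax), se_k=float(se_k), se_n=float(se_n),
                   specificity_se=float(np.sqrt(max(spec_var, 0.0))),
                   converged=True, rss=rss, n_points=len(S), covariance=pcov)


def fit_curves(curves: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (construct, metal) series in a tidy curve table."""
    rows = []
    for (construct, metal), g in curves.groupby(["construct", "metal"],
                                                sort=True):
        fit = fit_hill(g, **kwargs)
        rows.append({
            "construct": construct, "metal": metal,
            "vmax": fit.vmax, "se_vmax": fit.se_vmax,
            "km": fit.k, "se_km": fit.se_k,
            "hill_n": fit.n, "se_hill_n": fit.se_n,
            "vmax_over_km": fit.specificity,
            "se_vmax_over_km": fit.specificity_se,
            "n_points": fit.n_points,
        })
    return pd.DataFrame(rows)


def specificity_fold(fit_a: HillFit, fit_b: HillFit) -> tuple[float, float]:
    """Fold by which fit_b's specificity constant is lower than fit_a's.

    ``fold = (Vmax_a/K_a) / (Vmax_b/K_b)``, with a delta-method SE (NaN when
    the inputs carry no SEs).  ``specificity_fold(a, b) *
    specificity_fold(b, a) == 1``.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    fold = fit_a.specificity / fit_b.specificity
    rel_a = fit_a.specificity_se / fit_a.specificity
    rel_b = fit_b.specificity_se / fit_b.specificity
    se = abs(fold) * float(np.sqrt(rel_a**2 + rel_b**2))
    return float(fold), se


def percent_inhibition(activity_without: float, activity_with: float) -> float:
    """Percent change of tracer transport caused by a competitor.

    ``100 * (with - without) / without``; negative values are inhibition,
    positive values stimulation.  Paired activities must come from the same
    experiment; the baseline must be positive.
    """
    if activity_without <= 0:
        raise ValueError("baseline activity must be positive")
    return 100.0 * (activity_with - activity_without) / activity_without


# ---------------------------------------------------------------------------
# ICP-MS elemental calibration and Mn/P molar ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementCalibration:
    """Linear signal-vs-concentration calibration for one element."""

    element: str
    slope: float          # signal per (ng/mL)
    intercept: float
    r_squared: float

    def to_concentration(self, signal) -> np.ndarray | float:
        conc = (np.asarray(signal, dtype=float) - self.intercept) / self.slope
        return float(conc) if conc.ndim == 0 else conc


def fit_element_calibration(element: str, conc_ng_ml, signal
                            ) -> ElementCalibration:
    """Ordinary least-squares standard curve from a dilution series."""
    x = np.asarray(conc_ng_ml, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise ValueError("standard series must span >= 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope for {element}")
    return ElementCalibration(element=element, slope=float(slope),
                              intercept=float(intercept), r_squared=r2)


@dataclass(frozen=True)
class ElementRatio:
    sample_id: str
    mn_mol: float
    p_mol: float

    @property
    def ratio(self) -> float:
        return self.mn_mol / self.p_mol


def mn_p_ratio(mn_signal: float, p_signal: float,
               mn_calibration: ElementCalibration,
               p_calibration: ElementCalibration,
               *, sample_id: str = "sample") -> ElementRatio:
    """Mn/P molar ratio of one sample from per-element standard curves.

    Each signal is converted to ng/mL via its calibration, then to moles per
    volume using atomic weights; the ratio normalises cellular Mn content to
    phosphorus (a proxy for the amount of cell material).  Phosphorus at or
    below the detection limit is an error.
    """
    mn_ng = mn_calibration.to_concentration(mn_signal)
    p_ng = p_calibration.to_concentration(p_signal)
    if p_ng <= 0:
        raise ValueError("phosphorus below detection; ratio undefined")
    if mn_ng < 0:
        warnings.warn("Mn below calibration zero; clamped to 0", stacklevel=2)
        mn_ng = 0.0
    mn_mol = mn_ng / ATOMIC_WEIGHTS["Mn"]
    p_mol = p_ng / ATOMIC_WEIGHTS["P"]
    return ElementRatio(sample_id=sample_id, mn_mol=mn_mol, p_mol=p_mol)
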