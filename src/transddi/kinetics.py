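"""Michaelis-Menten and 4/5-parameter-logistic fitting; Cheng-Prusoff Ki.

Km/Vmax are estimated by nonlinear least squares on corrected uptake rates
v = Vmax*S/(Km+S).  Inhibition dose-response curves are fitted on percent-
(vehicle)-control activity against log10 inhibitor concentration with either
the symmetric four-parameter logistic

    y = bottom + (top-bottom) / (1 + (x/xmid)^hill)

or its asymmetric five-parameter (Richards) extension with exponent ``s``.
The IC50 is the concentration where the fitted curve crosses
(top+bottom)/2 — equal to xmid for the 4PL, back-computed from the curve for
the 5PL.  With the probe substrate far below Km and competitive inhibition,
Ki = IC50 / (1 + S/Km) ~= IC50 (Cheng-Prusoff).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import uptake as _uptake
from .uptake import SpecificActivity, WellRecord

__all__ = [
    "KineticFit",
    "InhibitionResult",
    "ChengPrusoff",
    "FitError",
    "fit_michaelis_menten",
    "percent_control",
    "fit_logistic",
    "cheng_prusoff_ki",
    "aggregate_occasions",
    "fit_kinetics_from_wells",
    "fit_inhibition_from_wells",
]


class FitError(RuntimeError):
    """Nonlinear fit failed; carries diagnostics in ``args``."""


@dataclass(frozen=True)
class KineticFit:
    km: float  # umol/L
    vmax: float  # pmol/min/mg
    km_se: float
    vmax_se: float
    converged: bool = True
    warnings: tuple[str, ...] = ()

    def rate(self, s: float) -> float:
        return self.vmax * s / (self.km + s)


@dataclass(frozen=True)
class InhibitionResult:
    inhibitor: str
    transporter: str
    ic50: float | None  # umol/L; None when censored
    model: str  # "4PL" | "5PL"
    hill: float
    bottom: float
    top: float
    asymmetry: float  # 1.0 for 4PL
    probe_conc: float | None = None
    per_occasion_ic50s: tuple[float, ...] = ()
    ic50_mean: float | None = None
    ic50_sd: float | None = None
    ki: float | None = None
    ic50_equals_ki: bool | None = None
    censored_above: float | None = None  # max tested conc when no inhibition seen


@dataclass(frozen=True)
class ChengPrusoff:
    ki: float
    ic50_equals_ki: bool  # probe S <= Km/10, so IC50 may stand in for Ki


# default fit bounds; stabilize fits on partial curves and are configurable
LOGISTIC_BOUNDS = {
    "bottom": (-20.0, 50.0),
    "top": (50.0, 150.0),
    "hill": (1e-3, 10.0),
    "asymmetry": (0.2, 5.0),
}

#: percent-control floor above which a curve is deemed uninformative
NO_INHIBITION_FLOOR = 80.0


def fit_michaelis_menten(
    concs: Sequence[float], corrected_rates: Sequence[float]
) -> KineticFit:
    """Least-squares Km/Vmax with asymptotic standard errors.

    Warns (without failing) when fewer than 4 distinct concentrations are
    supplied or the design does not bracket the Km estimate; flags the fit
    when Km is unidentifiable (all concentrations saturating).
    """
    s = np.asarray(concs, dtype=float)
    v = np.asarray(corrected_rates, dtype=float)
    if s.shape != v.shape or s.size < 2:
        raise ValueError("need >= 2 paired (conc, rate) points")
    if np.any(s <= 0):
        raise ValueError("concentrations must be positive")
    warns: list[str] = []
    if np.unique(s).size < 4:
        warns.append("fewer than 4 distinct concentrations; Km poorly constrained")

    def mm(x, vmax, km):
        return vmax * x / (km + x)

    p0 = (float(v.max()) * 1.2 if v.max() > 0 else 1.0, float(np.median(s)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                mm, s, v, p0=p0, bounds=([0, 0], [np.inf, np.inf]), maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    vmax_se, km_se = float(se[0]), float(se[1])
    if not (s.min() < km < s.max()):
        warns.append("design does not bracket the Km estimate")
    if not np.isfinite(km_se) or (km > 0 and km_se / km > 1.0):
        warns.append("Km unidentifiable at this design (saturating or flat rates)")
    if km <= 0 or vmax <= 0:
        raise FitError(f"non-physical fit: km={km}, vmax={vmax}")
    return KineticFit(
        km=km,
        vmax=vmax,
        km_se=km_se,
        vmax_se=vmax_se,
        converged=True,
        warnings=tuple(warns),
    )


def percent_control(corrected_inhibited: float, corrected_vehicle: float) -> float:
    """Corrected activity as percent of the vehicle (zero-inhibitor) control."""
    if corrected_vehicle <= 0:
        raise ValueError("vehicle corrected activity must be positive")
    return 100.0 * corrected_inhibited / corrected_vehicle


def _pl_curve(logx: np.ndarray, bottom: float, top: float, logxmid: float, hill: float, asym: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logxmid))) ** asym


def _ic50_from_params(logxmid: float, hill: float, asym: float) -> float:
    """Concentration where the curve crosses (top+bottom)/2."""
    xmid = 10.0**logxmid
    return xmid * (2.0 ** (1.0 / asym) - 1.0) ** (1.0 / hill)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_logistic(
    inhibitor_concs: Sequence[float],
    percent_controls: Sequence[float],
    model: str = "auto",
    inhibitor: str = "",
    transporter: str = "",
    probe_conc: float | None = None,
    bounds: dict | None = None,
) -> InhibitionResult:
    """Fit a 4PL or 5PL inhibition curve on log10 concentration.

    Vehicle (zero-concentration) points anchor the top plateau initialization
    but are excluded from the log-concentration axis.  ``model="auto"``
    selects 4PL vs 5PL by corrected AIC.  When no point falls below 80%
    control the IC50 is right-censored at the highest tested concentration.
    """
    if model not in ("4PL", "5PL", "auto"):
        raise ValueError("model must be '4PL', '5PL' or 'auto'")
    b = {**LOGISTIC_BOUNDS, **(bounds or {})}
    x = np.asarray(inhibitor_concs, dtype=float)
    y = np.asarray(percent_controls, dtype=float)
    if x.shape != y.shape:
        raise ValueError("concs and percents must pair up")
    if not np.all(np.isfinite(y)):
        raise ValueError("percent values must be finite")
    vehicle_mask = x == 0
    top_anchor = float(y[vehicle_mask].mean()) if vehicle_mask.any() else float(y[np.argmin(x)])
    x, y = x[~vehicle_mask], y[~vehicle_mask]
    if np.unique(x).size < 5:
        warnings.warn("fewer than 5 inhibitor concentrations; logistic fit may be unstable")
    if np.any(x <= 0):
        raise ValueError("non-vehicle inhibitor concentrations must be positive")
    logx = np.log10(x)

    if y.min() > NO_INHIBITION_FLOOR:
        return InhibitionResult(
            inhibitor=inhibitor,
            transporter=transporter,
            ic50=None,
            model="4PL",
            hill=float("nan"),
            bottom=float("nan"),
            top=top_anchor,
            asymmetry=1.0,
            probe_conc=probe_conc,
            censored_above=float(x.max()),
        )

    # initialization: plateaus from extremes, xmid from the 50% crossing
    top0 = float(np.clip(top_anchor, *b["top"]))
    bottom0 = float(np.clip(y.min(), *b["bottom"]))
    half = (top0 + bottom0) / 2.0
    order = np.argsort(logx)
    ylo = y[order]
    cross = np.nonzero(ylo <= half)[0]
    logxmid0 = float(logx[order][cross[0]]) if cross.size else float(np.median(logx))

    def _fit(asym_free: bool):
        if asym_free:
            f = _pl_curve
            p0 = [bottom0, top0, logxmid0, 1.0, 1.0]
            lb = [b["bottom"][0], b["top"][0], logx.min() - 2, b["hill"][0], b["asymmetry"][0]]
            ub = [b["bottom"][1], b["top"][1], logx.max() + 2, b["hill"][1], b["asymmetry"][1]]
        else:
            f = lambda lx, bo, to, lm, hi: _pl_curve(lx, bo, to, lm, hi, 1.0)
            p0 = [bottom0, top0, logxmid0, 1.0]
            lb = [b["bottom"][0], b["top"][0], logx.min() - 2, b["hill"][0]]
            ub = [b["bottom"][1], b["top"][1], logx.max() + 2, b["hill"][1]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(f, logx, y, p0=p0, bounds=(lb, ub), maxfev=50000)
        rss = float(np.sum((f(logx, *popt) - y) ** 2))
        return popt, rss

    try:
        fits = {}
        if model in ("4PL", "auto"):
            fits["4PL"] = _fit(asym_free=False)
        if model in ("5PL", "auto"):
            fits["5PL"] = _fit(asym_free=True)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc

    if model == "auto":
        n = y.size
        scores = {m: _aicc(rss, n, len(popt)) for m, (popt, rss) in fits.items()}
        chosen = min(scores, key=scores.get)
    else:
        chosen = model
    popt, _rss = fits[chosen]
    if chosen == "5PL":
        bottom, top, logxmid, hill, asym = (float(p) for p in popt)
    else:
        bottom, top, logxmid, hill = (float(p) for p in popt)
        asym = 1.0
    ic50 = _ic50_from_params(logxmid, hill, asym)
    return InhibitionResult(
        inhibitor=inhibitor,
        transporter=transporter,
        ic50=ic50,
        model=chosen,
        hill=hill,
        bottom=bottom,
        top=top,
        asymmetry=asym,
        probe_conc=probe_conc,
        per_occasion_ic50s=(ic50,),
        ic50_mean=ic50,
        ic50_sd=None,
    )


def cheng_prusoff_ki(ic50: float, probe_conc: float, km: float) -> ChengPrusoff:
    """Competitive-inhibition Ki from an IC50: Ki = IC50 / (1 + S/Km).

    ``ic50_equals_ki`` reports whether the probe concentration satisfies the
    S <= Km/10 condition under which the IC50 may be read directly as Ki.
    """
    if km <= 0:
        raise ValueError("km must be positive")
    if ic50 <= 0 or probe_conc < 0:
        raise ValueError("ic50 must be positive and probe_conc non-negative")
    ki = ic50 / (1.0 + probe_conc / km)
    return ChengPrusoff(ki=ki, ic50_equals_ki=probe_conc <= km / 10.0)


def aggregate_occasions(per_occasion: Sequence[InhibitionResult]) -> InhibitionResult:
    """Arithmetic mean +/- SD of per-occasion IC50s (SD is None for a single
    occasion).  All occasions must share inhibitor and transporter."""
    if not per_occasion:
        raise ValueError("need >= 1 occasion")
    keys = {(r.inhibitor, r.transporter) for r in per_occasion}
    if len(keys) > 1:
        raise ValueError(f"mixed inhibitor/transporter conditions: {keys}")
    ic50s = [r.ic50 for r in per_occasion if r.ic50 is not None]
    if not ic50s:
        return replace(per_occasion[0], per_occasion_ic50s=(), ic50_mean=None, ic50_sd=None)
    mean = float(np.mean(ic50s))
    sd = float(np.std(ic50s, ddof=1)) if len(ic50s) > 1 else None
    return replace(
        per_occasion[0],
        ic50=mean,
        per_occasion_ic50s=tuple(ic50s),
        ic50_mean=mean,
        ic50_sd=sd,
    )


# ---------------------------------------------------------------------------
# wiring from well tables


def fit_kinetics_from_wells(
    wells: Sequence[WellRecord], sa: SpecificActivity
) -> KineticFit:
    """Km plate end-to-end: summarize, control-correct, fit corrected rates."""
    summary = _uptake.summarize_activities(wells, sa)
    corrected = _uptake.correct_activities(summary)
    return fit_michaelis_menten(
        corrected["probe_conc"].to_numpy(), corrected["corrected_rate"].to_numpy()
    )


def fit_inhibition_from_wells(
    wells: Sequence[WellRecord],
    sa: SpecificActivity,
    km: float | None = None,
    model: str = "auto",
) -> InhibitionResult:
    """Inhibition plate end-to-end: per occasion, convert corrected activity
    to percent vehicle control, fit the logistic, then aggregate occasions.
    Attaches Ki via Cheng-Prusoff when ``km`` is given."""
    summary = _uptake.summarize_activities(wells, sa)
    corrected = _uptake.correct_activities(summary)
    inhibitors = corrected["inhibitor"].dropna().unique()
    if len(inhibitors) != 1:
        raise ValueError(f"expected exactly one inhibitor on the plate, got {inhibitors}")
    inhibitor = inhibitors[0]
    transporter = wells[0].transporter
    probe_conc = wells[0].probe_conc
    per_occ: list[InhibitionResult] = []
    for occ, grp in corrected.groupby("occasion"):
        vehicle = grp.loc[grp["inhibitor_conc"] == 0, "corrected"]
        if vehicle.empty:
            raise ValueError(f"occasion {occ} has no vehicle (zero-inhibitor) wells")
        v0 = float(vehicle.mean())
        pct = [percent_control(c, v0) for c in grp["corrected"]]
        per_occ.append(
            fit_logistic(
                grp["inhibitor_conc"].to_numpy(),
                np.asarray(pct),
                model=model,
                inhibitor=inhibitor,
                transporter=transporter,
                probe_conc=probe_conc,
            )
        )
    result = aggregate_occasions(per_occ)
    if km is not None and result.ic50 is not None:
        cp = cheng_prusoff_ki(result.ic50, probe_conc, km)
        result = replace(result, ki=cp.ki, ic50_equals_ki=cp.ic50_equals_ki)
    return result
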