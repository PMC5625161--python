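"""Mechanistic static prediction of victim-drug AUC change from renal
transporter inhibition.

The engine implements the adapted Rowland-Matin static model.  A victim drug
whose clearance is fraction ``fe`` attributable to an inhibitable active
renal pathway, exposed to a perpetrator at unbound systemic concentration
[I] against a transporter with inhibition constant Ki, has a predicted
exposure change of

    fold-dAUC = 1 / ( fe / (1 + [I]/Ki) + (1 - fe) )

which runs from 1 (no inhibitor) to the supremum 1/(1-fe) at complete
pathway shutdown.  For metformin, fe = 0.88 x 0.75 = 0.66 from intravenous
mass balance, or 0.52 x 0.75 = 0.39 when renal clearance is taken from oral
mass-balance data (the drug's flip-flop kinetics reduce the apparent renal
contribution after oral dosing).

Screening ratios follow regulatory static practice: systemic risk when
unbound Cmax/Ki >= 0.1, intestinal risk when [I2]/Ki >= 10 with [I2] the
theoretical luminal concentration, dose in moles per 250 mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Perpetrator",
    "VictimDisposition",
    "StaticPrediction",
    "ObservedDDI",
    "PredictionSet",
    "SYSTEMIC_CUTOFF",
    "GUT_CUTOFF",
    "derive_fe",
    "cmax_free",
    "i2_gut",
    "ratio_screen",
    "fold_auc",
    "predict_all",
    "compare_to_observed",
    "concordance_range",
    "round_sig",
]

SYSTEMIC_CUTOFF = 0.1  # unbound Cmax / Ki
GUT_CUTOFF = 10.0  # [I2] / Ki


@dataclass(frozen=True)
class Perpetrator:
    """Inhibitor drug with the clinical exposure parameters the static model
    consumes.  ``igut_max`` (theoretical enterocyte concentration) is only
    ever a supplied constant."""

    name: str
    dose_mg: float
    mw: float  # g/mol
    fu: float  # fraction unbound
    cmax_total: tuple[float, ...]  # umol/L, one or more clinical values
    igut_max: float | None = None  # umol/L

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be non-negative")
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")
        object.__setattr__(self, "cmax_total", tuple(self.cmax_total))


@dataclass(frozen=True)
class VictimDisposition:
    """Victim-drug renal disposition and the derived fraction excreted."""

    renal_fraction_of_total_clearance: float
    active_fraction_of_renal_clearance: float
    route_label: str  # "iv" | "oral"
    fe: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fe",
            derive_fe(
                self.renal_fraction_of_total_clearance,
                self.active_fraction_of_renal_clearance,
            ),
        )


@dataclass(frozen=True)
class StaticPrediction:
    perpetrator: str
    transporter: str
    ki: float  # umol/L
    cmax_total: float  # umol/L
    i_unbound: float  # umol/L, [I] = Cmax * fu
    ratio_systemic: float  # [I]/Ki
    flag_systemic: bool  # ratio >= systemic cutoff
    fe_used: float
    route_label: str
    fold_auc: float  # full precision
    i2: float | None = None  # umol/L
    ratio_gut: float | None = None
    flag_gut: bool | None = None

    @property
    def fold_auc_reported(self) -> float:
        return round(self.fold_auc, 2)


@dataclass(frozen=True)
class ObservedDDI:
    """One clinical interaction study's observed AUC fold-change, keyed for
    pairing by perpetrator and the total Cmax measured in that study."""

    perpetrator: str
    cmax_total: float  # umol/L; pairs the study with a prediction row
    observed_fold_auc: float
    victim_dose_mg: float | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.observed_fold_auc <= 0:
            raise ValueError("observed_fold_auc must be positive")


@dataclass
class PredictionSet:
    predictions: list[StaticPrediction]
    errors: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            rows.append(
                {
                    "perpetrator": p.perpetrator,
                    "transporter": p.transporter,
                    "fe": p.fe_used,
                    "route": p.route_label,
                    "cmax_total": p.cmax_total,
                    "i_unbound": p.i_unbound,
                    "ki": p.ki,
                    "ratio_systemic": p.ratio_systemic,
                    "flag_systemic": p.flag_systemic,
                    "fold_auc": p.fold_auc,
                    "fold_auc_reported": p.fold_auc_reported,
                }
            )
        return pd.DataFrame(rows)


def derive_fe(renal_fraction: float, active_fraction: float) -> float:
    """Fraction excreted via the inhibitable pathway: the renal fraction of
    total clearance times the active (transporter-mediated) fraction of renal
    clearance, reported at 2 d.p."""
    for f in (renal_fraction, active_fraction):
        if not 0 <= f <= 1:
            raise ValueError("fractions must be in [0, 1]")
    return round(renal_fraction * active_fraction, 2)


def cmax_free(cmax_total: float, fu: float) -> float:
    """Unbound systemic concentration [I] = Cmax,total * fu."""
    if cmax_total < 0:
        raise ValueError("cmax_total must be non-negative")
    return cmax_total * fu


def i2_gut(dose_mg: float, mw: float, volume_ml: float = 250.0) -> float:
    """Theoretical intestinal luminal concentration [I2] in umol/L:
    dose in moles dissolved in 250 mL.  Full precision; reporting rounds to
    the nearest integer."""
    if mw <= 0:
        raise ValueError("mw must be positive")
    if dose_mg < 0 or volume_ml <= 0:
        raise ValueError("dose and volume must be non-negative/positive")
    mmol = dose_mg / mw
    return mmol / (volume_ml / 1000.0) * 1000.0  # umol/L


def ratio_screen(i: float, ki: float, cutoff: float) -> tuple[float, bool]:
    """Exposure ratio against a regulatory cutoff; flag True when at risk."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    if i < 0:
        raise ValueError("concentration must be non-negative")
    ratio = i / ki
    return ratio, ratio >= cutoff


def fold_auc(fe: float, i: float, ki: float) -> float:
    """Static-model predicted AUC fold-change (full precision).

    Monotone non-decreasing in both ``i`` and ``fe``; equals 1 at i=0 and
    approaches 1/(1-fe) as i -> inf.
    """
    if not 0 <= fe <= 1:
        raise ValueError("fe must be in [0, 1]")
    if i < 0:
        raise ValueError("i must be non-negative")
    if ki <= 0:
        raise ValueError("ki must be positive")
    return 1.0 / (fe / (1.0 + i / ki) + (1.0 - fe))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention for
    systemic ratios)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def predict_all(
    perpetrators: Sequence[Perpetrator],
    ki_table: Mapping[tuple[str, str], float],
    dispositions: Sequence[VictimDisposition],
    transporters: Sequence[str] = ("OCT2", "MATE1"),
    systemic_cutoff: float = SYSTEMIC_CUTOFF,
    gut_cutoff: float = GUT_CUTOFF,
) -> PredictionSet:
    """Cross-product of perpetrator x clinical Cmax x transporter x fe
    scenario.  ``ki_table`` maps (perpetrator name, transporter) to Ki in
    umol/L.  A missing Ki yields a recorded error for that combination; all
    other rows are still produced."""
    preds: list[StaticPrediction] = []
    errors: list[str] = []
    for perp in perpetrators:
        i2 = i2_gut(perp.dose_mg, perp.mw) if perp.dose_mg and perp.mw else None
        for transporter in transporters:
            ki = ki_table.get((perp.name, transporter))
            if ki is None:
                errors.append(f"no Ki for ({perp.name}, {transporter})")
                continue
            ratio_g, flag_g = (None, None)
            if i2 is not None:
                ratio_g, flag_g = ratio_screen(i2, ki, gut_cutoff)
            for cmax in perp.cmax_total:
                i_u = cmax_free(cmax, perp.fu)
                ratio_s, flag_s = ratio_screen(i_u, ki, systemic_cutoff)
                for disp in dispositions:
                    preds.append(
                        StaticPrediction(
                            perpetrator=perp.name,
                            transporter=transporter,
                            ki=ki,
                            cmax_total=cmax,
                            i_unbound=i_u,
                            ratio_systemic=ratio_s,
                            flag_systemic=flag_s,
                            fe_used=disp.fe,
                            route_label=disp.route_label,
                            fold_auc=fold_auc(disp.fe, i_u, ki),
                            i2=i2,
                            ratio_gut=ratio_g,
                            flag_gut=flag_g,
                        )
                    )
    return PredictionSet(predictions=preds, errors=errors)


def compare_to_observed(
    predictions: Iterable[StaticPrediction],
    observed: Iterable[ObservedDDI],
    metric: str = "percent_point_diff",
) -> pd.DataFrame:
    """Pair predictions with clinical observations and score concordance.

    Pairing is on (perpetrator, total Cmax).  The default metric is the
    absolute difference in percent AUC increase,
    |100*(pred-1) - 100*(obs-1)|, in percentage points; predictions and
    observations enter at their reported 2-d.p. precision.  The alternate
    ``metric="relative_fold_error"`` reports 100*|pred-obs|/obs.  Unmatched
    predictions are flagged (``matched`` False) and excluded from ranges.
    """
    if metric not in ("percent_point_diff", "relative_fold_error"):
        raise ValueError("unknown metric")
    obs_by_key = {(o.perpetrator, o.cmax_total): o for o in observed}
    rows = []
    for p in predictions:
        o = obs_by_key.get((p.perpetrator, p.cmax_total))
        pred = p.fold_auc_reported
        row = {
            "perpetrator": p.perpetrator,
            "transporter": p.transporter,
            "fe": p.fe_used,
            "cmax_total": p.cmax_total,
            "predicted": pred,
            "observed": o.observed_fold_auc if o else None,
            "matched": o is not None,
        }
        if o is not None:
            if metric == "percent_point_diff":
                row["delta"] = abs(100.0 * (pred - 1.0) - 100.0 * (o.observed_fold_auc - 1.0))
            else:
                row["delta"] = 100.0 * abs(pred - o.observed_fold_auc) / o.observed_fold_auc
        else:
            row["delta"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def concordance_range(comparison: pd.DataFrame) -> dict[float, tuple[float, float]]:
    """Min-max concordance delta per fe scenario over matched pairs."""
    out: dict[float, tuple[float, float]] = {}
    matched = comparison[comparison["matched"]]
    for fe, grp in matched.groupby("fe"):
        deltas = grp["delta"].astype(float)
        out[float(fe)] = (float(deltas.min()), float(deltas.max()))
    return out
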