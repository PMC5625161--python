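"""Caco-2 transwell permeability: Papp, mass balance, monolayer integrity.

Apparent permeability of a compound across a polarized cell monolayer is
computed from a single end-point receiver sample as

    Papp = (dQ/dt) / (A * C0)   [cm/s]

with dQ/dt the receiver amount divided by incubation time, A the insert
surface area and C0 the donor concentration.  Monolayer integrity is judged
per well from the paracellular marker lucifer yellow: a well passes when the
lucifer-yellow Papp is <= 1.0e-6 cm/s (boundary inclusive).  Failing wells
are excluded from every aggregate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TranswellRecord",
    "PermeabilityResult",
    "EffectSummary",
    "LY_PAPP_THRESHOLD",
    "apparent_permeability",
    "mass_balance",
    "integrity_gate",
    "ly_papp",
    "efflux_ratio",
    "summarize_transwells",
    "inhibitor_effect_test",
]

#: lucifer-yellow Papp acceptance threshold, cm/s (inclusive)
LY_PAPP_THRESHOLD = 1.0e-6

#: warn when receiver concentration exceeds this fraction of donor C0
SINK_WARNING_FRACTION = 0.10

#: "no change" equivalence band on the fold-change, by analogy with the
#: 0.8-1.25 bioequivalence bounds used for AUC ratios
EQUIVALENCE_BAND = (0.8, 1.25)


@dataclass(frozen=True)
class TranswellRecord:
    """One transwell's end-point measurements."""

    well_id: str
    direction: str  # "AB" (apical->basolateral) | "BA"
    c0: float  # donor concentration, umol/L
    donor_volume: float  # uL
    receiver_volume: float  # uL
    area: float  # cm^2
    duration: float  # s
    receiver_amount: float  # pmol (whole receiver compartment)
    donor_amount_end: float | None = None  # pmol
    ly_receiver_amount: float | None = None  # pmol lucifer yellow in receiver
    ly_c0: float = 100.0  # umol/L lucifer yellow donor concentration
    inhibitor: str | None = None
    matrix: str = "buffer"  # "buffer" | "fassif_hsa"

    def __post_init__(self) -> None:
        if self.direction not in ("AB", "BA"):
            raise ValueError("direction must be 'AB' or 'BA'")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.area <= 0 or self.duration <= 0:
            raise ValueError("area and duration must be positive")
        if self.receiver_amount < 0:
            raise ValueError("receiver_amount must be non-negative")


@dataclass(frozen=True)
class PermeabilityResult:
    """Aggregated directional permeability for one condition."""

    direction: str
    c0: float
    inhibitor: str | None
    matrix: str
    papp: float  # cm/s, mean over integrity-passing wells
    sd: float | None
    n_wells: int
    mass_balance_pct: float | None
    integrity_pass: bool
    efflux_ratio: float | None = None


@dataclass(frozen=True)
class EffectSummary:
    """Two-arm comparison of absorptive Papp with vs without inhibitor."""

    fold_change: float
    ci_low: float
    ci_high: float
    p_value: float | None
    verdict: str  # "no_change" | "change" | "inconclusive"
    n_with: int
    n_without: int


def apparent_permeability(rec: TranswellRecord, warn_sink: bool = True) -> float:
    """End-point apparent permeability in cm/s.

    C0 in umol/L is converted to pmol/cm^3 (x1000) so that
    pmol / (s * cm^2 * pmol/cm^3) = cm/s.  Warns when the end-of-assay
    receiver concentration exceeds 10% of donor C0 (sink assumption strained).
    """
    papp = rec.receiver_amount / (rec.duration * rec.area * rec.c0 * 1000.0)
    if warn_sink and rec.receiver_volume > 0:
        receiver_conc = rec.receiver_amount / rec.receiver_volume  # pmol/uL == umol/L
        if receiver_conc > SINK_WARNING_FRACTION * rec.c0:
            warnings.warn(
                f"well {rec.well_id}: receiver concentration exceeds "
                f"{SINK_WARNING_FRACTION:.0%} of donor C0; sink conditions violated",
                stacklevel=2,
            )
    return papp


def mass_balance(rec: TranswellRecord, initial_donor_amount: float) -> float | None:
    """Percent recovery: (receiver + donor-end) / initial donor amount.

    Returns None when no end-of-assay donor sample exists.
    """
    if initial_donor_amount <= 0:
        raise ValueError("initial_donor_amount must be positive")
    if rec.donor_amount_end is None:
        return None
    return 100.0 * (rec.receiver_amount + rec.donor_amount_end) / initial_donor_amount


def integrity_gate(ly_papp_value: float, threshold: float = LY_PAPP_THRESHOLD) -> bool:
    """Monolayer acceptable iff lucifer-yellow Papp <= threshold (inclusive)."""
    if ly_papp_value < 0:
        raise ValueError("ly_papp must be non-negative")
    return ly_papp_value <= threshold


def ly_papp(rec: TranswellRecord) -> float | None:
    """Lucifer-yellow Papp of a well, or None if the LY channel is absent."""
    if rec.ly_receiver_amount is None:
        return None
    return rec.ly_receiver_amount / (rec.duration * rec.area * rec.ly_c0 * 1000.0)


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """B->A over A->B permeability; >1 suggests net efflux."""
    if papp_ab <= 0:
        raise ZeroDivisionError("efflux ratio undefined for non-positive A->B Papp")
    return papp_ba / papp_ab


def summarize_transwells(
    records: Iterable[TranswellRecord],
    ly_threshold: float = LY_PAPP_THRESHOLD,
) -> list[PermeabilityResult]:
    """Per-condition (direction, C0, inhibitor, matrix) mean Papp over
    integrity-passing wells, with SD, mean recovery, and the efflux ratio
    attached to each A->B result when the paired B->A condition exists.

    Wells without a lucifer-yellow channel are treated as passing.
    """
    rows = []
    for rec in records:
        lp = ly_papp(rec)
        ok = True if lp is None else integrity_gate(lp, ly_threshold)
        mb = None
        if rec.donor_amount_end is not None:
            mb = mass_balance(rec, rec.c0 * rec.donor_volume)
        rows.append(
            {
                "direction": rec.direction,
                "c0": rec.c0,
                "inhibitor": rec.inhibitor,
                "matrix": rec.matrix,
                "papp": apparent_permeability(rec, warn_sink=False),
                "mass_balance": mb,
                "integrity": ok,
            }
        )
    df = pd.DataFrame(rows)
    results: list[PermeabilityResult] = []
    for (direction, c0, inhibitor, matrix), grp in df.groupby(
        ["direction", "c0", "inhibitor", "matrix"], dropna=False
    ):
        inhibitor = None if pd.isna(inhibitor) else inhibitor
        passing = grp[grp["integrity"]]
        if passing.empty:
            results.append(
                PermeabilityResult(
                    direction=direction,
                    c0=c0,
                    inhibitor=inhibitor,
                    matrix=matrix,
                    papp=float("nan"),
                    sd=None,
                    n_wells=0,
                    mass_balance_pct=None,
                    integrity_pass=False,
                )
            )
            continue
        mb_vals = passing["mass_balance"].dropna()
        results.append(
            PermeabilityResult(
                direction=direction,
                c0=c0,
                inhibitor=inhibitor,
                matrix=matrix,
                papp=float(passing["papp"].mean()),
                sd=float(passing["papp"].std()) if len(passing) > 1 else None,
                n_wells=int(len(passing)),
                mass_balance_pct=float(mb_vals.mean()) if not mb_vals.empty else None,
                integrity_pass=True,
            )
        )
    # attach efflux ratios to A->B rows with a matching B->A condition
    by_key = {(r.direction, r.c0, r.inhibitor, r.matrix): r for r in results}
    out = []
    for r in results:
        er = None
        if r.direction == "AB" and r.n_wells > 0:
            mate = by_key.get(("BA", r.c0, r.inhibitor, r.matrix))
            if mate is not None and mate.n_wells > 0 and r.papp > 0:
                er = efflux_ratio(mate.papp, r.papp)
        out.append(
            PermeabilityResult(**{**asdict(r), "efflux_ratio": er})
            if er is not None
            else r
        )
    return out


def inhibitor_effect_test(
    papp_with: Sequence[float],
    papp_without: Sequence[float],
    equivalence_band: tuple[float, float] = EQUIVALENCE_BAND,
    confidence: float = 0.90,
) -> EffectSummary:
    """Compare absorptive Papp between inhibitor-present and control arms.

    Works on log-permeability: the fold-change is the ratio of geometric
    means, its CI a Welch t-interval on the log scale.  Verdicts:
    "no_change" when the CI lies inside the equivalence band (default
    0.8-1.25 fold), "change" when it excludes 1, else "inconclusive".
    """
    a = np.asarray(papp_with, dtype=float)
    b = np.asarray(papp_without, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 integrity-passing wells per arm")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("Papp values must be positive")
    la, lb = np.log(a), np.log(b)
    diff = la.mean() - lb.mean()
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    se = math.sqrt(va / a.size + vb / b.size)
    fold = math.exp(diff)
    if se == 0:  # identical arms / zero variance
        lo = hi = fold
        p = None
    else:
        dof = (va / a.size + vb / b.size) ** 2 / (
            (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
        )
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, dof)
        lo, hi = math.exp(diff - tcrit * se), math.exp(diff + tcrit * se)
        p = float(2.0 * stats.t.sf(abs(diff) / se, dof))
    band_lo, band_hi = equivalence_band
    if band_lo <= lo and hi <= band_hi:
        verdict = "no_change"
    elif hi < 1.0 or lo > 1.0:
        verdict = "change"
    else:
        verdict = "inconclusive"
    return EffectSummary(
        fold_change=fold,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        verdict=verdict,
        n_with=int(a.size),
        n_without=int(b.size),
    )
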