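"""Raw well measurements → normalized uptake activities and rates.

A transporter uptake assay measures radiolabelled probe substrate
(here [14C]-metformin) accumulated by transporter-transfected cells and by
mock-transfected vector-control cells.  Scintillation counts (dpm) are
converted to pmol via the specific activity of the dosing solution, scaled
back from the counted lysate aliquot to the whole lysate, normalized to the
protein content of each well (pmol/mg), and optionally to incubation time
(pmol/min/mg).  Transporter-mediated signal is the transporter-cell mean
minus the matched vector-control mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRecord",
    "SpecificActivity",
    "UptakeActivity",
    "LinearityAssessment",
    "dpm_to_pmol",
    "activity",
    "control_correct",
    "uptake_ratio",
    "assess_linearity",
    "summarize_activities",
    "correct_activities",
    "wells_to_frame",
    "frame_to_wells",
    "read_wells_csv",
    "write_wells_csv",
]

#: lysate volume counted / total lysate volume (300 of 400 uL)
DEFAULT_LYSATE_FRACTION = 300.0 / 400.0

CELL_LINES = ("transporter", "vector_control")

#: columns of the flat well-table CSV dialect shared with synthetic generators
WELL_COLUMNS = [
    "well_id",
    "cell_line",
    "transporter",
    "probe_conc",
    "inhibitor",
    "inhibitor_conc",
    "time",
    "dpm",
    "protein",
    "lysate_fraction_counted",
    "occasion",
]

# keys that define a matched experimental condition (correction pairs
# transporter vs control wells sharing these)
CONDITION_KEYS = ["transporter", "probe_conc", "inhibitor", "inhibitor_conc", "time", "occasion"]


@dataclass(frozen=True)
class SpecificActivity:
    """Radioactivity per amount of probe in the dosing solution."""

    dpm_per_pmol: float

    def __post_init__(self) -> None:
        if not self.dpm_per_pmol > 0:
            raise ValueError("specific activity must be positive")

    @classmethod
    def from_solution(cls, kbq_per_ml: float, conc_umol_per_l: float) -> "SpecificActivity":
        """Specific activity of a dosing solution of known radioactivity
        concentration and chemical concentration.

        1 Bq = 60 dpm; ``conc`` umol/L = ``conc`` * 1000 pmol/mL.  A solution
        of 37 kBq/mL at 100 umol/L gives 22.2 dpm/pmol.
        """
        if kbq_per_ml <= 0 or conc_umol_per_l <= 0:
            raise ValueError("solution parameters must be positive")
        dpm_per_ml = kbq_per_ml * 1000.0 * 60.0
        pmol_per_ml = conc_umol_per_l * 1000.0
        return cls(dpm_per_ml / pmol_per_ml)


@dataclass(frozen=True)
class WellRecord:
    """One assay well's raw measurements."""

    well_id: str
    cell_line: str  # "transporter" | "vector_control"
    transporter: str  # OCT1 | OCT2 | MATE1 | MATE2-K
    probe_conc: float  # umol/L
    time: float  # min
    dpm: float
    protein: float  # mg
    inhibitor: str | None = None
    inhibitor_conc: float | None = None  # umol/L; 0 = vehicle
    lysate_fraction_counted: float = DEFAULT_LYSATE_FRACTION
    occasion: int = 1

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(f"cell_line must be one of {CELL_LINES}")
        if self.dpm < 0:
            raise ValueError("dpm must be non-negative")
        if self.protein <= 0:
            raise ValueError("protein must be positive")
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.probe_conc <= 0:
            raise ValueError("probe_conc must be positive")
        if not 0 < self.lysate_fraction_counted <= 1:
            raise ValueError("lysate_fraction_counted must be in (0, 1]")
        if self.inhibitor_conc is not None and self.inhibitor_conc < 0:
            raise ValueError("inhibitor_conc must be non-negative")


@dataclass(frozen=True)
class UptakeActivity:
    """Protein-normalized uptake (pmol/mg) for one condition and cell line."""

    pmol_per_mg: float
    cell_line: str
    transporter: str
    probe_conc: float
    time: float
    inhibitor: str | None = None
    inhibitor_conc: float | None = None
    occasion: int = 1
    sd: float | None = None
    n: int = 1

    def condition_key(self) -> tuple:
        return (
            self.transporter,
            self.probe_conc,
            self.inhibitor,
            self.inhibitor_conc,
            self.time,
            self.occasion,
        )


@dataclass(frozen=True)
class LinearityAssessment:
    linear_window: tuple[float, float]
    chosen_time: float
    r_squared: float
    uptake_ratio_at_chosen_time: float | None = None


def dpm_to_pmol(dpm: float, sa: SpecificActivity, lysate_fraction_counted: float = 1.0) -> float:
    """Convert counted dpm to pmol in the whole lysate.

    The counted aliquot holds only ``lysate_fraction_counted`` of the lysate,
    so the amount is scaled back up by that fraction.
    """
    if dpm < 0:
        raise ValueError("dpm must be non-negative")
    if not 0 < lysate_fraction_counted <= 1:
        raise ValueError("lysate_fraction_counted must be in (0, 1]")
    return dpm / sa.dpm_per_pmol / lysate_fraction_counted


def activity(record: WellRecord, sa: SpecificActivity) -> UptakeActivity:
    """Protein-normalized uptake activity (pmol/mg) of a single well."""
    pmol = dpm_to_pmol(record.dpm, sa, record.lysate_fraction_counted)
    return UptakeActivity(
        pmol_per_mg=pmol / record.protein,
        cell_line=record.cell_line,
        transporter=record.transporter,
        probe_conc=record.probe_conc,
        time=record.time,
        inhibitor=record.inhibitor,
        inhibitor_conc=record.inhibitor_conc,
        occasion=record.occasion,
    )


def control_correct(
    transporter_mean: UptakeActivity, control_mean: UptakeActivity
) -> tuple[UptakeActivity, bool]:
    """Subtract vector-control (background) uptake from the transporter-cell
    mean for a matched condition.

    Returns the corrected activity and a flag that is True when the corrected
    value is negative (control exceeded transporter signal).  Negative values
    are reported as-is rather than clamped: clamping would bias the bottom
    plateau of downstream inhibition curves.
    """
    if transporter_mean.cell_line != "transporter" or control_mean.cell_line != "vector_control":
        raise ValueError("expected a (transporter, vector_control) pair")
    if transporter_mean.condition_key() != control_mean.condition_key():
        raise ValueError(
            "condition mismatch: "
            f"{transporter_mean.condition_key()} vs {control_mean.condition_key()}"
        )
    corrected = transporter_mean.pmol_per_mg - control_mean.pmol_per_mg
    sd = None
    if transporter_mean.sd is not None and control_mean.sd is not None:
        sd = math.hypot(transporter_mean.sd, control_mean.sd)  # quadrature
    out = UptakeActivity(
        pmol_per_mg=corrected,
        cell_line="transporter",
        transporter=transporter_mean.transporter,
        probe_conc=transporter_mean.probe_conc,
        time=transporter_mean.time,
        inhibitor=transporter_mean.inhibitor,
        inhibitor_conc=transporter_mean.inhibitor_conc,
        occasion=transporter_mean.occasion,
        sd=sd,
        n=transporter_mean.n,
    )
    return out, corrected < 0


def uptake_ratio(transporter_mean: float, control_mean: float) -> float:
    """Transporter-cell over control-cell uptake; assay-window QC statistic."""
    if control_mean <= 0:
        raise ZeroDivisionError("uptake ratio undefined for non-positive control uptake")
    return transporter_mean / control_mean


def _through_origin_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and uncentered R^2."""
    slope = float(np.dot(t, y) / np.dot(t, t))
    resid = y - slope * t
    ss_tot = float(np.dot(y, y))
    if ss_tot == 0:
        raise ValueError("degenerate (all-zero) uptake series: linearity undefined")
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot
    return slope, r2


def assess_linearity(
    times: Sequence[float],
    corrected_activities: Sequence[float],
    r2_threshold: float = 0.95,
    max_rel_deviation: float = 0.15,
    uptake_ratios: Sequence[float] | None = None,
) -> LinearityAssessment:
    """Find the linear incubation window of a corrected uptake time course.

    Uptake through a transporter is proportional to time only while
    intracellular accumulation is far from steady state; fits must use a time
    inside that window.  The window is the longest prefix (starting at the
    earliest time) over which a through-origin line achieves
    ``R^2 >= r2_threshold`` with every point within ``max_rel_deviation`` of
    the line.  ``chosen_time`` is the last time inside the window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(corrected_activities, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 3:
        raise ValueError("need >= 3 paired (time, activity) points")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    order = np.argsort(t)
    t, y = t[order], y[order]
    if not np.any(y):
        raise ValueError("degenerate (all-zero) uptake series: linearity undefined")

    best: tuple[int, float] | None = None  # (end index, r2)
    for end in range(3, t.size + 1):
        slope, r2 = _through_origin_fit(t[:end], y[:end])
        pred = slope * t[:end]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(y[:end] - pred) / np.where(pred != 0, np.abs(pred), np.inf)
        if r2 >= r2_threshold and np.all(rel <= max_rel_deviation):
            best = (end, r2)
    if best is None:
        raise ValueError("no linear window found (first 3 points already nonlinear)")
    end, r2 = best
    chosen = float(t[end - 1])
    ratio = None
    if uptake_ratios is not None:
        ratios = np.asarray(uptake_ratios, dtype=float)[order]
        ratio = float(ratios[end - 1])
    return LinearityAssessment(
        linear_window=(float(t[0]), chosen),
        chosen_time=chosen,
        r_squared=float(r2),
        uptake_ratio_at_chosen_time=ratio,
    )


# ---------------------------------------------------------------------------
# tabular plumbing: well tables in and tidy activity tables out


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(w) for w in wells])
    return df[WELL_COLUMNS]


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    wells = []
    for row in df.to_dict("records"):
        inh = row.get("inhibitor")
        if inh is None or (isinstance(inh, float) and math.isnan(inh)) or inh == "":
            row["inhibitor"] = None
            row["inhibitor_conc"] = None
        else:
            row["inhibitor_conc"] = float(row["inhibitor_conc"])
        row.setdefault("lysate_fraction_counted", DEFAULT_LYSATE_FRACTION)
        row.setdefault("occasion", 1)
        if pd.isna(row.get("lysate_fraction_counted")):
            row["lysate_fraction_counted"] = DEFAULT_LYSATE_FRACTION
        row["occasion"] = int(row["occasion"]) if not pd.isna(row.get("occasion")) else 1
        wells.append(WellRecord(**{k: row[k] for k in WELL_COLUMNS}))
    return wells


def read_wells_csv(path) -> list[WellRecord]:
    """Read a well-table CSV (one row per well, UTF-8, headered; empty
    inhibitor field means no inhibitor)."""
    return frame_to_wells(pd.read_csv(path, float_precision="round_trip"))


def write_wells_csv(wells: Iterable[WellRecord], path) -> None:
    # %.17g keeps the dpm round-trip bit-exact (determinism contract)
    wells_to_frame(wells).to_csv(path, index=False, float_format="%.17g")


def summarize_activities(wells: Iterable[WellRecord], sa: SpecificActivity) -> pd.DataFrame:
    """Mean (+/- SD) activity of replicate wells per condition and cell line.

    Replicates are averaged before control correction, mirroring triplicate-
    well assay designs.
    """
    acts = [activity(w, sa) for w in wells]
    df = pd.DataFrame([asdict(a) for a in acts])
    grouped = (
        df.groupby(CONDITION_KEYS + ["cell_line"], dropna=False)["pmol_per_mg"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return grouped


def correct_activities(summary: pd.DataFrame) -> pd.DataFrame:
    """Control-correct a per-condition summary table.

    Pivots transporter vs vector_control means per condition, subtracts,
    propagates SDs in quadrature, and carries a ``negative_flag`` and the
    uptake ratio (NaN when the control mean is non-positive).
    """
    wide = summary.pivot_table(
        index=CONDITION_KEYS,
        columns="cell_line",
        values=["mean", "sd", "n"],
        aggfunc="first",
        dropna=False,
    )
    if ("mean", "transporter") not in wide.columns:
        raise ValueError("summary contains no transporter-cell rows")
    tmean = wide[("mean", "transporter")]
    cmean = wide.get(("mean", "vector_control"))
    if cmean is None:
        cmean = pd.Series(0.0, index=wide.index)
    cmean = cmean.fillna(0.0)
    corrected = tmean - cmean
    tsd = wide.get(("sd", "transporter"), pd.Series(np.nan, index=wide.index))
    csd = wide.get(("sd", "vector_control"), pd.Series(np.nan, index=wide.index))
    sd = np.sqrt(tsd.fillna(0.0) ** 2 + csd.fillna(0.0) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cmean > 0, tmean / cmean, np.nan)
    out = pd.DataFrame(
        {
            "transporter_mean": tmean,
            "control_mean": cmean,
            "corrected": corrected,
            "sd": sd,
            "uptake_ratio": ratio,
            "negative_flag": corrected < 0,
        },
        index=wide.index,
    ).reset_index()
    # corrected rate: normalize by incubation time
    out["corrected_rate"] = out["corrected"] / out["time"]
    return out
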