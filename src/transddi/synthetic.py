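"""Synthetic plate generators with known ground truth.

No raw well-level data are deposited for transporter uptake assays of this
design, so every downstream stage is exercised against simulated plates whose
generating parameters are known exactly.  The generators emulate the real
assay layout: triplicate transporter-cell and vector-control wells, saturable
Michaelis-Menten uptake that is linear in time within a window, sigmoidal
(4/5-parameter logistic) inhibition with between-occasion variability, and
bidirectional transwell transport with a paracellular-range permeability
(~0.5e-6 cm/s) plus a lucifer-yellow integrity channel.

Noise model: multiplicative lognormal on well dpm, parameterized by CV —
scintillation counts of moderate magnitude are strictly positive with roughly
constant CV.  Protein per well is normal around nominal (truncated positive).
The true distributional form of well noise is unknown; lognormal is a
configurable stand-in.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .uptake import DEFAULT_LYSATE_FRACTION, SpecificActivity, WellRecord
from .permeability import TranswellRecord

__all__ = [
    "AssayTruth",
    "InhibitionTruth",
    "TranswellTruth",
    "DEFAULT_SPECIFIC_ACTIVITY",
    "gen_uptake_timecourse",
    "gen_kinetic_plate",
    "gen_inhibition_plate",
    "gen_transwell_plate",
    "logistic_percent",
    "write_truth_sidecar",
]

#: [14C]-probe dosing solution: 37 kBq/mL at 100 umol/L -> 22.2 dpm/pmol
DEFAULT_SPECIFIC_ACTIVITY = SpecificActivity.from_solution(37.0, 100.0)


@dataclass(frozen=True)
class AssayTruth:
    """Ground truth for one transporter's uptake assay."""

    transporter: str  # OCT1 | OCT2 | MATE1 | MATE2-K
    km_true: float  # umol/L
    vmax_true: float  # pmol/min/mg
    control_fraction: float = 0.05  # background uptake / transporter-mediated rate
    protein_per_well: float = 0.1  # mg
    protein_cv: float = 0.05
    noise_cv: float = 0.0  # lognormal CV on well dpm
    seed: int = 0
    linear_until: float | None = None  # min; None = linear at all times
    sat_tau: float = 3.0  # min; exponential saturation time constant past linear_until

    def __post_init__(self) -> None:
        if self.km_true <= 0 or self.vmax_true <= 0:
            raise ValueError("km_true and vmax_true must be positive")
        if not 0 <= self.control_fraction < 1:
            raise ValueError("control_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.protein_per_well <= 0:
            raise ValueError("protein_per_well must be positive")

    def rate(self, probe_conc: float) -> float:
        """Transporter-mediated Michaelis-Menten rate (pmol/min/mg)."""
        return self.vmax_true * probe_conc / (self.km_true + probe_conc)

    def cumulative_time(self, t: float) -> float:
        """Effective uptake time: identity within the linear window, then an
        exponential approach past ``linear_until`` (no intracellular model is
        implied; this is a phenomenological departure from linearity)."""
        if self.linear_until is None or t <= self.linear_until:
            return t
        return self.linear_until + self.sat_tau * (
            1.0 - math.exp(-(t - self.linear_until) / self.sat_tau)
        )


@dataclass(frozen=True)
class InhibitionTruth:
    """Ground truth for one inhibitor x transporter dose-response."""

    ic50_true: float  # umol/L
    hill_true: float = 1.0
    bottom_true: float = 0.0  # percent control
    top_true: float = 100.0
    asymmetry_true: float = 1.0  # 1 = symmetric 4PL
    occasions: int = 1
    occasion_cv: float = 0.0  # lognormal CV on ic50_true per occasion

    def __post_init__(self) -> None:
        if self.ic50_true <= 0:
            raise ValueError("ic50_true must be positive")
        if self.hill_true <= 0 or self.asymmetry_true <= 0:
            raise ValueError("hill_true and asymmetry_true must be positive")
        if not self.bottom_true < self.top_true:
            raise ValueError("bottom_true must be below top_true")
        if self.occasions < 1:
            raise ValueError("occasions must be >= 1")


@dataclass(frozen=True)
class TranswellTruth:
    """Ground truth for a bidirectional transwell permeability plate."""

    papp_true: float = 0.5e-6  # cm/s, both directions
    area: float = 0.12  # cm^2
    donor_volume_ab: float = 90.0  # uL apical donor
    donor_volume_ba: float = 210.0  # uL basolateral donor
    duration: float = 5400.0  # s (90 min)
    ly_papp_true: float = 0.4e-6  # cm/s lucifer yellow
    ly_c0: float = 100.0  # umol/L lucifer yellow donor concentration
    loss_fraction: float = 0.0  # unrecovered fraction (mass balance = 1 - this)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.papp_true < 0 or self.ly_papp_true < 0:
            raise ValueError("permeabilities must be non-negative")
        if self.area <= 0 or self.duration <= 0:
            raise ValueError("area and duration must be positive")
        if not 0 <= self.loss_fraction < 1:
            raise ValueError("loss_fraction must be in [0, 1)")


def logistic_percent(conc: float, truth: InhibitionTruth, ic50: float | None = None) -> float:
    """Percent-control activity at an inhibitor concentration under the 4/5PL
    generating model.

    The curve is parameterized by its true half-inhibition concentration: for
    an asymmetric (5PL / Richards) curve the inflection ``xmid`` is back-solved
    so that the response passes (top+bottom)/2 exactly at ``ic50``.
    """
    ic50 = truth.ic50_true if ic50 is None else ic50
    if conc <= 0:
        return truth.top_true
    g = truth.asymmetry_true
    h = truth.hill_true
    xmid = ic50 / (2.0 ** (1.0 / g) - 1.0) ** (1.0 / h)
    frac = 1.0 / (1.0 + (conc / xmid) ** h) ** g
    return truth.bottom_true + (truth.top_true - truth.bottom_true) * frac


def _well(
    rng: np.random.Generator,
    truth: AssayTruth,
    *,
    well_id: str,
    cell_line: str,
    expected_pmol_per_mg: float,
    probe_conc: float,
    time: float,
    sa: SpecificActivity,
    lysate_fraction: float,
    inhibitor: str | None = None,
    inhibitor_conc: float | None = None,
    occasion: int = 1,
) -> WellRecord:
    protein = truth.protein_per_well
    if truth.protein_cv > 0:
        while True:  # truncate at > 0
            protein = rng.normal(truth.protein_per_well, truth.protein_cv * truth.protein_per_well)
            if protein > 0:
                break
    pmol = expected_pmol_per_mg * protein
    dpm = pmol * sa.dpm_per_pmol * lysate_fraction
    if truth.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
        dpm *= rng.lognormal(-0.5 * sigma**2, sigma)  # mean-one multiplier
    return WellRecord(
        well_id=well_id,
        cell_line=cell_line,
        transporter=truth.transporter,
        probe_conc=probe_conc,
        time=time,
        dpm=float(dpm),
        protein=float(protein),
        inhibitor=inhibitor,
        inhibitor_conc=inhibitor_conc,
        lysate_fraction_counted=lysate_fraction,
        occasion=occasion,
    )


def gen_uptake_timecourse(
    truth: AssayTruth,
    probe_conc: float,
    times: Sequence[float],
    replicates: int = 3,
    sa: SpecificActivity = DEFAULT_SPECIFIC_ACTIVITY,
    lysate_fraction: float = DEFAULT_LYSATE_FRACTION,
) -> list[WellRecord]:
    """Paired transporter/control wells across an incubation time course.

    Within the linear window the expected transporter-cell content at time t
    is ``rate(S) * (1 + control_fraction) * t`` pmol/mg; control wells carry
    only the ``control_fraction`` component.
    """
    if not times:
        raise ValueError("times must be non-empty")
    if any(t <= 0 for t in times):
        raise ValueError("times must be positive")
    if probe_conc <= 0:
        raise ValueError("probe_conc must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    rate = truth.rate(probe_conc)
    wells: list[WellRecord] = []
    for t in times:
        teff = truth.cumulative_time(t)
        for cell_line, per_mg in (
            ("transporter", rate * (1.0 + truth.control_fraction) * teff),
            ("vector_control", rate * truth.control_fraction * t),
        ):
            for r in range(replicates):
                wells.append(
                    _well(
                        rng,
                        truth,
                        well_id=f"{truth.transporter}_{cell_line}_t{t}_r{r + 1}",
                        cell_line=cell_line,
                        expected_pmol_per_mg=per_mg,
                        probe_conc=probe_conc,
                        time=float(t),
                        sa=sa,
                        lysate_fraction=lysate_fraction,
                    )
                )
    return wells


def gen_kinetic_plate(
    truth: AssayTruth,
    concs: Sequence[float],
    time: float,
    replicates: int = 3,
    sa: SpecificActivity = DEFAULT_SPECIFIC_ACTIVITY,
    lysate_fraction: float = DEFAULT_LYSATE_FRACTION,
) -> list[WellRecord]:
    """Km-determination plate: replicate transporter/control wells per
    substrate concentration at one (linear) incubation time."""
    if not concs:
        raise ValueError("concs must be non-empty")
    if any(c <= 0 for c in concs):
        raise ValueError("concs must be positive")
    if time <= 0:
        raise ValueError("time must be positive")
    rng = np.random.default_rng(truth.seed)
    wells: list[WellRecord] = []
    teff = truth.cumulative_time(time)
    for conc in concs:
        rate = truth.rate(conc)
        for cell_line, per_mg in (
            ("transporter", rate * (1.0 + truth.control_fraction) * teff),
            ("vector_control", rate * truth.control_fraction * time),
        ):
            for r in range(replicates):
                wells.append(
                    _well(
                        rng,
                        truth,
                        well_id=f"{truth.transporter}_{cell_line}_S{conc}_r{r + 1}",
                        cell_line=cell_line,
                        expected_pmol_per_mg=per_mg,
                        probe_conc=float(conc),
                        time=float(time),
                        sa=sa,
                        lysate_fraction=lysate_fraction,
                    )
                )
    return wells


def gen_inhibition_plate(
    assay: AssayTruth,
    inh: InhibitionTruth,
    inhibitor: str,
    inhibitor_concs: Sequence[float],
    probe_conc: float,
    time: float = 2.0,
    replicates: int = 3,
    sa: SpecificActivity = DEFAULT_SPECIFIC_ACTIVITY,
    lysate_fraction: float = DEFAULT_LYSATE_FRACTION,
    allow_high_probe: bool = False,
) -> list[WellRecord]:
    """Inhibition plate(s): vehicle plus a concentration series of inhibitor,
    one independent noise realization (and IC50 lognormal multiplier) per
    occasion.

    The probe concentration must sit at least 10-fold below the assay Km so
    that the fitted IC50 equates to Ki (Cheng-Prusoff condition); pass
    ``allow_high_probe=True`` to override deliberately.
    """
    if not inhibitor_concs:
        raise ValueError("inhibitor_concs must be non-empty")
    if probe_conc > assay.km_true / 10.0 and not allow_high_probe:
        raise ValueError(
            "probe_conc exceeds km_true/10; IC50 would not equate to Ki "
            "(pass allow_high_probe=True to override)"
        )
    rng = np.random.default_rng(assay.seed)
    base_rate = assay.rate(probe_conc)
    teff = assay.cumulative_time(time)
    wells: list[WellRecord] = []
    for occ in range(1, inh.occasions + 1):
        ic50_occ = inh.ic50_true
        if inh.occasion_cv > 0:
            sigma = math.sqrt(math.log(1.0 + inh.occasion_cv**2))
            ic50_occ *= rng.lognormal(-0.5 * sigma**2, sigma)
        for conc in [0.0, *inhibitor_concs]:
            pct = logistic_percent(conc, inh, ic50=ic50_occ) / 100.0
            for cell_line, per_mg in (
                ("transporter", base_rate * (pct + assay.control_fraction) * teff),
                ("vector_control", base_rate * assay.control_fraction * time),
            ):
                for r in range(replicates):
                    wells.append(
                        _well(
                            rng,
                            assay,
                            well_id=(
                                f"{assay.transporter}_{inhibitor}_{cell_line}"
                                f"_occ{occ}_I{conc}_r{r + 1}"
                            ),
                            cell_line=cell_line,
                            expected_pmol_per_mg=per_mg,
                            probe_conc=probe_conc,
                            time=float(time),
                            sa=sa,
                            lysate_fraction=lysate_fraction,
                            inhibitor=inhibitor,
                            inhibitor_conc=float(conc),
                            occasion=occ,
                        )
                    )
    return wells


def gen_transwell_plate(
    truth: TranswellTruth,
    metformin_concs: Sequence[float],
    directions: Sequence[str] = ("AB", "BA"),
    replicates: int = 3,
    inhibitor: str | None = None,
    matrix: str = "buffer",
) -> list[TranswellRecord]:
    """Bidirectional transwell plate: receiver amounts follow
    ``Q = Papp * A * C0 * t`` (with C0 in pmol/cm^3), the donor remainder is
    consistent with a stated recovery (1 - loss_fraction), and the lucifer-
    yellow channel follows ``ly_papp_true``."""
    if any(c <= 0 for c in metformin_concs):
        raise ValueError("concentrations must be positive")
    if truth.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(truth.seed)
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2)) if truth.noise_cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma == 0 or x == 0:
            return x
        return x * rng.lognormal(-0.5 * sigma**2, sigma)

    records: list[TranswellRecord] = []
    for c0 in metformin_concs:
        for direction in directions:
            if direction == "AB":
                donor_v, recv_v = truth.donor_volume_ab, truth.donor_volume_ba
            elif direction == "BA":
                donor_v, recv_v = truth.donor_volume_ba, truth.donor_volume_ab
            else:
                raise ValueError("direction must be 'AB' or 'BA'")
            q = truth.papp_true * truth.area * (c0 * 1000.0) * truth.duration  # pmol
            ly_q = truth.ly_papp_true * truth.area * (truth.ly_c0 * 1000.0) * truth.duration
            initial = c0 * donor_v  # pmol (umol/L == pmol/uL)
            for r in range(replicates):
                q_r = noisy(q)
                records.append(
                    TranswellRecord(
                        well_id=f"{direction}_C{c0}_r{r + 1}"
                        + (f"_{inhibitor}" if inhibitor else ""),
                        direction=direction,
                        c0=float(c0),
                        donor_volume=donor_v,
                        receiver_volume=recv_v,
                        area=truth.area,
                        duration=truth.duration,
                        receiver_amount=q_r,
                        donor_amount_end=max(initial * (1.0 - truth.loss_fraction) - q_r, 0.0),
                        ly_receiver_amount=noisy(ly_q),
                        ly_c0=truth.ly_c0,
                        inhibitor=inhibitor,
                        matrix=matrix,
                    )
                )
    return records


def write_truth_sidecar(path, *truths) -> None:
    """Echo generating parameters to a JSON sidecar for test harnesses."""
    payload = [{"type": type(t).__name__, **asdict(t)} for t in truths]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
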