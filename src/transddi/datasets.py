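"""Bundled input datasets.

``load_metformin_ddi()`` returns the published metformin case-study inputs
(perpetrator pharmacokinetics, determined Ki values, victim disposition
fractions, observed clinical AUC changes) as the domain objects the static
engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .static_model import ObservedDDI, Perpetrator, VictimDisposition
from .uptake import SpecificActivity

__all__ = ["MetforminDDIInputs", "load_metformin_ddi"]


@dataclass
class MetforminDDIInputs:
    perpetrators: list[Perpetrator]
    ki_table: dict[tuple[str, str], float]
    ki_sd_table: dict[tuple[str, str], float]
    dispositions: list[VictimDisposition]
    observed: list[ObservedDDI]
    kinetics: dict[str, dict[str, float]]  # transporter -> km/vmax (+SEs)
    min_uptake_ratios: dict[str, float]
    probe_conc: float  # umol/L
    specific_activity: SpecificActivity
    victim: str = "metformin"


def load_metformin_ddi() -> MetforminDDIInputs:
    ref = resources.files("transddi.data").joinpath("metformin_ddi.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    perps = [
        Perpetrator(
            name=p["name"],
            dose_mg=p["dose_mg"],
            mw=p["mw_g_mol"],
            fu=p["fu"],
            cmax_total=tuple(p["cmax_total_umol_l"]),
            igut_max=p.get("igut_max_umol_l"),
        )
        for p in raw["perpetrators"]
    ]
    ki = {
        (drug, transporter): float(v)
        for drug, tv in raw["ki_umol_l"].items()
        for transporter, v in tv.items()
    }
    ki_sd = {
        (drug, transporter): float(v)
        for drug, tv in raw.get("ki_sd_umol_l", {}).items()
        for transporter, v in tv.items()
    }
    dispositions = [
        VictimDisposition(
            renal_fraction_of_total_clearance=d["renal_fraction_of_total_clearance"],
            active_fraction_of_renal_clearance=d["active_fraction_of_renal_clearance"],
            route_label=d["route_label"],
        )
        for d in raw["dispositions"]
    ]
    observed = [
        ObservedDDI(
            perpetrator=o["perpetrator"],
            cmax_total=float(o["cmax_total_umol_l"]),
            observed_fold_auc=float(o["observed_fold_auc"]),
            victim_dose_mg=o.get("victim_dose_mg"),
            source_label=o.get("source_label", ""),
        )
        for o in raw["observed"]
    ]
    sa = SpecificActivity.from_solution(
        raw["specific_activity"]["kbq_per_ml"], raw["specific_activity"]["conc_umol_l"]
    )
    return MetforminDDIInputs(
        perpetrators=perps,
        ki_table=ki,
        ki_sd_table=ki_sd,
        dispositions=dispositions,
        observed=observed,
        kinetics=raw["kinetics"],
        min_uptake_ratios=raw["min_uptake_ratios"],
        probe_conc=float(raw["probe_conc_umol_l"]),
        specific_activity=sa,
        victim=raw.get("victim", "metformin"),
    )
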