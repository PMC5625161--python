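"""Pipeline orchestration: configuration, stage execution, validation,
report generation.

Stages: ``simulate`` (synthetic plates with truth sidecar) -> ``fit``
(Km/Vmax and IC50/Ki from the well tables) -> ``papp`` (transwell summary)
-> ``predict`` (static-model grid from the bundled clinical inputs) ->
``compare`` (predicted vs observed concordance) -> ``report`` (Markdown
summary).  Any stage can run from prior artifacts alone; re-running with the
same config and seed reproduces identical artifacts (hashes are logged).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import kinetics, permeability, static_model, synthetic, uptake
from .datasets import load_metformin_ddi

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

STAGES = ("simulate", "fit", "papp", "predict", "compare", "report")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "transddi_out"
    stages: tuple[str, ...] = STAGES
    transporter: str = "MATE1"
    inhibitors: tuple[str, ...] = ("cimetidine", "trimethoprim", "pyrimethamine")
    noise_cv: float = 0.05
    occasions: int = 3
    occasion_cv: float = 0.10
    replicates: int = 3
    control_fraction: float = 1.0 / 46.0
    incubation_time_min: float = 1.5
    linearity_r2: float = 0.95
    linearity_max_rel_dev: float = 0.15
    ly_threshold_cm_s: float = permeability.LY_PAPP_THRESHOLD
    systemic_cutoff: float = static_model.SYSTEMIC_CUTOFF
    gut_cutoff: float = static_model.GUT_CUTOFF
    concordance_metric: str = "percent_point_diff"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("linearity_r2", "ly_threshold_cm_s", "systemic_cutoff", "gut_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "inhibitors" in raw:
            raw["inhibitors"] = tuple(raw["inhibitors"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(files: dict[str, str | Path]) -> list[dict]:
    """Schema-check CSV inputs; returns row-level violations (report only).

    ``files`` maps a kind ("wells" | "transwells") to a path.
    """
    violations: list[dict] = []
    for kind, path in files.items():
        path = Path(path)
        if not path.exists():
            violations.append({"file": str(path), "row": None, "issue": "file not found"})
            continue
        df = pd.read_csv(path)
        if kind == "wells":
            required = ["well_id", "cell_line", "probe_conc", "time", "dpm", "protein"]
        elif kind == "transwells":
            required = ["well_id", "direction", "c0", "area", "duration", "receiver_amount"]
        else:
            violations.append({"file": str(path), "row": None, "issue": f"unknown kind {kind!r}"})
            continue
        for col in required:
            if col not in df.columns:
                violations.append(
                    {"file": str(path), "row": None, "issue": f"missing column {col!r}"}
                )
        checks = {
            "dpm": lambda v: v >= 0,
            "protein": lambda v: v > 0,
            "time": lambda v: v > 0,
            "duration": lambda v: v > 0,
            "area": lambda v: v > 0,
            "c0": lambda v: v > 0,
            "receiver_amount": lambda v: v >= 0,
        }
        for col, ok in checks.items():
            if col in df.columns:
                bad = df.index[~df[col].map(lambda v: pd.notna(v) and ok(v))]
                for idx in bad:
                    violations.append(
                        {"file": str(path), "row": int(idx), "issue": f"invalid {col}"}
                    )
    return violations


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns {artifact name: path} plus hashes."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_metformin_ddi()
    artifacts: dict[str, Path] = {}
    sa = inputs.specific_activity

    if "simulate" in config.stages:
        kin = inputs.kinetics[config.transporter]
        truth = synthetic.AssayTruth(
            transporter=config.transporter,
            km_true=kin["km_umol_l"],
            vmax_true=kin["vmax_pmol_min_mg"],
            control_fraction=config.control_fraction,
            noise_cv=config.noise_cv,
            seed=config.seed,
        )
        concs = [10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0]
        kin_wells = synthetic.gen_kinetic_plate(
            truth, concs, time=config.incubation_time_min, replicates=config.replicates
        )
        uptake.write_wells_csv(kin_wells, out / "kinetic_wells.csv")
        artifacts["kinetic_wells"] = out / "kinetic_wells.csv"
        inh_truths = {}
        for i_idx, inhibitor in enumerate(config.inhibitors):
            ki = inputs.ki_table.get((inhibitor, config.transporter))
            if ki is None:
                continue
            inh_truth = synthetic.InhibitionTruth(
                ic50_true=ki,
                occasions=config.occasions,
                occasion_cv=config.occasion_cv,
            )
            inh_truths[inhibitor] = inh_truth
            inh_wells = synthetic.gen_inhibition_plate(
                dataclasses.replace(truth, seed=config.seed + 1 + i_idx),
                inh_truth,
                inhibitor=inhibitor,
                inhibitor_concs=[ki * m for m in (0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100)],
                probe_conc=min(inputs.probe_conc, truth.km_true / 10.0),
                time=config.incubation_time_min,
                replicates=config.replicates,
            )
            uptake.write_wells_csv(inh_wells, out / f"inhibition_{inhibitor}.csv")
            artifacts[f"inhibition_{inhibitor}"] = out / f"inhibition_{inhibitor}.csv"
        tw_truth = synthetic.TranswellTruth(noise_cv=config.noise_cv, seed=config.seed)
        tw = synthetic.gen_transwell_plate(
            tw_truth, [10.0, 100.0, 1000.0, 10000.0], replicates=config.replicates
        )
        pd.DataFrame([asdict(r) for r in tw]).to_csv(out / "transwells.csv", index=False)
        artifacts["transwells"] = out / "transwells.csv"
        synthetic.write_truth_sidecar(out / "truth.json", truth, tw_truth, *inh_truths.values())
        artifacts["truth"] = out / "truth.json"

    if "fit" in config.stages:
        kin_wells = uptake.read_wells_csv(out / "kinetic_wells.csv")
        fit = kinetics.fit_kinetics_from_wells(kin_wells, sa)
        km_for_ki = fit.km
        fit_rows = [
            {
                "kind": "kinetics",
                "transporter": config.transporter,
                "km": fit.km,
                "km_se": fit.km_se,
                "vmax": fit.vmax,
                "vmax_se": fit.vmax_se,
            }
        ]
        report = {"kinetics": {"converged": fit.converged, "warnings": list(fit.warnings)}}
        for inhibitor in config.inhibitors:
            path = out / f"inhibition_{inhibitor}.csv"
            if not path.exists():
                continue
            res = kinetics.fit_inhibition_from_wells(
                uptake.read_wells_csv(path), sa, km=km_for_ki
            )
            fit_rows.append(
                {
                    "kind": "inhibition",
                    "transporter": config.transporter,
                    "inhibitor": inhibitor,
                    "model": res.model,
                    "ic50_mean": res.ic50_mean,
                    "ic50_sd": res.ic50_sd,
                    "ki": res.ki,
                }
            )
            report[f"ic50_{inhibitor}"] = {
                "per_occasion": list(res.per_occasion_ic50s),
                "ic50_equals_ki": res.ic50_equals_ki,
            }
        pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        (out / "fit_report.json").write_text(json.dumps(report, indent=2), encoding="utf-8")
        artifacts["fits"] = out / "fits.csv"
        artifacts["fit_report"] = out / "fit_report.json"

    if "papp" in config.stages:
        tw_df = pd.read_csv(out / "transwells.csv")
        recs = [
            permeability.TranswellRecord(
                **{
                    k: (None if pd.isna(v) else v)
                    for k, v in row.items()
                }
            )
            for row in tw_df.to_dict("records")
        ]
        results = permeability.summarize_transwells(recs, config.ly_threshold_cm_s)
        pd.DataFrame([asdict(r) for r in results]).to_csv(out / "papp.csv", index=False)
        artifacts["papp"] = out / "papp.csv"

    if "predict" in config.stages:
        pset = static_model.predict_all(
            inputs.perpetrators,
            inputs.ki_table,
            inputs.dispositions,
            systemic_cutoff=config.systemic_cutoff,
            gut_cutoff=config.gut_cutoff,
        )
        pset.to_frame().to_csv(out / "predictions.csv", index=False)
        artifacts["predictions"] = out / "predictions.csv"

    if "compare" in config.stages:
        pred_df = pd.read_csv(out / "predictions.csv")
        pset = static_model.predict_all(
            inputs.perpetrators, inputs.ki_table, inputs.dispositions
        )
        mate1 = [p for p in pset.predictions if p.transporter == "MATE1"]
        comp = static_model.compare_to_observed(
            mate1, inputs.observed, metric=config.concordance_metric
        )
        comp.to_csv(out / "comparison.csv", index=False)
        artifacts["comparison"] = out / "comparison.csv"

    if "report" in config.stages:
        def _table(path: Path) -> str:
            return "```\n" + pd.read_csv(path).to_string(index=False) + "\n```"

        lines = ["# transddi pipeline report", ""]
        if (out / "fits.csv").exists():
            lines += ["## Fitted parameters", "", _table(out / "fits.csv"), ""]
        if (out / "papp.csv").exists():
            lines += ["## Permeability", "", _table(out / "papp.csv"), ""]
        if (out / "predictions.csv").exists():
            lines += ["## Static predictions", "", _table(out / "predictions.csv"), ""]
        if (out / "comparison.csv").exists():
            comp = pd.read_csv(out / "comparison.csv")
            lines += ["## Predicted vs observed", "", _table(out / "comparison.csv"), ""]
            rng = static_model.concordance_range(comp)
            for fe, (lo, hi) in sorted(rng.items()):
                lines.append(f"- fe={fe:.2f}: concordance deltas span {lo:.0f}-{hi:.0f} points")
            lines.append("")
        (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
        artifacts["report"] = out / "report.md"

    hashes = {name: _sha256(path) for name, path in artifacts.items()}
    (out / "artifact_hashes.json").write_text(json.dumps(hashes, indent=2), encoding="utf-8")
    return {"artifacts": {k: str(v) for k, v in artifacts.items()}, "hashes": hashes}
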