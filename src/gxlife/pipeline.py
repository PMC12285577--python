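"""Stage orchestration and run manifests.

Executes simulate -> score -> endpoints -> models -> interaction -> orm ->
report in order, writing every artifact plus a manifest (config hash,
seed, per-file digests, package version, timestamps) so a run can be
reproduced byte-identically from its recorded inputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .endpoints import apply_exclusions
from .genetics import attach_genetic_risk
from .interaction import InteractionModel
from .lifestyle import (attach_lifestyle, categorize, estimate_weights,
                        weighted_score)
from .models import (fit_risk_model, isolated_effect, joint_category_grid,
                     risk_gradient_curve)
from .orm import bmi_adjusted_scan, lifestyle_subgroups, orm_association_scan
from .simulate import read_cohort, simulate, write_cohort

log = logging.getLogger("gxlife")

ALL_STAGES = ("simulate", "score", "endpoints", "models", "interaction",
              "orm", "report")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class RunManifest:
    def __init__(self, config: SimulationConfig, out_dir: Path):
        self.out_dir = out_dir
        self.data = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "started": _dt.datetime.now().isoformat(timespec="seconds"),
            "stages": [],
        }

    def record(self, stage: str, outputs: list[Path], status: str = "ok",
               error: str | None = None) -> None:
        self.data["stages"].append({
            "stage": stage,
            "status": status,
            "error": error,
            "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
        })
        self.write()

    def write(self) -> None:
        self.data["updated"] = _dt.datetime.now().isoformat(timespec="seconds")
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.data, fh, indent=2)


def run(config: SimulationConfig, out_dir, *,
        stages=ALL_STAGES, endpoint: str = "incident_obesity",
        weighted: bool = False, bootstrap_b: int = 200,
        cohort_path=None) -> RunManifest:
    """Run the pipeline stages in order, writing artifacts and a manifest.

    ``cohort_path`` supplies a pre-existing cohort TSV, skipping the
    simulate stage. A stage failure is recorded in the manifest (with the
    error) and aborts subsequent stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, out)
    state: dict = {"cohort": None}

    def load():
        if state["cohort"] is None:
            src = Path(cohort_path) if cohort_path else out / "cohort.tsv"
            state["cohort"] = read_cohort(src)
        return state["cohort"]

    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        try:
            outputs = _run_stage(stage, config, out, load, state,
                                 endpoint=endpoint, weighted=weighted,
                                 bootstrap_b=bootstrap_b,
                                 skip_simulate=cohort_path is not None)
            manifest.record(stage, outputs)
            log.info("stage %s complete (%d outputs)", stage, len(outputs))
        except Exception as exc:
            manifest.record(stage, [], status="failed", error=str(exc))
            log.error("stage %s failed: %s", stage, exc)
            raise
    return manifest


def _run_stage(stage, config, out: Path, load, state, *, endpoint, weighted,
               bootstrap_b, skip_simulate) -> list[Path]:
    if stage == "simulate":
        if skip_simulate:
            log.info("cohort supplied by user; skipping simulation")
            return []
        df = simulate(config)
        write_cohort(df, out / "cohort.tsv")
        state["cohort"] = df
        return [out / "cohort.tsv",
                out / "cohort.tsv.provenance.json"]

    if stage == "score":
        df = load()
        if "pgs_z" not in df.columns:
            df = attach_genetic_risk(df)
        if "lifestyle_score" not in df.columns:
            df = attach_lifestyle(df)
        weights = estimate_weights(df)
        weights.to_json(out / "lifestyle_weights.json")
        indicators = df[[c for c in df.columns if c.startswith("fav_")]]
        df["weighted_lifestyle_score"] = weighted_score(indicators, weights)
        df["weighted_lifestyle_category"] = categorize(
            df["weighted_lifestyle_score"])
        write_cohort(df, out / "cohort_scored.tsv")
        state["cohort"] = df
        return [out / "lifestyle_weights.json", out / "cohort_scored.tsv"]

    if stage == "endpoints":
        df = load()
        kept, ledger = apply_exclusions(df)
        ledger.to_json(out / "exclusion_ledger.json")
        write_cohort(kept, out / "cohort_analysis.tsv")
        state["cohort"] = kept
        return [out / "exclusion_ledger.json", out / "cohort_analysis.tsv"]

    if stage == "models":
        df = _with_weighted(load(), weighted)
        family = "cox" if endpoint.startswith("incident") else "logistic"
        if family == "cox" and "prevalent_obesity" in df.columns:
            # incident analysis: at-risk set excludes baseline obesity
            df = df[df["prevalent_obesity"] == 0]
        grid = joint_category_grid(df, endpoint=endpoint, family=family)
        grid.to_csv(out / "joint_grid.tsv", sep="\t", index=False)
        outputs = [out / "joint_grid.tsv"]
        for domain in ("genetic", "lifestyle"):
            res = isolated_effect(df, domain=domain, endpoint=endpoint,
                                  family=family)
            path = out / f"isolated_{domain}.tsv"
            res.to_tsv(path)
            outputs.append(path)
        if family == "cox":
            rm = fit_risk_model(df, endpoint=endpoint)
            curve = risk_gradient_curve(rm)
            curve.to_csv(out / "risk_curve.tsv", sep="\t", index=False)
            outputs.append(out / "risk_curve.tsv")
        return outputs

    if stage == "interaction":
        df = _with_weighted(load(), weighted)
        res = InteractionModel(df).fit(bootstrap_b=bootstrap_b,
                                       seed=config.seed)
        with open(out / "interaction.json", "w") as fh:
            json.dump(res.decomposition.to_dict()
                      | {"p_interaction": res.p_interaction}, fh, indent=2)
        res.decomposition.to_row().to_csv(out / "interaction.tsv", sep="\t",
                                          index=False)
        return [out / "interaction.json", out / "interaction.tsv"]

    if stage == "orm":
        df = load()
        scan = orm_association_scan(df)
        scan.to_csv(out / "orm_scan.tsv", sep="\t", index=False)
        sub = lifestyle_subgroups(df)
        sub.to_csv(out / "orm_subgroups.tsv", sep="\t", index=False)
        med = bmi_adjusted_scan(df)
        med.to_csv(out / "orm_bmi_adjusted.tsv", sep="\t", index=False)
        return [out / "orm_scan.tsv", out / "orm_subgroups.tsv",
                out / "orm_bmi_adjusted.tsv"]

    if stage == "report":
        return report(out)

    raise ValueError(f"unknown stage {stage!r}")


def _with_weighted(df: pd.DataFrame, weighted: bool) -> pd.DataFrame:
    if not weighted:
        return df
    if "weighted_lifestyle_category" not in df.columns:
        raise ValueError("weighted analysis requested but the score stage "
                         "has not produced weighted columns")
    out = df.copy()
    out["lifestyle_score"] = out["weighted_lifestyle_score"]
    out["lifestyle_category"] = out["weighted_lifestyle_category"]
    out["unfavorable_count"] = 5.0 - out["lifestyle_score"]
    return out


def report(out_dir) -> list[Path]:
    """Render a plain-text summary of whichever artifacts are present."""
    out = Path(out_dir)
    lines = [f"gxlife run summary ({out})", "=" * 40]

    grid_path = out / "joint_grid.tsv"
    if grid_path.exists():
        grid = pd.read_csv(grid_path, sep="\t")
        assert len(grid) == 9 and grid["reference"].sum() == 1
        lines.append("\nJoint genetic x lifestyle grid (reference "
                     "low/healthy):")
        lines.append(grid.to_string(index=False))
    else:
        log.warning("joint grid artifact absent; section omitted")

    for domain in ("genetic", "lifestyle"):
        path = out / f"isolated_{domain}.tsv"
        if path.exists():
            lines.append(f"\nIsolated {domain} effect:")
            lines.append(pd.read_csv(path, sep="\t").to_string(index=False))

    curve_path = out / "risk_curve.tsv"
    if curve_path.exists():
        curve = pd.read_csv(curve_path, sep="\t")
        lines.append("\nRisk by age 75 (median over percentile grid):")
        lines.append(f"  healthy: {curve['healthy_pct'].median():.2f}%  "
                     f"poor: {curve['poor_pct'].median():.2f}%")
    else:
        log.warning("risk-curve artifact absent; section omitted")

    ipath = out / "interaction.json"
    if ipath.exists():
        with open(ipath) as fh:
            dec = json.load(fh)
        ap_sum = (dec["AP_genetic"] + dec["AP_lifestyle"]
                  + dec["AP_interaction"])
        lines.append(f"\nInteraction decomposition: RERI={dec['RERI']:.3f}, "
                     f"AP G/L/I = {dec['AP_genetic']:.1%}/"
                     f"{dec['AP_lifestyle']:.1%}/{dec['AP_interaction']:.1%} "
                     f"(sum check: {ap_sum:.12f})")

    orm_path = out / "orm_scan.tsv"
    if orm_path.exists():
        scan = pd.read_csv(orm_path, sep="\t")
        lines.append(f"\nORM scan: {int(scan['replicated'].sum())}/"
                     f"{len(scan)} endpoints nominally replicated, "
                     f"{int(scan['bonferroni'].sum())} past Bonferroni")

    text = "\n".join(lines) + "\n"
    with open(out / "summary.txt", "w") as fh:
        fh.write(text)
    return [out / "summary.txt"]
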