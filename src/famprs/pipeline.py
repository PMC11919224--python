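"""End-to-end orchestration: simulate, score, compare, report.

``run_simulated_study`` drives the full analysis surface on a synthetic
study — panel, case-control cohort, multicase families, Welch/ROC,
population subsampling and kinship mixed models — and returns one
JSON-serialisable report.  Every source of randomness derives from a single
master seed, so reruns with the same seed are byte-identical.
``run_fixture_report`` produces the family-table report for the bundled
published familial scores (no genotypes required).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import roc_auc, welch_t
from .data_io import PedigreeRecord, load_family_scores, write_pedigree, write_scores, write_vcf
from .errors import FamprsError, ValidationError
from .family_comparison import family_report, render_family_table, subsample_compare
from .kinship_mm import test_group_difference
from .prs_scoring import format_2dp, score_cohort
from .synthetic_data import (
    FamilySim,
    SimulationConfig,
    ascertain_multicase_families,
    simulate_case_control_cohort,
    simulate_panel,
)

__all__ = ["PipelineConfig", "run_simulated_study", "run_fixture_report",
           "write_report", "report_to_json"]

_SEX01 = {"male": 0, "female": 1, "unknown": 0}


@dataclasses.dataclass
class PipelineConfig:
    sim: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    k: int = 500
    iterations: int = 100
    seed: int | None = None


def _subseed(stream: np.random.SeedSequence) -> int:
    return int(stream.generate_state(1)[0] % (2 ** 31))


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, FamprsError):
                raise ValidationError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, FamprsError):
                raise type(exc)(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def _family_scores(families: Sequence[FamilySim]) -> pd.DataFrame:
    rows = []
    for fam in families:
        fam_id = fam.pedigree[0].family_id
        for i, rec in enumerate(fam.pedigree):
            rows.append(
                {
                    "family_id": fam_id,
                    "individual_id": rec.individual_id,
                    "group": "familial_case" if fam.affected[i] else "unaffected_relative",
                    "wprs": float(fam.score[i]),
                    "sex": _SEX01[rec.sex],
                }
            )
    return pd.DataFrame(rows)


def run_simulated_study(config: PipelineConfig) -> dict:
    """Run the whole pipeline on a fresh simulation; return the report."""
    master = np.random.SeedSequence(config.seed)
    s_panel, s_cohort, s_fam, s_sub_cc, s_sub_cs, s_sub_uc = master.spawn(6)
    log: list[str] = []

    with _stage("simulate_panel"):
        panel, freqs = simulate_panel(config.sim, np.random.default_rng(s_panel))
        log.append(f"panel: {len(panel)} variants ({int(panel.variants['hla'].sum())} HLA-like)")

    with _stage("simulate_cohort"):
        cohort, labels, _pool = simulate_case_control_cohort(
            panel, freqs, config.sim, np.random.default_rng(s_cohort)
        )
        scores = score_cohort(cohort, panel, labels)
        scores["sex"] = labels["sex"].to_numpy()
        log.append(f"cohort: {len(scores)} scored individuals")

    case_scores = scores.loc[scores["group"] == "case", "wprs"].to_numpy()
    ctrl_scores = scores.loc[scores["group"] == "control", "wprs"].to_numpy()

    with _stage("cohort_stats"):
        welch = welch_t(case_scores, ctrl_scores)
        roc = roc_auc(
            scores["wprs"].to_numpy(), (scores["group"] == "case").to_numpy().astype(int)
        )

    with _stage("ascertain_families"):
        families, attempts = ascertain_multicase_families(
            panel, freqs, config.sim, np.random.default_rng(s_fam)
        )
        fam_scores = _family_scores(families)
        log.append(
            f"families: {len(families)} accepted in {attempts} attempts; "
            f"{len(fam_scores)} members"
        )

    with _stage("family_report"):
        fam_rep = family_report(fam_scores)

    famcase = fam_scores.loc[fam_scores["group"] == "familial_case", "wprs"].to_numpy()
    unaff = fam_scores.loc[fam_scores["group"] == "unaffected_relative", "wprs"].to_numpy()

    with _stage("subsample_compare"):
        subs = {
            "familial_case_vs_controls": subsample_compare(
                ctrl_scores, famcase, k=min(config.k, ctrl_scores.size),
                iterations=config.iterations, seed=_subseed(s_sub_cc)),
            "familial_case_vs_cases": subsample_compare(
                case_scores, famcase, k=min(config.k, case_scores.size),
                iterations=config.iterations, seed=_subseed(s_sub_cs)),
            "unaffected_vs_controls": subsample_compare(
                ctrl_scores, unaff, k=min(config.k, ctrl_scores.size),
                iterations=config.iterations, seed=_subseed(s_sub_uc)),
        }

    with _stage("mixed_model"):
        pedigree = [rec for fam in families for rec in fam.pedigree]
        fc = fam_scores[fam_scores["group"] == "familial_case"]
        un = fam_scores[fam_scores["group"] == "unaffected_relative"]
        ctrl_sex = scores.loc[scores["group"] == "control", "sex"].to_numpy()
        case_sex = scores.loc[scores["group"] == "case", "sex"].to_numpy()
        mm = {
            "familial_case_vs_controls": test_group_difference(
                fc["wprs"].to_numpy(), ctrl_scores, pedigree_a=pedigree,
                ids_a=fc["individual_id"].tolist(),
                sex=np.concatenate([fc["sex"].to_numpy(), ctrl_sex])),
            "familial_case_vs_cases": test_group_difference(
                fc["wprs"].to_numpy(), case_scores, pedigree_a=pedigree,
                ids_a=fc["individual_id"].tolist(),
                sex=np.concatenate([fc["sex"].to_numpy(), case_sex])),
            "unaffected_vs_controls": test_group_difference(
                un["wprs"].to_numpy(), ctrl_scores, pedigree_a=pedigree,
                ids_a=un["individual_id"].tolist(),
                sex=np.concatenate([un["sex"].to_numpy(), ctrl_sex])),
        }

    report = {
        "famprs_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config.sim)
        | {"k": config.k, "iterations": config.iterations},
        "panel": {"n_variants": len(panel), "provenance": panel.provenance},
        "cohort": {
            "n_cases": int(welch.n_a),
            "n_controls": int(welch.n_b),
            "case_mean": welch.mean_a,
            "case_sd": welch.sd_a,
            "control_mean": welch.mean_b,
            "control_sd": welch.sd_b,
            "welch": dataclasses.asdict(welch),
            "roc": {"auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                    "se": roc.se, "ci_method": roc.ci_method},
        },
        "families": {
            "n_families": len(families),
            "attempts": attempts,
            "n_affected": [f.n_affected for f in families],
            "by_family": fam_rep["by_family"].to_dict(orient="records"),
            "combined": fam_rep["combined"].to_dict(orient="records"),
        },
        "subsampling": {k: v.to_dict() for k, v in subs.items()},
        "mixed_model": {k: v.to_dict() for k, v in mm.items()},
        "log": log,
    }
    report["_tables"] = {
        "scores": scores,
        "family_scores": fam_scores,
        "family_table": render_family_table(fam_rep),
        "roc_points": pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}),
        "pedigree": pedigree,
    }
    return report


def run_fixture_report() -> dict:
    """Family-table report for the bundled published familial scores."""
    scores = load_family_scores()
    rep = family_report(scores)
    rendered = render_family_table(rep)
    return {
        "famprs_version": __version__,
        "n_individuals": len(scores),
        "n_affected": int((scores["group"] == "familial_case").sum()),
        "n_unaffected": int((scores["group"] == "unaffected_relative").sum()),
        "by_family": rep["by_family"].to_dict(orient="records"),
        "combined": rep["combined"].to_dict(orient="records"),
        "rendered": {
            fam: {col: rendered.loc[fam, col] for col in rendered.columns}
            for fam in rendered.index
        },
        "individuals": rep["individuals"].to_dict(orient="records"),
    }


def report_to_json(report: dict) -> str:
    """Deterministic JSON rendering (tables stripped, keys sorted)."""
    slim = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(slim, sort_keys=True, indent=2, allow_nan=True)


def write_report(report: dict, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report) + "\n")
    tables = report.get("_tables", {})
    if "scores" in tables:
        write_scores(tables["scores"], out / "cohort_scores.csv")
    if "family_scores" in tables:
        write_scores(tables["family_scores"], out / "family_scores.csv")
    if "family_table" in tables:
        tables["family_table"].to_csv(out / "family_table.csv")
    if "roc_points" in tables:
        tables["roc_points"].to_csv(out / "roc_points.csv", index=False)
    if "pedigree" in tables:
        write_pedigree(tables["pedigree"], out / "families.ped")
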