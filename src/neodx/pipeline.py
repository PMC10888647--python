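"""End-to-end pipeline orchestration.

Stage order: univariate → PCA → network → enrichment → OPLS → logistic.
Each stage writes machine-readable CSV into the output directory and
contributes to a JSON summary; identical configuration + seed gives
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import scenario_library
from .config import PipelineConfig
from .io import SampleTable, read_gmt, read_sample_table
from .logit import DxBuilder, expand_features, loo_cv_logit
from .network import adjacency_change, ward_silhouette
from .opls import classify_at_cutoff, fit_opls, loo_cv_opls, roc, \
    youden_cutoff
from .ora import consensus_enrich, expand_markers
from .univariate import (compare_groups, pca_on_significant,
                         significant_in_any, spearman_time)

__all__ = ["run_pipeline", "PipelineReport", "default_gmt_path",
           "StageError"]

log = logging.getLogger("neodx")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_gmt_path() -> Path:
    """Packaged synthetic pathway library (SMPDB-style compound sets)."""
    return Path(
        resources.files("neodx").joinpath("data/pathways_synthetic.gmt")
    )


@dataclass
class PipelineReport:
    """In-memory results of a pipeline run plus where they were written."""

    out_dir: Path
    summary: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    stage_outputs: dict = field(default_factory=dict)


def _load_table(config: PipelineConfig) -> SampleTable:
    if config.table_path:
        return read_sample_table(config.table_path)
    lib = scenario_library()
    if config.scenario not in lib:
        raise ValueError(
            f"unknown scenario {config.scenario!r}; "
            f"available: {sorted(lib)}"
        )
    return lib[config.scenario].generate(config.seed)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the configured stages in order; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    table = _load_table(config)
    groups = list(dict.fromkeys(table.groups))
    ref = config.reference_group or groups[0]
    cases = [g for g in groups if g != ref]
    summary["groups"] = {g: int((table.groups == g).sum()) for g in groups}
    summary["reference_group"] = ref

    comparisons = []
    stage = "univariate"
    if stage in config.stages:
        try:
            for case in cases:
                res = compare_groups(table, ref, case,
                                     config.alpha_univariate)
                comparisons.append(res)
                path = out / f"univariate_{_slug(ref)}_vs_{_slug(case)}.csv"
                res.table.to_csv(path, index=False)
            times = table.meta["time_h"].dropna().unique()
            if len(times) >= 2:
                ta = spearman_time(table)
                ta.table.to_csv(out / "time_association.csv", index=False)
                report.stage_outputs["time_association"] = ta
            report.comparisons = comparisons
            summary["univariate"] = {
                f"{r.group_a} vs {r.group_b}": {
                    "n_fdr_significant": int(r.table["significant"].sum()),
                    "n_raw_significant": int(
                        r.table["raw_significant"].sum()),
                    "fdr_significant": r.significant,
                }
                for r in comparisons
            }
        except Exception as e:  # noqa: BLE001 - stage boundary
            raise StageError(stage, e) from e

    stage = "pca"
    if stage in config.stages and comparisons:
        try:
            selection = significant_in_any(comparisons)
            if len(selection) >= 2:
                pca = pca_on_significant(table, selection)
                scores = pd.DataFrame(
                    pca.scores[:, :2], index=pca.sample_ids,
                    columns=["PC1", "PC2"],
                )
                scores["group"] = table.groups.values
                scores.to_csv(out / "pca_scores.csv")
                summary["pca"] = {
                    "n_analytes": len(pca.analytes),
                    "explained_variance_ratio":
                        [round(float(v), 4)
                         for v in pca.explained_variance_ratio[:5]],
                }
                report.stage_outputs["pca"] = pca
            else:
                summary["pca"] = {"n_analytes": len(selection),
                                  "skipped": "fewer than 2 selected"}
        except Exception as e:
            raise StageError(stage, e) from e

    stage = "network"
    if stage in config.stages:
        try:
            pair = config.network_pair or (
                (cases[-2], cases[-1]) if len(cases) >= 2
                else (ref, cases[0])
            )
            change = adjacency_change(table, pair[0], pair[1])
            if change.no_rewiring:
                summary["network"] = {"pair": list(pair),
                                      "no_rewiring": True}
            else:
                clusters = ward_silhouette(change)
                pd.DataFrame({
                    "analyte": clusters.analytes,
                    "cluster": clusters.labels,
                }).to_csv(out / "network_clusters.csv", index=False)
                pd.DataFrame(change.C, index=change.analytes,
                             columns=change.analytes).to_csv(
                    out / "adjacency_change.csv")
                summary["network"] = {
                    "pair": list(pair),
                    "k": clusters.k,
                    "mean_silhouette":
                        round(float(clusters.mean_silhouette), 4),
                }
                report.stage_outputs["network"] = clusters
        except Exception as e:
            raise StageError(stage, e) from e

    stage = "enrichment"
    if stage in config.stages and comparisons:
        try:
            gmt = read_gmt(config.gmt_path or default_gmt_path(),
                           library="synthetic")
            universe = table.panel.all_variants() & gmt.universe
            enr_rows = []
            for res in comparisons:
                markers = res.raw_significant
                if not markers:
                    continue
                family = expand_markers(markers, table.panel)
                enr = consensus_enrich(family, gmt,
                                       config.alpha_enrichment,
                                       universe=universe)
                t = enr.table.copy()
                t["comparison"] = f"{res.group_a} vs {res.group_b}"
                enr_rows.append(t)
                report.stage_outputs.setdefault("enrichment", {})[
                    f"{res.group_a} vs {res.group_b}"] = enr
            if enr_rows:
                allenr = pd.concat(enr_rows)
                allenr.to_csv(out / "enrichment.csv", index=False)
                summary["enrichment"] = {
                    comp: sorted(
                        sub.loc[sub["consensus_significant"], "pathway"]
                    )
                    for comp, sub in allenr.groupby("comparison")
                }
        except Exception as e:
            raise StageError(stage, e) from e

    stage = "opls"
    if stage in config.stages:
        try:
            summary["opls"] = {}
            for case in cases:
                n_ortho = config.opls_n_ortho.get(
                    case, config.default_n_ortho)
                sub = table.select_groups(ref, case)
                y = sub.binary_labels(ref, case)
                model = fit_opls(sub.X, y, n_ortho,
                                 feature_names=table.panel.codes)
                q2, cv_scores, _ = loo_cv_opls(sub.X, y, n_ortho)
                ok = ~np.isnan(cv_scores)
                cutoff = youden_cutoff(cv_scores[ok], y[ok])
                sens, spec = classify_at_cutoff(cv_scores[ok], y[ok],
                                                cutoff)
                curve = roc(cv_scores[ok], y[ok])
                vip_markers = [
                    c for c, v in zip(table.panel.codes, model.vip)
                    if v > 1
                ]
                summary["opls"][f"{ref} vs {case}"] = {
                    "n_ortho": n_ortho,
                    "R2X": round(model.R2X, 4),
                    "R2Y": round(model.R2Y, 4),
                    "Q2": round(q2, 4),
                    "auc": round(curve.auc, 4),
                    "cutoff": round(cutoff, 4),
                    "sensitivity": round(sens, 4),
                    "specificity": round(spec, 4),
                    "vip_gt1": vip_markers,
                }
                pd.DataFrame({
                    "analyte": table.panel.codes,
                    "vip": model.vip, "vip_pred": model.vip_pred,
                    "weight": model.w,
                }).to_csv(out / f"opls_vip_{_slug(case)}.csv", index=False)
                report.stage_outputs.setdefault("opls", {})[case] = model
        except Exception as e:
            raise StageError(stage, e) from e

    stage = "logistic"
    if stage in config.stages:
        try:
            summary["logistic"] = {}
            builder = DxBuilder()
            for case in cases:
                sub = table.select_groups(ref, case)
                y = sub.binary_labels(ref, case)
                feats = expand_features(sub)
                model = loo_cv_logit(feats, y, builder)
                summary["logistic"][f"{ref} vs {case}"] = {
                    "features": model.features,
                    "auc": round(model.roc_curve.auc, 4),
                    "cutoff": round(model.cutoff, 4),
                    "sensitivity": round(model.sensitivity, 4),
                    "specificity": round(model.specificity, 4),
                }
                report.stage_outputs.setdefault("logistic", {})[case] = \
                    model
        except Exception as e:
            raise StageError(stage, e) from e

    report.summary = summary
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline finished; outputs in %s", out)
    return report


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)
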