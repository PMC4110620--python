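"""End-to-end orchestration: config, staged pipeline, summary tables.

One config drives the whole analysis: load → stratify → select extremes →
filter → initial core-vs-core scan → window scan(s) → rank genes →
validation suite → KM baseline → method comparison. Every stage writes its
outputs (CSV/JSON) into the run directory and the fully resolved config is
serialized alongside for provenance, so a report can be regenerated from
the directory contents alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as cio
from .filtering import FilterSpec, filter_variable_genes
from .km import compare_methods, km_rank_genes
from .logit import LabelledCases, fit_all_genes
from .select import SelectionCriteria, apply_strata, select_extremes
from .simulate import SyntheticSpec, generate
from .validate import cluster_prediction_patterns, gene_correlations, leave_one_out, split_half
from .windows import (
    REVOLVING,
    bidirectional_scan,
    rank_genes,
    scores_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; validated up front, serialized on start."""

    out_dir: str
    expression_path: str | None = None
    clinical_path: str | None = None
    probe_map_path: str | None = None
    clinical_schema: dict[str, str] = field(
        default_factory=lambda: {"id": "sample_id", "time": "time", "event": "event", "stage": "stage"}
    )
    synthetic: dict[str, Any] | None = None  # SyntheticSpec kwargs instead of files
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    filter_spec: FilterSpec | None = field(default_factory=FilterSpec)
    scan_mode: str = REVOLVING
    window_size: int | None = None  # defaults to criteria.core_size
    threshold: float = 0.8
    min_hits: int = 20
    n_bootstrap: int = 200
    run_loo: bool = True
    run_split_half: bool = True
    km_q: int = 4
    compare_top_n: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and (self.expression_path is None or self.clinical_path is None):
            raise ValueError("need either file paths or a synthetic spec")
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must be in (0.5, 1)")
        if self.window_size is None:
            self.window_size = self.criteria.core_size

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "criteria" in d and isinstance(d["criteria"], Mapping):
            crit = dict(d["criteria"])
            if crit.get("include_stages") is not None:
                crit["include_stages"] = frozenset(crit["include_stages"])
            d["criteria"] = SelectionCriteria(**crit)
        if "filter_spec" in d and isinstance(d["filter_spec"], Mapping):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict[str, Any]:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return {k: encode(v) for k, v in dataclasses.asdict(self).items()}


def sorted_accuracy_table(models: pd.DataFrame, threshold: float = 0.8) -> tuple[pd.DataFrame, int]:
    """Genes sorted by folded AUC descending, plus the count at/above threshold.

    ``models`` is the per-gene table from :func:`extremescan.logit.fit_all_genes`.
    """
    table = models.sort_values(["auc_folded", "gene"], ascending=[False, True], key=None)
    count = int((table["auc_folded"] >= threshold).sum())
    return table, count


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_json(config.to_dict(), out / "config.json")
    report: dict[str, Any] = {"stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            info["seconds"] = round(time.perf_counter() - t0, 3)
            report["stages"][name] = info
            logger.info("stage %s: %s", name, info)

        return done

    # ---- load ----
    done = stage("load")
    if config.synthetic is not None:
        spec = SyntheticSpec(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        sim = generate(spec)
        matrix, cohort = sim.expression, sim.cohort
        sim.write(out / "inputs")
        report["ground_truth"] = {
            "signal_genes": sim.truth.signal_genes,
            "outlier_cases": sim.truth.outlier_cases,
        }
    else:
        matrix, _ = cio.read_expression(config.expression_path, config.probe_map_path)
        cohort, join = cio.read_clinical(config.clinical_path, config.clinical_schema, matrix)
        if join and join.unmatched_clinical:
            logger.warning("unmatched clinical ids: %s", join.unmatched_clinical)
    done(n_genes=matrix.n_genes, n_samples=matrix.n_samples, n_clinical=len(cohort))

    # ---- stratify + select extremes ----
    done = stage("select")
    strat = apply_strata(cohort, config.criteria)
    groups = select_extremes(strat, config.criteria)
    pd.DataFrame(
        {
            "sample_id": groups.early_extended + groups.late_extended,
            "group": ["early"] * len(groups.early_extended) + ["late"] * len(groups.late_extended),
            "in_core": [s in set(groups.early_core + groups.late_core)
                        for s in groups.early_extended + groups.late_extended],
        }
    ).to_csv(out / "groups.csv", index=False)
    done(n_stratified=len(strat), censoring=groups.censoring_summary)

    # ---- gene filter ----
    done = stage("filter")
    if config.filter_spec is not None:
        genes, diagnostics = filter_variable_genes(matrix, config.filter_spec)
        diagnostics.to_csv(out / "filter_diagnostics.csv")
    else:
        genes = matrix.gene_ids
    done(n_genes_in=matrix.n_genes, n_genes_kept=len(genes))

    # ---- initial core-vs-core scan ----
    done = stage("initial_scan")
    cases = LabelledCases.from_groups(matrix, groups.early_core, groups.late_core)
    models = fit_all_genes(cases, genes)
    acc_table, n_excellent = sorted_accuracy_table(models, config.threshold)
    acc_table.to_csv(out / "initial_models.csv")
    done(n_models=len(models), n_above_threshold=n_excellent)

    # ---- window scan + ranking ----
    done = stage("window_scan")
    scores = bidirectional_scan(
        genes, matrix,
        groups.early_extended, groups.late_extended,
        groups.early_core, groups.late_core,
        window_size=config.window_size, threshold=config.threshold,
        kind=config.scan_mode, seed=config.seed, n_replicates=config.n_bootstrap,
    )
    scores_frame(scores).to_csv(out / "window_scores.csv")
    ranked = rank_genes(scores, config.min_hits)
    (out / "ranked_genes.csv").write_text("gene\n" + "\n".join(ranked) + "\n")
    total = scores[0].total_comparisons if scores else 0
    done(total_comparisons=total, n_ranked=len(ranked))
    report["ranked_genes"] = ranked

    # ---- validation ----
    top = ranked if ranked else rank_genes(scores, 0)[: config.compare_top_n]
    if config.run_loo and len(top) >= 2:
        done = stage("loo")
        loo = leave_one_out(top, cases)
        loo.correct.astype(int).to_csv(out / "loo_matrix.csv")
        leaf_order, _, _ = cluster_prediction_patterns(loo)
        report["loo_gene_accuracy"] = loo.gene_accuracy.round(4).to_dict()
        report["loo_case_consensus"] = loo.case_consensus.round(4).to_dict()
        report["loo_cluster_order"] = leaf_order
        done(n_genes=len(top), mean_accuracy=float(loo.gene_accuracy.mean()))
    if config.run_split_half and top:
        done = stage("split_half")
        sh = split_half(top, cases)
        sh.to_csv(out / "split_half.csv")
        report["split_half_mean"] = float(sh.mean())
        done(mean_heldout_auc=float(sh.mean()))
    if top:
        done = stage("correlations")
        anchor = top[0]
        r, counts = gene_correlations(
            matrix, anchor, top[1:], groups.early_core + groups.late_core
        )
        r.to_csv(out / "correlations.csv")
        report["correlation_counts"] = {str(k): v for k, v in counts.items()}
        done(anchor=anchor, **{f"above_{k}": v for k, v in counts.items()})

    # ---- KM baseline + comparison ----
    done = stage("km_baseline")
    km_table = km_rank_genes(matrix, genes, strat, config.km_q)
    km_table.to_csv(out / "km_ranking.csv")
    lr_ranking = rank_genes(scores, 0)
    overlap = compare_methods(lr_ranking, list(km_table.index), config.compare_top_n)
    report["km_overlap"] = {
        "top_n": overlap.top_n,
        "count": overlap.overlap_count,
        "genes": overlap.overlap_genes,
        "jaccard": overlap.jaccard_by_depth,
    }
    done(overlap=overlap.overlap_count)

    cio.write_json(report, out / "report.json")
    return report
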