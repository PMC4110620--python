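"""Synthetic survival cohorts with planted prognostic structure.

The generator emulates the statistical shape the scanning method assumes: a
log-scale expression matrix of ~100 cases by thousands of genes, of which a
small correlated block of "signal" genes shifts between two latent survival
classes, plus right-censored survival times whose ordering separates the
classes. Every run returns the ground truth (signal genes, outlier cases,
true class per case) so each pipeline stage can be tested against a known
answer.

Model
-----
Cases split evenly into an early-event class (short exponential survival,
event observed) and a long-survivor class (a guaranteed follow-up gap plus
an exponential tail; a ``censor_rate`` fraction right-censored uniformly
over follow-up). Signal genes load on a shared latent factor per case —
inducing the within-block correlation — and shift by ``effect_delta`` noise
standard deviations between classes, higher in survivors by default (the
direction an infiltrating-immune-cell signal would take). ``signal_block_rho``
is the *target marginal* Pearson correlation between signal genes over the
pooled two-class cohort; the residual within-class correlation is derived
from it and the class shift, so empirical correlations land on the target.

Optionally, "advanced-stage" contamination cases can be added: they die
early, carry no signal-gene shift, and instead elevate a separate block of
progression-like genes — the structure that degrades whole-cohort quantile
analyses but is excluded by clinical stratification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalRecord, CohortTable, ExpressionMatrix, RAW_LOG


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one simulated cohort.

    Defaults mirror the target study scale: ~100 early-stage cases, 2000
    log2-scale genes around baseline 7, 20 signal genes with a 2.5-sd class
    shift correlated at ~0.75, and 30% of long survivors right-censored.
    """

    n_cases: int = 100
    n_genes: int = 2000
    n_signal_genes: int = 20
    signal_block_rho: float = 0.75
    effect_delta: float = 2.5
    noise_sd: float = 1.0
    baseline_mean: float = 7.0
    censor_rate: float = 0.3
    outlier_flip_count: int = 0
    signal_higher_in_survivors: bool = True
    # early-event survival scale and the survivor-side follow-up window (months)
    early_mean_months: float = 8.0
    survivor_gap_months: float = 60.0
    survivor_tail_months: float = 40.0
    # stage-III-like contamination (0 = none)
    n_contam_cases: int = 0
    n_contam_genes: int = 0
    contam_delta: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes + self.n_contam_genes > self.n_genes:
            raise ValueError("signal + contamination genes exceed n_genes")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        if not 0 <= self.signal_block_rho < 1:
            raise ValueError("signal_block_rho must be in [0, 1)")
        if self.outlier_flip_count > self.n_cases // 2:
            raise ValueError("outlier_flip_count exceeds the early class size")

    def residual_rho(self) -> float:
        """Within-class signal correlation implied by the marginal target.

        Over the pooled equal-size classes the marginal covariance of two
        signal genes is rho_resid + d^2/4 against a variance of 1 + d^2/4
        (d = effect_delta in noise-sd units); inverting gives rho_resid.
        """
        half_sq = (self.effect_delta / 2.0) ** 2
        rho = self.signal_block_rho * (1 + half_sq) - half_sq
        if rho < 0:
            raise ValueError(
                f"signal_block_rho={self.signal_block_rho} unattainable with "
                f"effect_delta={self.effect_delta}: the class shift alone forces "
                f"marginal correlation above the target"
            )
        return rho


@dataclass
class GroundTruth:
    signal_genes: list[str]
    contam_genes: list[str]
    outlier_cases: list[str]
    class_of: dict[str, str]  # case -> early | survivor | contam

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "signal_genes": self.signal_genes,
                    "contam_genes": self.contam_genes,
                    "outlier_cases": self.outlier_cases,
                    "class_of": self.class_of,
                },
                indent=2,
            )
        )


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    cohort: CohortTable
    truth: GroundTruth
    spec: SyntheticSpec = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        """Write expression TSV, clinical CSV, and ground-truth JSON in the
        same formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = self.expression.values.copy()
        df.index.name = "gene"
        df.to_csv(out / "expression.tsv", sep="\t")
        self.cohort.to_frame().to_csv(out / "clinical.csv", index=False)
        self.truth.to_json(out / "ground_truth.json")


def generate(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw one cohort. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_early = spec.n_cases // 2
    n_surv = spec.n_cases - n_early
    n_total = spec.n_cases + spec.n_contam_cases

    case_ids = [f"S{i + 1:03d}" for i in range(n_total)]
    early_ids = case_ids[:n_early]
    surv_ids = case_ids[n_early : spec.n_cases]
    contam_ids = case_ids[spec.n_cases :]

    # --- survival times ---
    t_early = rng.exponential(spec.early_mean_months, n_early)
    surv_event = rng.random(n_surv) >= spec.censor_rate
    t_surv = np.where(
        surv_event,
        spec.survivor_gap_months + rng.exponential(spec.survivor_tail_months, n_surv),
        spec.survivor_gap_months + rng.uniform(0, 2 * spec.survivor_tail_months, n_surv),
    )
    t_contam = rng.exponential(spec.early_mean_months, spec.n_contam_cases)

    records = []
    stages = ["I", "II"]
    for i, cid in enumerate(early_ids):
        records.append(ClinicalRecord(cid, float(t_early[i]), True, stages[i % 2], False))
    for i, cid in enumerate(surv_ids):
        records.append(
            ClinicalRecord(cid, float(t_surv[i]), bool(surv_event[i]), stages[i % 2], False)
        )
    for i, cid in enumerate(contam_ids):
        records.append(ClinicalRecord(cid, float(t_contam[i]), True, "III", False))
    cohort = CohortTable(records)

    # --- expression ---
    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    signal_genes = gene_ids[: spec.n_signal_genes]
    contam_genes = gene_ids[spec.n_signal_genes : spec.n_signal_genes + spec.n_contam_genes]

    values = spec.baseline_mean + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, n_total)
    )

    # class sign per case: +1 survivor, -1 early; contamination cases carry
    # the survivor-like signal level yet die early — their progression is
    # driven by the contamination block, not the signal block, which is what
    # erodes whole-cohort survival associations of the signal genes
    sign = np.zeros(n_total)
    sign[:n_early] = -1.0
    sign[n_early:] = 1.0
    if not spec.signal_higher_in_survivors:
        sign = -sign

    outliers = []
    if spec.outlier_flip_count:
        # flip the expression-class linkage of extreme-ranked cases (the
        # shortest-lived early cases and longest-followed survivors) so the
        # flips land inside any core group a downstream selection would pick
        n_flip_early = spec.outlier_flip_count // 2 + spec.outlier_flip_count % 2
        n_flip_surv = spec.outlier_flip_count // 2
        flip_early = list(np.argsort(t_early)[:n_flip_early])
        flip_surv = [n_early + j for j in np.argsort(-t_surv)[:n_flip_surv]]
        for j in flip_early + flip_surv:
            sign[j] = -sign[j]
            outliers.append(case_ids[j])

    rho_resid = spec.residual_rho()
    latent = rng.standard_normal(n_total)  # shared factor inducing the block correlation
    if spec.n_signal_genes:
        eps = rng.standard_normal((spec.n_signal_genes, n_total))
        block = np.sqrt(rho_resid) * latent + np.sqrt(1 - rho_resid) * eps
        shift = (spec.effect_delta / 2.0) * sign
        values[: spec.n_signal_genes] = spec.baseline_mean + spec.noise_sd * (shift + block)

    if spec.n_contam_genes and spec.n_contam_cases:
        rows = slice(spec.n_signal_genes, spec.n_signal_genes + spec.n_contam_genes)
        values[rows, spec.n_cases :] += spec.noise_sd * spec.contam_delta

    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=case_ids), scale_tag=RAW_LOG
    )
    class_of = {cid: "early" for cid in early_ids}
    class_of.update({cid: "survivor" for cid in surv_ids})
    class_of.update({cid: "contam" for cid in contam_ids})
    truth = GroundTruth(
        signal_genes=signal_genes,
        contam_genes=list(contam_genes),
        outlier_cases=outliers,
        class_of=class_of,
    )
    return SyntheticCohort(expression, cohort, truth, spec)
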