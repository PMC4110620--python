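"""Expression-quantile Kaplan-Meier baseline and method comparison.

The conventional route to prognostic genes: split the cohort into expression
quantiles for each gene, estimate a product-limit survival curve per
quantile, and rank genes by a chi-square test of curve equality. Here the
equality test is the standard log-rank (Mantel-Cox) statistic on q groups
(q-1 degrees of freedom). The comparison report measures how much of the
extreme-group scan's gene list this baseline recovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io import CohortTable, ExpressionMatrix


@dataclass
class KmQuantileResult:
    gene_id: str
    quantile_of: pd.Series          # sample id -> quantile label 1..q
    curves: dict[int, pd.DataFrame]  # quantile -> (time, survival, at_risk)
    chisq: float
    p: float
    zero_event_quantiles: list[int]


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Product-limit survival curve under right censoring.

    Returns a step-function table (time, survival, at_risk) defined at the
    observed event times, starting from S(0) = 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(float),
            "survival": surv.to_numpy(float),
            "at_risk": table["at_risk"].to_numpy(float),
        }
    )


def assign_quantiles(values: pd.Series, q: int) -> pd.Series:
    """Deterministic near-equal quantile assignment by expression rank.

    Ties broken by stable sample order; group sizes differ by at most one
    (remainder cases go to the lowest-expression groups).
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    n = len(values)
    if n < q:
        raise ValueError(f"cannot split {n} cases into {q} quantiles")
    order = np.argsort(values.to_numpy(), kind="stable")
    base, extra = divmod(n, q)
    labels = np.empty(n, dtype=int)
    start = 0
    for g in range(1, q + 1):
        size = base + (1 if g <= extra else 0)
        labels[order[start : start + size]] = g
        start += size
    return pd.Series(labels, index=values.index, name="quantile")


def km_quantile_test(
    matrix: ExpressionMatrix, gene_id: str, cohort: CohortTable, q: int = 4
) -> KmQuantileResult:
    """Log-rank equality test across q expression quantiles of one gene."""
    ids = [s for s in cohort.sample_ids if s in matrix.values.columns]
    if len(ids) < q:
        raise ValueError("too few joined cases for the requested quantiles")
    sub = cohort.subset(ids)
    expr = matrix.values.loc[gene_id, ids]
    quantiles = assign_quantiles(expr, q)

    times = np.array([r.time for r in sub.records])
    events = np.array([r.event for r in sub.records], bool)
    groups = quantiles.loc[sub.sample_ids].to_numpy()

    res = multivariate_logrank_test(times, groups, events)
    curves = {}
    zero_event = []
    for g in range(1, q + 1):
        mask = groups == g
        curves[g] = km_estimate(times[mask], events[mask])
        if events[mask].sum() == 0:
            zero_event.append(g)
    return KmQuantileResult(
        gene_id=gene_id,
        quantile_of=quantiles,
        curves=curves,
        chisq=float(res.test_statistic),
        p=float(res.p_value),
        zero_event_quantiles=zero_event,
    )


def logrank_chisq(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray, q: int
) -> tuple[float, float]:
    """Multi-group log-rank (Mantel-Cox) chi-square with q-1 df.

    Array implementation of the standard observed-minus-expected statistic
    with the hypergeometric covariance at each event time; agrees with
    lifelines' ``multivariate_logrank_test`` (asserted in the test suite)
    but is fast enough to rank thousands of genes.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups, int)
    event_times = np.unique(times[events])
    if event_times.size == 0:
        return 0.0, 1.0

    sorted_by_group = [np.sort(times[groups == g]) for g in range(1, q + 1)]
    # at-risk counts n_j(t) and event counts d_j(t) per group at each event time
    n_at = np.stack([
        len(tj) - np.searchsorted(tj, event_times, side="left")
        for tj in sorted_by_group
    ])  # q x T
    d_at = np.stack([
        np.array([np.sum((times == t) & events & (groups == g)) for t in event_times])
        for g in range(1, q + 1)
    ])
    n_tot = n_at.sum(axis=0).astype(float)
    d_tot = d_at.sum(axis=0).astype(float)

    observed = d_at.sum(axis=1).astype(float)
    expected = (d_tot * n_at / n_tot).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    p_at = n_at / n_tot
    cov = np.zeros((q, q))
    for t in range(event_times.size):
        pt = p_at[:, t]
        cov += factor[t] * (np.diag(pt) - np.outer(pt, pt))

    z = (observed - expected)[: q - 1]
    v = cov[: q - 1, : q - 1]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    from scipy import stats as sps

    return stat, float(sps.chi2.sf(stat, df=q - 1))


def km_rank_genes(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    cohort: CohortTable,
    q: int = 4,
) -> pd.DataFrame:
    """Per-gene quantile log-rank statistics, most significant first.

    Ranking only needs the test statistic, so the per-quantile survival
    curves of :func:`km_quantile_test` are skipped and the statistic comes
    from the array log-rank implementation.
    """
    ids = [s for s in cohort.sample_ids if s in matrix.values.columns]
    sub = cohort.subset(ids)
    times = np.array([r.time for r in sub.records])
    events = np.array([r.event for r in sub.records], bool)
    expr = matrix.values.loc[list(genes), ids]
    rows = []
    for g in genes:
        quantiles = assign_quantiles(expr.loc[g], q)
        chisq, p = logrank_chisq(times, events, quantiles.to_numpy(), q)
        rows.append({"gene": g, "chisq": chisq, "p": p})
    df = pd.DataFrame(rows).set_index("gene")
    return df.sort_values(["p", "gene"], ascending=[True, True])


@dataclass
class OverlapReport:
    top_n: int
    overlap_count: int
    overlap_genes: list[str]
    jaccard_by_depth: dict[int, float]


def compare_methods(
    lr_ranking: Sequence[str],
    km_ranking: Sequence[str],
    top_n: int,
    depths: Sequence[int] = (10, 20, 40),
) -> OverlapReport:
    """Overlap between the scan ranking and the KM ranking at top_n, plus
    Jaccard similarity at several depths."""
    common = set(lr_ranking) & set(km_ranking)
    if not common:
        raise ValueError("rankings share no genes; not comparable")
    top_lr = set(lr_ranking[:top_n])
    top_km = set(km_ranking[:top_n])
    inter = top_lr & top_km
    jaccard = {}
    for d in depths:
        a, b = set(lr_ranking[:d]), set(km_ranking[:d])
        union = a | b
        jaccard[d] = len(a & b) / len(union) if union else 0.0
    return OverlapReport(
        top_n=top_n,
        overlap_count=len(inter),
        overlap_genes=sorted(inter),
        jaccard_by_depth=jaccard,
    )
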