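"""Validation of per-gene models: leave-one-out, split-half, clustering.

Overfitting is the chief hazard of small two-group designs, so each
candidate gene's logistic model is re-derived with held-out cases. The LOO
matrix records, gene by case, whether the case was classified correctly by
a model trained on the other n-1 cases; its column means expose cases that
defy prediction by most genes (outliers), and clustering its rows groups
genes with similar prediction patterns (coordinately expressed genes make
the same mistakes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from typing import Sequence

from .io import ExpressionMatrix
from .logit import LabelledCases, fit_gene_model, pairwise_auc_unfolded


@dataclass
class LooMatrix:
    """Genes x cases correctness matrix from leave-one-out refits."""

    correct: pd.DataFrame  # bool, genes x case ids
    labels: pd.Series      # case id -> class

    @property
    def gene_accuracy(self) -> pd.Series:
        return self.correct.mean(axis=1)

    @property
    def case_consensus(self) -> pd.Series:
        """Fraction of genes predicting each case correctly; low values mark
        consistently mispredicted cases."""
        return self.correct.mean(axis=0)


def leave_one_out(
    genes: Sequence[str], cases: LabelledCases, threshold: float = 0.5
) -> LooMatrix:
    """Refit each gene's model with one case held out, predict that case.

    For every (gene, case): train on the remaining n-1 cases, classify the
    held-out case at fitted probability ``threshold``, record correctness.
    """
    genes = list(genes)
    labels = cases.labels
    ids = list(cases.values.columns)
    n = len(ids)
    out = np.zeros((len(genes), n), dtype=bool)
    for j in range(n):
        keep = np.arange(n) != j
        fold_labels = labels[keep]
        if fold_labels.min() == fold_labels.max():
            raise ValueError(f"leaving out {ids[j]!r} empties one class")
        fold = LabelledCases(cases.values.iloc[:, keep], fold_labels)
        for i, g in enumerate(genes):
            model = fit_gene_model(fold, g)
            pred = model.predict(np.array([cases.values.loc[g].iloc[j]]), threshold)[0]
            out[i, j] = pred == labels[j]
    return LooMatrix(
        correct=pd.DataFrame(out, index=genes, columns=ids),
        labels=pd.Series(labels, index=ids),
    )


def _directional_heldout_auc(
    train: LabelledCases, test: LabelledCases, gene: str
) -> float:
    """Held-out AUC in the direction the trained slope predicts.

    A model trained on the wrong direction scores below 0.5 on the test set,
    so training genuinely matters to the estimate.
    """
    model = fit_gene_model(train, gene)
    t1, t0 = test.gene_values(gene)
    a = pairwise_auc_unfolded(t1, t0)
    return a if model.slope >= 0 else 1.0 - a


def split_half(genes: Sequence[str], cases: LabelledCases) -> pd.Series:
    """Alternating split-half validation; per-gene mean held-out AUC.

    Within each class, cases in their given order are split into
    odd-indexed (A) and even-indexed (B) halves. The two half-pairings
    (A1+A0 vs B1+B0, and A1+B0 vs B1+A0), each evaluated in both
    train/evaluate directions, give 4 held-out AUCs per gene.
    """
    labels = cases.labels
    idx1 = np.flatnonzero(labels == 1)
    idx0 = np.flatnonzero(labels == 0)
    for name, idx in (("class 1", idx1), ("class 0", idx0)):
        if len(idx) % 2:
            raise ValueError(f"{name} has odd size {len(idx)}; split-half needs even classes")
    a1, b1 = idx1[::2], idx1[1::2]
    a0, b0 = idx0[::2], idx0[1::2]

    def subset(i1: np.ndarray, i0: np.ndarray) -> LabelledCases:
        sel = np.concatenate([i1, i0])
        return LabelledCases(
            cases.values.iloc[:, sel], np.r_[np.ones(len(i1), int), np.zeros(len(i0), int)]
        )

    pairings = [
        (subset(a1, a0), subset(b1, b0)),
        (subset(a1, b0), subset(b1, a0)),
    ]
    result = {}
    for g in genes:
        aucs = []
        for train, test in pairings:
            aucs.append(_directional_heldout_auc(train, test, g))
            aucs.append(_directional_heldout_auc(test, train, g))
        result[g] = float(np.mean(aucs))
    return pd.Series(result, name="mean_heldout_auc")


def cluster_prediction_patterns(
    loo: LooMatrix, cut_height: float | None = None
) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Cluster genes by similarity of their LOO correctness vectors.

    Hamming distance between correctness rows, average linkage. Returns the
    display leaf order, the linkage matrix, and (if ``cut_height`` given)
    flat cluster assignments aligned with the input gene order.
    """
    if loo.correct.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    rows = loo.correct.to_numpy().astype(float)
    dist = pdist(rows, metric="hamming")
    linkage = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(hierarchy.optimal_leaf_ordering(linkage, dist))
    leaf_genes = [loo.correct.index[i] for i in order]
    assignments = (
        hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
        if cut_height is not None
        else None
    )
    return leaf_genes, linkage, assignments


def gene_correlations(
    matrix: ExpressionMatrix,
    anchor: str,
    others: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    thresholds: Sequence[float] = (0.7, 0.8),
) -> tuple[pd.Series, dict[float, int]]:
    """Pearson correlation of an anchor gene against each other gene.

    Computed over ``sample_ids`` (default: all samples). Also returns counts
    of genes exceeding each threshold — the summary used to argue that top
    prognostic genes form one coordinately expressed block.
    """
    cols = list(sample_ids) if sample_ids is not None else matrix.sample_ids
    if len(cols) < 3:
        raise ValueError("need at least 3 samples for correlation")
    anchor_row = matrix.values.loc[anchor, cols].to_numpy(dtype=float)
    r = pd.Series(
        {g: float(np.corrcoef(anchor_row, matrix.values.loc[g, cols])[0, 1]) for g in others},
        name="pearson_r",
    )
    counts = {t: int((r > t).sum()) for t in thresholds}
    return r, counts
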