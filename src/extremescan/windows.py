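"""Sliding-window resampling of the extreme groups and hit-count scoring.

A single 20-vs-20 comparison can be swayed by the particular cases that fell
into the groups. The window analyses stress each gene against many
alternative group compositions drawn from the 40-case extended extremes:

* sequential windows slide one rank at a time (m-k+1 windows), which
  over-samples mid-ranked cases;
* revolving windows wrap around the ordered group (m windows, every case
  sampled exactly k times), equalizing case usage while preserving the
  survival ordering as much as possible;
* bootstrap windows resample k cases without replacement B times, for
  cohorts whose survival ordering is less trustworthy.

A gene's score is the number of window comparisons in which its folded
concordance AUC exceeds a threshold (0.8 by default — the conventional bar
for an excellent discriminatory model). Because the fitted-probability AUC
of a one-covariate logistic model equals the raw-value AUC, each window
comparison is scored directly from expression ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .logit import auc_matrix

SEQUENTIAL = "sequential"
REVOLVING = "revolving"
BOOTSTRAP = "bootstrap"


@dataclass
class WindowSet:
    """A family of ordered k-case windows over an m-case source group."""

    windows: list[list[str]]
    kind: str
    window_size: int
    source_size: int
    source_group: str = ""

    def __len__(self) -> int:
        return len(self.windows)

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.windows:
            for case in w:
                counts[case] = counts.get(case, 0) + 1
        return counts


@dataclass
class WindowScore:
    """Per-gene threshold hit count over a family of window comparisons."""

    gene_id: str
    hits: int
    total_comparisons: int
    mean_auc: float
    by_direction: dict[str, tuple[int, int]]  # label -> (hits, total)

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.total_comparisons:
            raise ValueError("hits outside [0, total_comparisons]")


def _check_k_m(k: int, m: int) -> None:
    if k < 1:
        raise ValueError("window size must be positive")
    if k > m:
        raise ValueError(f"window size {k} exceeds group size {m}")


def sequential_windows(group: Sequence[str], k: int) -> WindowSet:
    """All m-k+1 consecutive rank windows: ranks 1..k, 2..k+1, ..., m-k+1..m."""
    group = list(group)
    _check_k_m(k, len(group))
    wins = [group[i : i + k] for i in range(len(group) - k + 1)]
    return WindowSet(wins, SEQUENTIAL, k, len(group))


def revolving_windows(group: Sequence[str], k: int) -> WindowSet:
    """m wrap-around windows; every case is sampled exactly k times.

    Window i holds ranks i..i+k-1 modulo m, so once the trailing edge passes
    rank m-k+1 the earliest-ranked cases complete the window.
    """
    group = list(group)
    m = len(group)
    _check_k_m(k, m)
    wins = [[group[(i + j) % m] for j in range(k)] for i in range(m)]
    return WindowSet(wins, REVOLVING, k, m)


def bootstrap_windows(
    group: Sequence[str], k: int, n_replicates: int = 200, seed: int | None = None
) -> WindowSet:
    """B random k-subsets (without replacement within a window), order-free."""
    group = list(group)
    _check_k_m(k, len(group))
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    rng = np.random.default_rng(seed)
    wins = [list(rng.choice(group, size=k, replace=False)) for _ in range(n_replicates)]
    return WindowSet(wins, BOOTSTRAP, k, len(group))


def _window_aucs(
    genes: list[str],
    matrix: ExpressionMatrix,
    windows: WindowSet,
    fixed: list[str],
    fixed_is_class1: bool,
) -> np.ndarray:
    """Folded AUC per gene x window; class 1 is always the early-event side."""
    sub = matrix.values.loc[genes]
    fixed_block = sub.loc[:, fixed].to_numpy()
    out = np.empty((len(genes), len(windows)), float)
    for j, win in enumerate(windows.windows):
        win_block = sub.loc[:, win].to_numpy()
        if fixed_is_class1:
            a = auc_matrix(fixed_block, win_block)
        else:
            a = auc_matrix(win_block, fixed_block)
        out[:, j] = np.maximum(a, 1.0 - a)
    return out


def scan(
    genes: Sequence[str],
    matrix: ExpressionMatrix,
    moving: WindowSet,
    fixed: Sequence[str],
    threshold: float = 0.8,
    moving_is_class1: bool = True,
    direction_label: str = "",
) -> tuple[list[WindowScore], pd.DataFrame]:
    """Score every gene over one family of window-vs-fixed comparisons.

    Each window is compared against the constant opposing group; a hit is a
    folded AUC above ``threshold``. Returns per-gene scores plus the full
    genes x windows folded-AUC table for distribution work.
    """
    genes = list(genes)
    fixed = list(fixed)
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    overlap = {c for w in moving.windows for c in w} & set(fixed)
    if overlap:
        raise ValueError(f"window and fixed-group membership overlap: {sorted(overlap)[:3]}")

    aucs = _window_aucs(genes, matrix, moving, fixed, fixed_is_class1=not moving_is_class1)
    label = direction_label or f"{moving.kind}_vs_fixed"
    hits = (aucs > threshold).sum(axis=1)
    scores = [
        WindowScore(
            gene_id=g,
            hits=int(hits[i]),
            total_comparisons=len(moving),
            mean_auc=float(aucs[i].mean()),
            by_direction={label: (int(hits[i]), len(moving))},
        )
        for i, g in enumerate(genes)
    ]
    auc_table = pd.DataFrame(
        aucs, index=genes, columns=[f"{label}_{j + 1}" for j in range(len(moving))]
    )
    return scores, auc_table


def combine_scores(*score_lists: list[WindowScore]) -> list[WindowScore]:
    """Sum hit counts over scans of the same genes (e.g. the two directions
    of the bidirectional design, 40 + 40 = 80 comparisons)."""
    if not score_lists:
        raise ValueError("no score lists given")
    genes = [s.gene_id for s in score_lists[0]]
    for other in score_lists[1:]:
        if [s.gene_id for s in other] != genes:
            raise ValueError("score lists cover different genes or orders")
    combined = []
    for per_gene in zip(*score_lists):
        total = sum(s.total_comparisons for s in per_gene)
        hits = sum(s.hits for s in per_gene)
        mean_auc = sum(s.mean_auc * s.total_comparisons for s in per_gene) / total
        by_direction: dict[str, tuple[int, int]] = {}
        for s in per_gene:
            by_direction.update(s.by_direction)
        combined.append(
            WindowScore(per_gene[0].gene_id, hits, total, mean_auc, by_direction)
        )
    return combined


def bidirectional_scan(
    genes: Sequence[str],
    matrix: ExpressionMatrix,
    early_extended: Sequence[str],
    late_extended: Sequence[str],
    early_core: Sequence[str],
    late_core: Sequence[str],
    window_size: int = 20,
    threshold: float = 0.8,
    kind: str = REVOLVING,
    seed: int | None = None,
    n_replicates: int = 200,
) -> list[WindowScore]:
    """The two-sided design: moving early windows vs the fixed late core,
    plus moving late windows vs the fixed early core; hit counts summed
    (2m comparisons for revolving windows)."""
    make = {
        SEQUENTIAL: lambda g: sequential_windows(g, window_size),
        REVOLVING: lambda g: revolving_windows(g, window_size),
        BOOTSTRAP: lambda g: bootstrap_windows(g, window_size, n_replicates, seed),
    }[kind]
    early_scores, _ = scan(
        genes, matrix, make(list(early_extended)), list(late_core),
        threshold, moving_is_class1=True, direction_label="early_windows",
    )
    late_scores, _ = scan(
        genes, matrix, make(list(late_extended)), list(early_core),
        threshold, moving_is_class1=False, direction_label="late_windows",
    )
    return combine_scores(early_scores, late_scores)


def all_pairs_scan(
    genes: Sequence[str],
    matrix: ExpressionMatrix,
    early_windows: WindowSet,
    late_windows: WindowSet,
    threshold: float = 0.8,
) -> tuple[list[WindowScore], pd.DataFrame]:
    """Compare every early window against every late window.

    |E| x |L| comparisons per gene (e.g. 30 x 30 = 900); returns scores plus
    the full per-gene AUC list as a genes x comparisons frame, the substrate
    for AUC-distribution plots and KS tests.
    """
    genes = list(genes)
    early_members = {c for w in early_windows.windows for c in w}
    late_members = {c for w in late_windows.windows for c in w}
    if early_members & late_members:
        raise ValueError("early and late window families share cases")

    sub = matrix.values.loc[genes]
    n_e, n_l = len(early_windows), len(late_windows)
    aucs = np.empty((len(genes), n_e * n_l), float)
    late_blocks = [sub.loc[:, w].to_numpy() for w in late_windows.windows]
    col = 0
    for we in early_windows.windows:
        e_block = sub.loc[:, we].to_numpy()
        for l_block in late_blocks:
            a = auc_matrix(e_block, l_block)
            aucs[:, col] = np.maximum(a, 1.0 - a)
            col += 1
    hits = (aucs > threshold).sum(axis=1)
    scores = [
        WindowScore(
            gene_id=g,
            hits=int(hits[i]),
            total_comparisons=n_e * n_l,
            mean_auc=float(aucs[i].mean()),
            by_direction={"all_pairs": (int(hits[i]), n_e * n_l)},
        )
        for i, g in enumerate(genes)
    ]
    table = pd.DataFrame(
        aucs, index=genes,
        columns=[f"e{i + 1}_l{j + 1}" for i in range(n_e) for j in range(n_l)],
    )
    return scores, table


def rank_genes(scores: Sequence[WindowScore], min_hits: int = 0) -> list[str]:
    """Genes with hits >= min_hits, best first.

    Sorted by hit count descending; ties broken by mean AUC descending, then
    gene id for determinism.
    """
    totals = {s.total_comparisons for s in scores}
    if len(totals) > 1:
        raise ValueError(f"scores mix different comparison totals: {sorted(totals)}")
    kept = [s for s in scores if s.hits >= min_hits]
    kept.sort(key=lambda s: (-s.hits, -s.mean_auc, s.gene_id))
    return [s.gene_id for s in kept]


def scores_frame(scores: Sequence[WindowScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {
            "gene": s.gene_id,
            "hits": s.hits,
            "total": s.total_comparisons,
            "mean_auc": s.mean_auc,
        }
        for label, (h, t) in s.by_direction.items():
            row[f"hits_{label}"] = h
            row[f"total_{label}"] = t
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
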