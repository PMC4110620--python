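"""Window families, scan hit counts, all-pairs comparisons, gene ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from extremescan import (
    ExpressionMatrix,
    LabelledCases,
    all_pairs_scan,
    bidirectional_scan,
    bootstrap_windows,
    pairwise_auc,
    rank_genes,
    revolving_windows,
    scan,
    sequential_windows,
)
from extremescan.windows import WindowScore, combine_scores


def ranks(n):
    return [f"r{i + 1}" for i in range(n)]


class TestSequentialWindows:
    def test_40_cases_window_20_gives_21_windows(self):
        ws = sequential_windows(ranks(40), 20)
        assert len(ws) == 21
        assert ws.windows[0] == ranks(40)[:20]        # ranks 1-20
        assert ws.windows[-1] == ranks(40)[20:40]     # ranks 21-40

    def test_window_equals_group(self):
        ws = sequential_windows(ranks(5), 5)
        assert len(ws) == 1 and ws.windows[0] == ranks(5)

    def test_enumeration_m5_k2(self):
        ws = sequential_windows(ranks(5), 2)
        assert ws.windows == [["r1", "r2"], ["r2", "r3"], ["r3", "r4"], ["r4", "r5"]]

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            sequential_windows(ranks(3), 4)


class TestRevolvingWindows:
    def test_40_cases_each_sampled_exactly_20_times(self):
        ws = revolving_windows(ranks(40), 20)
        assert len(ws) == 40
        assert set(ws.membership_counts().values()) == {20}

    def test_wraparound_enumeration_m5_k3(self):
        ws = revolving_windows(ranks(5), 3)
        assert ws.windows[3] == ["r4", "r5", "r1"]
        assert ws.windows[4] == ["r5", "r1", "r2"]
        assert set(ws.membership_counts().values()) == {3}

    def test_full_width_windows_are_rotations(self):
        ws = revolving_windows(ranks(4), 4)
        assert len(ws) == 4
        assert all(sorted(w) == sorted(ranks(4)) for w in ws.windows)

    @given(m=st.integers(2, 50), data=st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_coverage_property(self, m, data):
        k = data.draw(st.integers(1, m))
        ws = revolving_windows(ranks(m), k)
        assert len(ws) == m
        assert set(ws.membership_counts().values()) == {k}
        seq = sequential_windows(ranks(m), k)
        assert len(seq) == m - k + 1


class TestBootstrapWindows:
    def test_seeded_determinism_and_shape(self):
        a = bootstrap_windows(ranks(10), 4, n_replicates=25, seed=3)
        b = bootstrap_windows(ranks(10), 4, n_replicates=25, seed=3)
        assert a.windows == b.windows
        assert len(a) == 25 and all(len(set(w)) == 4 for w in a.windows)


def planted_matrix(seed=0):
    """10 genes x 14 samples; g0 strongly separates s0-6 from s7-13."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(7, 1, (10, 14))
    vals[0, :7] -= 4.0
    vals[1] = 7.0  # constant gene
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                     columns=[f"s{i}" for i in range(14)])
    )


class TestScan:
    def test_membership_overlap_rejected(self):
        m = planted_matrix()
        ws = sequential_windows([f"s{i}" for i in range(7)], 3)
        with pytest.raises(ValueError, match="overlap"):
            scan(["g0"], m, ws, ["s5", "s8"], 0.8)

    def test_constant_gene_scores_zero(self):
        m = planted_matrix()
        ws = revolving_windows([f"s{i}" for i in range(7)], 4)
        scores, _ = scan(["g1"], m, ws, [f"s{i}" for i in range(7, 14)], 0.8)
        assert scores[0].hits == 0

    def test_planted_gene_hits_everywhere(self):
        m = planted_matrix()
        ws = revolving_windows([f"s{i}" for i in range(7)], 4)
        scores, aucs = scan(["g0"], m, ws, [f"s{i}" for i in range(7, 14)], 0.8)
        assert scores[0].hits == scores[0].total_comparisons == 7
        assert (aucs.loc["g0"] > 0.8).all()

    def test_auc_table_matches_single_comparisons(self):
        m = planted_matrix(3)
        moving = revolving_windows([f"s{i}" for i in range(7)], 3)
        fixed = [f"s{i}" for i in range(7, 14)]
        _, aucs = scan(["g0", "g2", "g3"], m, moving, fixed, 0.8)
        for g in ["g0", "g2", "g3"]:
            for j, win in enumerate(moving.windows):
                x1 = m.values.loc[g, win].to_numpy()
                x0 = m.values.loc[g, fixed].to_numpy()
                assert aucs.loc[g].iloc[j] == pytest.approx(pairwise_auc(x1, x0))

    def test_hit_counts_invariant_to_gene_order(self):
        m = planted_matrix(4)
        ws = revolving_windows([f"s{i}" for i in range(7)], 4)
        fixed = [f"s{i}" for i in range(7, 14)]
        genes = [f"g{i}" for i in range(10)]
        s1, _ = scan(genes, m, ws, fixed, 0.7)
        s2, _ = scan(genes[::-1], m, ws, fixed, 0.7)
        h1 = {s.gene_id: s.hits for s in s1}
        h2 = {s.gene_id: s.hits for s in s2}
        assert h1 == h2

    def test_bad_threshold_rejected(self):
        m = planted_matrix()
        ws = revolving_windows([f"s{i}" for i in range(7)], 4)
        with pytest.raises(ValueError, match="threshold"):
            scan(["g0"], m, ws, [f"s{i}" for i in range(7, 14)], 0.4)


class TestBidirectional:
    def test_total_comparisons_is_2m(self, small_cohort, small_groups):
        g = small_groups
        scores = bidirectional_scan(
            ["G00001", "G00050"], small_cohort.expression,
            g.early_extended, g.late_extended, g.early_core, g.late_core,
        )
        assert all(s.total_comparisons == 80 for s in scores)
        for s in scores:
            assert s.by_direction["early_windows"][1] == 40
            assert s.by_direction["late_windows"][1] == 40

    def test_signal_vs_noise_hit_separation(self, small_cohort, small_groups):
        g = small_groups
        genes = small_cohort.truth.signal_genes + ["G00100", "G00200"]
        scores = bidirectional_scan(
            genes, small_cohort.expression,
            g.early_extended, g.late_extended, g.early_core, g.late_core,
        )
        hits = {s.gene_id: s.hits for s in scores}
        assert min(hits[x] for x in small_cohort.truth.signal_genes) > 60
        assert hits["G00100"] < 8 and hits["G00200"] < 8


class TestAllPairs:
    def test_30x30_gives_900_comparisons(self, small_cohort, small_groups):
        m = small_cohort.expression
        e = revolving_windows(small_groups.early_extended[:30], 20)
        l = revolving_windows(small_groups.late_extended[:30], 20)
        scores, table = all_pairs_scan(["G00001"], m, e, l)
        assert scores[0].total_comparisons == 900
        assert table.shape == (1, 900)

    def test_single_windows_reduce_to_one_comparison(self):
        m = planted_matrix()
        e = sequential_windows([f"s{i}" for i in range(7)], 7)
        l = sequential_windows([f"s{i}" for i in range(7, 14)], 7)
        scores, table = all_pairs_scan(["g0"], m, e, l)
        assert scores[0].total_comparisons == 1
        x1 = m.values.loc["g0"].iloc[:7]
        x0 = m.values.loc["g0"].iloc[7:]
        assert table.iloc[0, 0] == pytest.approx(pairwise_auc(x1, x0))

    def test_3x4_matches_loop_oracle(self):
        m = planted_matrix(5)
        e = sequential_windows([f"s{i}" for i in range(5)], 3)   # 3 windows
        l = sequential_windows([f"s{i}" for i in range(5, 11)], 3)  # 4 windows
        _, table = all_pairs_scan(["g2"], m, e, l)
        assert table.shape == (1, 12)
        col = 0
        for we in e.windows:
            for wl in l.windows:
                expected = pairwise_auc(
                    m.values.loc["g2", we], m.values.loc["g2", wl]
                )
                assert table.iloc[0, col] == pytest.approx(expected)
                col += 1

    def test_overlapping_families_rejected(self):
        m = planted_matrix()
        e = sequential_windows([f"s{i}" for i in range(7)], 3)
        with pytest.raises(ValueError, match="share"):
            all_pairs_scan(["g0"], m, e, e)


class TestRankGenes:
    def make(self, hits_by_gene, total=80):
        return [
            WindowScore(g, h, total, 0.5 + h / (2 * total), {"d": (h, total)})
            for g, h in hits_by_gene.items()
        ]

    def test_min_hits_above_total_empty(self):
        assert rank_genes(self.make({"a": 80}), min_hits=81) == []

    def test_zero_min_hits_returns_all_sorted(self):
        out = rank_genes(self.make({"a": 5, "b": 50, "c": 20}), min_hits=0)
        assert out == ["b", "c", "a"]

    def test_planted_hit_threshold(self):
        out = rank_genes(self.make({"w": 50, "x": 20, "y": 19, "z": 0}), min_hits=20)
        assert out == ["w", "x"]

    def test_mixed_totals_rejected(self):
        scores = self.make({"a": 5}) + self.make({"b": 5}, total=40)
        with pytest.raises(ValueError, match="totals"):
            rank_genes(scores)

    def test_combine_scores_sums_directions(self):
        a = self.make({"a": 10, "b": 0}, total=40)
        b = [WindowScore("a", 30, 40, 0.9, {"e": (30, 40)}),
             WindowScore("b", 1, 40, 0.4, {"e": (1, 40)})]
        merged = combine_scores(a, b)
        assert merged[0].hits == 40 and merged[0].total_comparisons == 80
        assert merged[1].hits == 1
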