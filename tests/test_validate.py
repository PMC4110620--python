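"""Leave-one-out and split-half validation, pattern clustering, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from extremescan import (
    LabelledCases,
    cluster_prediction_patterns,
    gene_correlations,
    leave_one_out,
    split_half,
)
from extremescan.validate import LooMatrix


def make_cases(values: np.ndarray, labels, genes=None):
    values = np.atleast_2d(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=genes,
                      columns=[f"s{i}" for i in range(values.shape[1])])
    return LabelledCases(df, np.asarray(labels, int))


# ------------------------------------------------------------- oracle
def loo_oracle(values, labels):
    """Fold-by-fold logistic refits done independently with scipy only."""
    values = np.atleast_2d(values)
    n = values.shape[1]
    out = np.zeros((values.shape[0], n), bool)
    for g in range(values.shape[0]):
        x_all = values[g]
        for j in range(n):
            keep = np.arange(n) != j
            x, y = x_all[keep], labels[keep]

            def neg_ll(theta):
                eta = theta[0] + theta[1] * x
                return -np.sum(y * eta - np.logaddexp(0.0, eta))

            res = optimize.minimize(neg_ll, [0.0, 0.0], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 5000})
            p = special.expit(res.x[0] + res.x[1] * x_all[j])
            out[g, j] = int(p >= 0.5) == labels[j]
    return out


class TestLeaveOneOut:
    def test_matches_fold_by_fold_oracle_4v4(self):
        rng = np.random.default_rng(17)
        # overlapping classes so no fold is separated
        vals = np.vstack([
            np.r_[rng.normal(0, 1, 4), rng.normal(1.0, 1, 4)],
            np.r_[rng.normal(0, 1, 4), rng.normal(-0.5, 1, 4)],
        ])
        labels = np.r_[np.ones(4, int), np.zeros(4, int)]
        cases = make_cases(vals, labels)
        loo = leave_one_out(["g0", "g1"], cases)
        assert np.array_equal(loo.correct.to_numpy(), loo_oracle(vals, labels))

    def test_perfectly_separated_gene_scores_one(self):
        vals = np.r_[np.full(5, 2.0), np.full(5, 8.0)] + np.linspace(0, 0.4, 10)
        cases = make_cases(vals, [1] * 5 + [0] * 5)
        loo = leave_one_out(["g0"], cases)
        assert loo.gene_accuracy["g0"] == 1.0

    def test_noise_gene_near_chance(self):
        rng = np.random.default_rng(23)
        accs = []
        for seed in range(8):
            vals = np.random.default_rng(seed).normal(0, 1, 20)
            cases = make_cases(vals, [1] * 10 + [0] * 10)
            accs.append(leave_one_out(["g0"], cases).gene_accuracy["g0"])
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_case_order_invariance(self):
        rng = np.random.default_rng(29)
        vals = rng.normal(0, 1, (2, 12))
        vals[0, :6] += 1.5
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        cases = make_cases(vals, labels)
        perm = rng.permutation(12)
        shuffled = LabelledCases(cases.values.iloc[:, perm], labels[perm])
        a = leave_one_out(["g0", "g1"], cases).gene_accuracy
        b = leave_one_out(["g0", "g1"], shuffled).gene_accuracy
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_fold_emptying_class_rejected(self):
        cases = make_cases(np.arange(4.0), [1, 0, 0, 0])
        with pytest.raises(ValueError, match="class"):
            leave_one_out(["g0"], cases)


class TestSplitHalf:
    def test_odd_class_size_rejected(self):
        cases = make_cases(np.arange(7.0), [1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="odd"):
            split_half(["g0"], cases)

    def test_duplicated_halves_equal_resubstitution(self):
        # odd- and even-indexed cases are identical, so every train/test
        # split sees the same data and the held-out AUC equals the
        # resubstitution AUC of one half
        rng = np.random.default_rng(31)
        half1 = rng.normal(1.0, 1, 5)
        half0 = rng.normal(0.0, 1, 5)
        x1 = np.repeat(half1, 2)  # s0==s1, s2==s3, ...
        x0 = np.repeat(half0, 2)
        cases = make_cases(np.r_[x1, x0], [1] * 10 + [0] * 10)
        from extremescan import pairwise_auc
        resub = pairwise_auc(half1, half0)
        result = split_half(["g0"], cases)
        assert result["g0"] == pytest.approx(resub)

    def test_matches_independent_refit_oracle(self):
        rng = np.random.default_rng(37)
        vals = np.r_[rng.normal(1.2, 1, 6), rng.normal(0, 1, 6)]
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        cases = make_cases(vals, labels)
        result = split_half(["g0"], cases)

        # independent recomputation of the same 4 evaluations
        from extremescan.logit import pairwise_auc_unfolded
        idx1, idx0 = np.arange(6), np.arange(6, 12)
        a1, b1 = idx1[::2], idx1[1::2]
        a0, b0 = idx0[::2], idx0[1::2]
        aucs = []
        for tr1, tr0, te1, te0 in [
            (a1, a0, b1, b0), (b1, b0, a1, a0),
            (a1, b0, b1, a0), (b1, a0, a1, b0),
        ]:
            x, y = vals[np.r_[tr1, tr0]], np.r_[np.ones(len(tr1)), np.zeros(len(tr0))]

            def neg_ll(theta):
                eta = theta[0] + theta[1] * x
                return -np.sum(y * eta - np.logaddexp(0.0, eta))

            res = optimize.minimize(neg_ll, [0.0, 0.0], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12})
            a = pairwise_auc_unfolded(vals[te1], vals[te0])
            aucs.append(a if res.x[1] >= 0 else 1 - a)
        assert result["g0"] == pytest.approx(np.mean(aucs), abs=1e-9)

    def test_planted_strong_gene_lands_in_validated_band(self, small_cohort, small_groups):
        cases = LabelledCases.from_groups(
            small_cohort.expression, small_groups.early_core, small_groups.late_core
        )
        result = split_half(small_cohort.truth.signal_genes, cases)
        assert result.mean() > 0.75


class TestClusterPredictionPatterns:
    def loo_from(self, rows, genes):
        df = pd.DataFrame(rows, index=genes,
                          columns=[f"s{i}" for i in range(len(rows[0]))]).astype(bool)
        labels = pd.Series([1] * (len(rows[0]) // 2) + [0] * (len(rows[0]) - len(rows[0]) // 2),
                           index=df.columns)
        return LooMatrix(df, labels)

    def test_identical_rows_merge_first(self):
        loo = self.loo_from(
            [[1, 1, 0, 1], [1, 1, 0, 1], [0, 0, 1, 0]], ["a", "b", "c"]
        )
        order, linkage, _ = cluster_prediction_patterns(loo)
        assert linkage[0, 2] == 0.0  # first merge at distance zero
        # the identical pair ends up adjacent in the display order
        assert abs(order.index("a") - order.index("b")) == 1

    def test_complementary_rows_maximal_distance(self):
        loo = self.loo_from([[1, 1, 1, 1], [0, 0, 0, 0]], ["a", "b"])
        _, linkage, _ = cluster_prediction_patterns(loo)
        assert linkage[0, 2] == 1.0  # hamming distance of complements

    def test_planted_block_structure_separated(self):
        block1 = [1, 1, 1, 1, 0, 0, 0, 0]
        block2 = [0, 0, 0, 0, 1, 1, 1, 1]
        loo = self.loo_from(
            [block1, block1, block2, block2, block2], ["a1", "a2", "b1", "b2", "b3"]
        )
        order, _, assignments = cluster_prediction_patterns(loo, cut_height=0.5)
        groups = {}
        for gene, c in zip(["a1", "a2", "b1", "b2", "b3"], assignments):
            groups.setdefault(c, set()).add(gene)
        assert {frozenset(v) for v in groups.values()} == {
            frozenset({"a1", "a2"}), frozenset({"b1", "b2", "b3"})
        }

    def test_single_gene_rejected(self):
        loo = self.loo_from([[1, 0]], ["a"])
        with pytest.raises(ValueError):
            cluster_prediction_patterns(loo)


class TestGeneCorrelations:
    def test_self_and_negation(self, small_cohort):
        m = small_cohort.expression
        import extremescan
        neg = extremescan.ExpressionMatrix(
            pd.concat([m.values, (-m.values.loc[["G00001"]]).rename(index={"G00001": "NEG"})])
        )
        r, _ = gene_correlations(neg, "G00001", ["G00001", "NEG"])
        assert r["G00001"] == pytest.approx(1.0)
        assert r["NEG"] == pytest.approx(-1.0)

    def test_planted_block_correlation_recovered(self, small_cohort, small_groups):
        sig = small_cohort.truth.signal_genes
        analysis_cases = small_groups.early_core + small_groups.late_core
        r, counts = gene_correlations(
            small_cohort.expression, sig[0], sig[1:], analysis_cases
        )
        # generator targets marginal correlation 0.75 among signal genes
        assert abs(r.mean() - 0.75) < 0.1
        assert counts[0.7] > len(sig) // 2

    def test_too_few_samples_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="3 samples"):
            gene_correlations(small_cohort.expression, "G00001", ["G00002"],
                              small_cohort.expression.sample_ids[:2])
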