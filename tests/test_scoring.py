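"""Gene-set scores, percentile calls and coexpression contingency."""

import numpy as np
import pandas as pd
import pytest

from ieilgl import scoring
from ieilgl.scoring import (
    ScoringError, build_stat3_signature, coexpression_contingency,
    geometric_mean_score, module_score, percentile_threshold,
)


def make_matrix(rng, n_cells=200, n_genes=120):
    """Distinct, evenly spread gene means so rank bins are unambiguous."""
    baselines = np.linspace(0, 4, n_genes)
    values = rng.normal(baselines, 0.3, size=(n_cells, n_genes))
    return pd.DataFrame(values,
                        index=[f"c{i}" for i in range(n_cells)],
                        columns=[f"g{j}" for j in range(n_genes)])


def dense_module_score_oracle(matrix, gene_set, n_bins):
    """Independent recomputation with whole-bin controls: sort genes by mean,
    cut into equal-size bins, use every gene of each set gene's bin as its
    control pool."""
    means = matrix.mean(axis=0)
    order = list(means.sort_values(kind="stable").index)
    bin_of = {}
    size = len(order) / n_bins
    for pos, g in enumerate(order):
        bin_of[g] = min(int(pos / size), n_bins - 1)
    control = set()
    for g in gene_set:
        control.update(h for h in order if bin_of[h] == bin_of[g])
    set_mean = matrix[list(gene_set)].mean(axis=1)
    ctrl_mean = matrix[sorted(control)].mean(axis=1)
    return set_mean - ctrl_mean


class TestModuleScore:
    def test_constant_set_vs_constant_rest(self, rng):
        # set genes constant c, other genes constant d -> score = c - d
        n_cells = 50
        df = pd.DataFrame(
            np.column_stack([np.full((n_cells, 3), 5.0), np.full((n_cells, 9), 2.0)]),
            columns=[f"g{j}" for j in range(12)])
        # one bin: controls are all genes of the single bin
        s = module_score(df, ["g0", "g1", "g2"], n_bins=1, n_ctrl=100, seed=0)
        assert np.allclose(s, 5.0 - (3 * 5.0 + 9 * 2.0) / 12)

    def test_degenerate_controls_equal_set(self):
        # matrix containing only the set genes, one bin -> self-subtraction
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)),
                          columns=list("abcd"))
        s = module_score(df, list("abcd"), n_bins=1, n_ctrl=10, seed=0)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_matches_dense_oracle_with_whole_bin_controls(self, rng):
        matrix = make_matrix(rng)
        gene_set = ["g5", "g50", "g90", "g115"]
        # n_ctrl >= bin size makes the control draw deterministic (whole bin)
        got = module_score(matrix, gene_set, n_bins=10, n_ctrl=1000, seed=1)
        want = dense_module_score_oracle(matrix, gene_set, n_bins=10)
        assert np.allclose(got, want, atol=1e-10)

    def test_shift_invariance(self, rng):
        matrix = make_matrix(rng)
        gene_set = ["g10", "g60"]
        a = module_score(matrix, gene_set, seed=3)
        b = module_score(matrix + 7.5, gene_set, seed=3)
        assert np.allclose(a, b, atol=1e-9)

    def test_cell_permutation_equivariance(self, rng):
        matrix = make_matrix(rng)
        gene_set = ["g10", "g60"]
        perm = rng.permutation(matrix.index)
        a = module_score(matrix, gene_set, seed=3).loc[perm]
        b = module_score(matrix.loc[perm], gene_set, seed=3)
        assert np.allclose(a, b, atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        matrix = make_matrix(rng)
        a = module_score(matrix, ["g3", "g80"], seed=9)
        b = module_score(matrix, ["g3", "g80"], seed=9)
        assert a.equals(b)

    def test_missing_all_genes_rejected(self, rng):
        with pytest.raises(ScoringError):
            module_score(make_matrix(rng), ["nope"])

    def test_agrees_with_scanpy_cross_check(self, rng):
        """Independent binned-control implementation (scanpy score_genes)
        ranks cells the same way on a shifted fixture."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        matrix = make_matrix(rng, n_cells=150)
        matrix.iloc[:50, [5, 50, 90]] += 1.0  # planted high-score cells
        gene_set = ["g5", "g50", "g90"]
        mine = module_score(matrix, gene_set, n_bins=10, n_ctrl=1000, seed=0)
        adata = ad.AnnData(matrix.to_numpy(), obs=pd.DataFrame(index=matrix.index),
                           var=pd.DataFrame(index=matrix.columns))
        sc.tl.score_genes(adata, gene_set, ctrl_size=1000, n_bins=10, score_name="sc")
        theirs = adata.obs["sc"]
        rho = pd.Series(mine).corr(pd.Series(theirs.to_numpy(), index=mine.index),
                                   method="spearman")
        assert rho > 0.9


class TestGeometricMeanScore:
    def test_equal_values_identity(self):
        df = pd.DataFrame({"a": [3.0, 7.0], "b": [3.0, 7.0]}, index=["s1", "s2"])
        s = geometric_mean_score(df, ["a", "b"], pseudocount=0.0)
        assert np.allclose(s, [3.0, 7.0])

    def test_hand_arithmetic(self):
        df = pd.DataFrame({"a": [1.0], "b": [4.0]})
        assert geometric_mean_score(df, ["a", "b"], 0.0).iloc[0] == pytest.approx(2.0)

    def test_matches_log_domain_oracle(self, rng):
        df = pd.DataFrame(rng.lognormal(0, 1, size=(10, 6)),
                          columns=[f"g{i}" for i in range(6)])
        s = geometric_mean_score(df, list(df.columns), pseudocount=0.5)
        want = np.exp(np.log(df.to_numpy() + 0.5).mean(axis=1))
        assert np.allclose(s, want)

    def test_negative_expression_rejected(self):
        df = pd.DataFrame({"a": [-1.0]})
        with pytest.raises(ScoringError):
            geometric_mean_score(df, ["a"])


class TestSignatureConstruction:
    def test_disjoint_lists_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert build_stat3_signature(["A", "B"], [["C"], ["D"]]) == []

    def test_nine_gene_overlap(self):
        internal = [f"UP{i}" for i in range(20)]
        ext1 = internal[:5] + ["X1", "X2"]
        ext2 = internal[3:9] + ["Y1"]
        sig = build_stat3_signature(internal, [ext1, ext2])
        assert sig == internal[:9]
        assert len(sig) == 9

    def test_matches_set_algebra_oracle(self, rng):
        pool = [f"G{i}" for i in range(60)]
        internal = list(rng.choice(pool, size=30, replace=False))
        exts = [list(rng.choice(pool, size=15, replace=False)) for _ in range(3)]
        sig = build_stat3_signature(internal, exts)
        want = [g for g in internal if g in set().union(*map(set, exts))]
        assert sig == want


class TestPercentileThreshold:
    def test_hundred_distinct_scores_ten_high(self):
        scores = pd.Series(np.arange(100, dtype=float))
        high = percentile_threshold(scores, 0.90)
        assert int(high.sum()) == 10  # strictly above the 90th percentile

    def test_constant_scores_all_low(self):
        with pytest.warns(UserWarning):
            high = percentile_threshold(pd.Series([1.0] * 50), 0.90)
        assert not high.any()

    def test_matches_sort_oracle(self, rng):
        scores = pd.Series(rng.normal(size=137))
        high = percentile_threshold(scores, 0.90)
        thr = float(np.quantile(scores, 0.90))
        assert (high == (scores > thr)).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ScoringError):
            percentile_threshold(pd.Series([1.0, 2.0]), 0.9)


class TestCoexpression:
    def make(self, fracs_a, n=1000):
        idx, groups, a, b = [], [], [], []
        for g, fa in fracs_a.items():
            for i in range(n):
                idx.append(f"{g}_{i}")
                groups.append(g)
                a.append(i < fa * n)
                b.append(i % 50 == 0)
        index = pd.Index(idx)
        return (pd.Series(a, index=index), pd.Series(b, index=index),
                pd.Series(groups, index=index))

    def test_group_proportions_and_chi2(self):
        a, b, groups = self.make({"STAT3mt": 0.14, "STAT3wt": 0.08,
                                  "healthy_control": 0.02})
        out = coexpression_contingency(a, b, groups, "STAT3", "TCR")
        assert out["per_group"]["STAT3mt"]["STAT3_high_frac"] == pytest.approx(0.14)
        assert out["STAT3_chi2_p"] < 0.0001

    def test_all_false_flags(self):
        a, b, groups = self.make({"STAT3mt": 0.0, "STAT3wt": 0.0})
        b[:] = False
        out = coexpression_contingency(a, b, groups)
        for g in out["per_group"].values():
            assert g["A_high_frac"] == 0.0
            assert g["double_high_frac"] == 0.0

    def test_single_group_skips_chi2(self):
        a, b, groups = self.make({"STAT3mt": 0.1})
        out = coexpression_contingency(a, b, groups)
        assert "A_chi2" not in out
        assert "STAT3mt" in out["per_group"]

    def test_misaligned_flags_rejected(self):
        a, b, groups = self.make({"STAT3mt": 0.1})
        with pytest.raises(ScoringError):
            coexpression_contingency(a.iloc[:-1], b, groups)
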