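"""Wilcoxon DEG, BH, ORA and proportion statistics against oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stroi.model import DEGTable, GeneSetLibrary, SpotAssignment, SpotLabel
from stroi.stats import (
    _rank_sum_p,
    bh_adjust,
    celltype_proportions,
    classify_degs,
    ora,
    top_degs,
    wilcoxon_deg,
)
from tests.conftest import tiny_dataset


# ---------------------------------------------------------------------------
# independent oracles

def permutation_p(a, b):
    """Exact two-sided rank-sum permutation p for small groups."""
    from scipy.stats import rankdata

    n1 = len(a)
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    mu = n1 * (len(b)) / 2.0  # mean of U1
    def u1(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
    observed = abs(u1(range(n1)) - mu)
    total = hits = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        total += 1
        if abs(u1(idx) - mu) >= observed - 1e-9:
            hits += 1
    return hits / total


def bh_oracle(p):
    """Closed-form step-up, written independently (scalar loop)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    term = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def make_assignment(n1, n2):
    labels = [SpotLabel.ROI1] * n1 + [SpotLabel.ROI2] * n2
    return SpotAssignment(labels=labels,
                          containing_mask_ids=[set() for _ in labels])


def dataset_with_normalized(X1, X2):
    X = np.vstack([X1, X2])
    ds = tiny_dataset(np.ones_like(X, dtype=int),
                      fullres_xy=[(1.0, 1.0)] * X.shape[0])
    ds.normalized = X.astype(float)
    return ds, make_assignment(X1.shape[0], X2.shape[0])


# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_independent_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_array_equal(bh_adjust(p), bh_oracle(list(p)))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_monotone_after_step_up(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRankSum:
    def test_extreme_separation_close_to_exact_permutation(self):
        a = np.array([5.0, 6.0, 7.0, 8.0])
        b = np.array([1.0, 2.0, 3.0, 4.0])
        exact = permutation_p(a, b)
        assert exact == pytest.approx(2 / 70)
        assert _rank_sum_p(a, b) == pytest.approx(exact, abs=0.02)

    def test_matches_permutation_oracle_and_order(self):
        rng = np.random.default_rng(2024)
        approx, exact = [], []
        for _ in range(200):
            a = rng.normal(size=6)
            b = rng.normal(size=6)
            approx.append(_rank_sum_p(a, b))
            exact.append(permutation_p(a, b))
        approx, exact = np.array(approx), np.array(exact)
        assert np.max(np.abs(approx - exact)) < 0.02
        # identical ranking: sorting by the approximation never decreases
        # the exact p (ties in the discrete exact p allowed)
        order = np.argsort(approx, kind="mergesort")
        assert np.all(np.diff(exact[order]) >= -1e-12)

    def test_tie_corrected_approximation_matches_mannwhitneyu(self):
        # independent cross-check of the tie-corrected normal approximation
        # (scipy computes the same z from the U statistic)
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 4, size=15).astype(float)
            b = rng.integers(0, 4, size=18).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            expected = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
            assert _rank_sum_p(a, b) == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_small_tie_free_groups_use_exact_null(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(2, 9)))
            b = rng.normal(size=int(rng.integers(2, 9)))
            assert _rank_sum_p(a, b) == pytest.approx(permutation_p(a, b), rel=1e-12)

    def test_all_tied_gives_p_one(self):
        assert _rank_sum_p(np.zeros(4), np.zeros(4)) == 1.0

    def test_global_null_type_I_calibration(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(100, 500))
        p = np.array([_rank_sum_p(X[:50, g], X[50:, g]) for g in range(500)])
        frac = float((p < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestWilcoxonDEG:
    def test_identical_groups_null(self):
        X = np.tile(np.linspace(0, 2, 8)[:, None], (1, 5))
        ds, assignment = dataset_with_normalized(X[:4], X[:4])
        degs = wilcoxon_deg(ds, assignment)
        np.testing.assert_array_equal(degs.table["p_value"], 1.0)
        np.testing.assert_allclose(degs.table["log_fc"], 0.0, atol=1e-9)

    def test_gene_zero_in_both_groups_convention(self):
        X = np.zeros((6, 2))
        X[:, 0] = [1, 2, 3, 4, 5, 6]
        ds, assignment = dataset_with_normalized(X[:3], X[3:])
        degs = wilcoxon_deg(ds, assignment)
        assert degs.table.loc[1, "p_value"] == 1.0
        assert degs.table.loc[1, "log_fc"] == 0.0

    def test_logfc_formula_closed_form(self):
        X1 = np.log1p(np.full((3, 1), 4.0))  # expm1 mean = 4
        X2 = np.log1p(np.full((3, 1), 1.0))  # expm1 mean = 1
        ds, assignment = dataset_with_normalized(X1, X2)
        degs = wilcoxon_deg(ds, assignment, pseudocount=0.0)
        assert degs.table.loc[0, "log_fc"] == pytest.approx(2.0, abs=1e-9)
        assert degs.table.loc[0, "mean_roi1"] == pytest.approx(4.0)

    def test_group_size_validation(self):
        X = np.ones((3, 2))
        ds, _ = dataset_with_normalized(X[:1], X[1:])
        with pytest.raises(ValueError, match=">= 2"):
            wilcoxon_deg(ds, make_assignment(1, 2))
        ds.normalized = None
        with pytest.raises(ValueError, match="normalized"):
            wilcoxon_deg(ds, make_assignment(2, 1))

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        X1 = rng.exponential(size=(8, 40))
        X2 = rng.exponential(size=(10, 40))
        ds, a12 = dataset_with_normalized(X1, X2)
        ds2, _ = dataset_with_normalized(X2, X1)
        a21 = make_assignment(10, 8)
        d12 = wilcoxon_deg(ds, a12)
        d21 = wilcoxon_deg(ds2, a21)
        np.testing.assert_allclose(
            d12.table["log_fc"], -d21.table["log_fc"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            d12.table["p_value"], d21.table["p_value"].to_numpy(), atol=1e-12
        )

    def test_p_values_match_scanpy(self):
        """Independent cross-check against the single-cell reference routine."""
        import warnings
        import anndata as ad
        import scanpy as sc

        rng = np.random.default_rng(12)
        X = rng.lognormal(size=(40, 30))
        ds, assignment = dataset_with_normalized(X[:20], X[20:])
        degs = wilcoxon_deg(ds, assignment)

        adata = ad.AnnData(X=X)
        adata.var_names = ds.gene_ids
        adata.obs["roi"] = ["ROI1"] * 20 + ["ROI2"] * 20
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.rank_genes_groups(
                adata, "roi", groups=["ROI1"], reference="ROI2", method="wilcoxon"
            )
        sc_p = pd.Series(
            adata.uns["rank_genes_groups"]["pvals"]["ROI1"],
            index=adata.uns["rank_genes_groups"]["names"]["ROI1"],
        )
        ours = degs.table.set_index("gene")["p_value"]
        np.testing.assert_allclose(ours[sc_p.index], sc_p, atol=1e-8)


class TestClassifyAndTop:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["gene", "log_fc", "p_adj"])
        df["p_value"] = df["p_adj"]
        df["mean_roi1"] = 1.0
        df["mean_roi2"] = 1.0
        df["group"] = "ns"
        return DEGTable(table=df)

    def test_classification_rules_and_boundary(self):
        t = self._table([
            ("up", 2.0, 0.001), ("down", -2.0, 0.001),
            ("at_cutoff", 1.0, 0.001), ("not_sig", 3.0, 0.5),
        ])
        out = classify_degs(t, 1.0, 0.05).table.set_index("gene")["group"]
        assert out["up"] == "up_roi1"
        assert out["down"] == "up_roi2"
        assert out["at_cutoff"] == "ns"  # strict inequality at the cutoff
        assert out["not_sig"] == "ns"

    def test_negative_cutoffs_rejected(self):
        t = self._table([("g", 1.0, 0.01)])
        with pytest.raises(ValueError):
            classify_degs(t, -1.0, 0.05)

    def test_top_returns_all_when_fewer_than_n(self):
        t = classify_degs(self._table([
            ("a", 2.0, 0.001), ("b", 3.0, 0.001), ("c", 1.5, 0.001),
        ]), 1.0, 0.05)
        assert top_degs(t, 10) == ["b", "a", "c"]

    def test_tie_broken_by_padj_then_gene(self):
        t = classify_degs(self._table([
            ("zzz", 2.0, 0.010), ("aaa", 2.0, 0.010), ("mid", 2.0, 0.002),
        ]), 1.0, 0.05)
        assert top_degs(t, 3) == ["mid", "aaa", "zzz"]

    def test_order_matches_oracle_sort(self):
        rng = np.random.default_rng(77)
        rows = [(f"G{i:03d}", float(rng.choice([1.5, 2.0, 3.0])),
                 float(rng.choice([0.001, 0.01, 0.04, 0.2]))) for i in range(200)]
        t = classify_degs(self._table(rows), 1.0, 0.05)
        got = top_degs(t, 10)
        eligible = [(g, fc, pa) for g, fc, pa in rows if fc > 1.0 and pa < 0.05]
        oracle = [g for g, _, _ in sorted(eligible, key=lambda r: (-r[1], r[2], r[0]))]
        assert got == oracle[:10]


class TestORA:
    def _lib(self, **terms):
        return GeneSetLibrary("lib", {k: set(v) for k, v in terms.items()})

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        lib = self._lib(T=universe[:5])
        out = ora(universe[10:15], lib, universe).table
        assert out.loc[0, "k"] == 0
        assert out.loc[0, "p_value"] == 1.0

    def test_complete_overlap_closed_form(self):
        universe = [f"G{i}" for i in range(20)]
        lib = self._lib(T=universe[:5])
        out = ora(universe[:5], lib, universe).table
        assert out.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = [f"G{i}" for i in range(N)]
        term = universe[:K]
        query = list(rng.choice(universe, size=n, replace=False))
        k = len(set(query) & set(term))
        out = ora(query, self._lib(T=term), universe).table
        assert out.loc[0, "k"] == k
        assert out.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail_oracle(N, K, n, k), rel=1e-9
        )

    def test_p_monotone_nonincreasing_in_k(self):
        from scipy.stats import hypergeom
        N, K, n = 50, 12, 9
        tails = [float(hypergeom.sf(k - 1, N, K, n)) for k in range(0, n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_case_insensitive_matching_and_empty_universe_error(self):
        universe = ["Abca1", "Tp53", "Gapdh", "Actb"]
        lib = self._lib(T=["ABCA1", "TP53"])
        out = ora(["abca1", "tp53"], lib, universe).table
        assert out.loc[0, "k"] == 2
        with pytest.raises(ValueError, match="case"):
            ora(["NOT_PRESENT"], lib, universe)

    def test_terms_outside_universe_skipped_and_reported_flag(self):
        universe = [f"G{i}" for i in range(30)]
        lib = self._lib(IN=universe[:6], OUT=["X1", "X2"])
        res = ora(universe[:6], lib, universe, padj_keep=0.05)
        assert list(res.table["term"]) == ["IN"]
        assert bool(res.table.loc[0, "reported"]) == (res.table.loc[0, "p_adj"] < 0.05)


class TestCellTypeProportions:
    def _fractions(self, n, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(4), size=n)
        return pd.DataFrame(f, index=[f"BC{i}" for i in range(n)],
                            columns=list("abcd"))

    def test_single_spot_per_roi(self):
        frac = self._fractions(2)
        a = make_assignment(1, 1)
        props = celltype_proportions(frac, a, ["BC0", "BC1"])
        np.testing.assert_allclose(props.roi_means.loc["ROI1"], frac.iloc[0])
        np.testing.assert_allclose(props.roi_means.loc["ROI2"], frac.iloc[1])

    def test_means_sum_to_one_and_match_groupby_oracle(self):
        frac = self._fractions(50, seed=4)
        a = make_assignment(20, 30)
        props = celltype_proportions(frac, a, list(frac.index))
        np.testing.assert_allclose(props.roi_means.sum(axis=1), 1.0, atol=1e-6)
        oracle1 = frac.iloc[:20].mean(axis=0)
        oracle2 = frac.iloc[20:].mean(axis=0)
        np.testing.assert_allclose(props.roi_means.loc["ROI1"], oracle1, atol=1e-12)
        np.testing.assert_allclose(props.roi_means.loc["ROI2"], oracle2, atol=1e-12)
        assert props.roi_counts == {"ROI1": 20, "ROI2": 30}

    def test_missing_barcode_listed(self):
        frac = self._fractions(3)
        a = make_assignment(2, 2)
        with pytest.raises(ValueError, match="missing"):
            celltype_proportions(frac, a, ["BC0", "BC1", "BC2", "GHOST"])
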