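"""Overlap significance, hierarchical clustering, branch composition tests."""
import io as std_io
import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epidrift import concordance as cc
from epidrift.screen import assign_groups
from epidrift.types import BetaMatrix, ExprMatrix, GroupAssignment

from conftest import make_samples


def exact_overlap_tail(k: int, universe: int, na: int, nb: int) -> Fraction:
    """Exact upper-tail hypergeometric by enumeration (Fraction arithmetic)."""
    total = comb(universe, nb)
    return Fraction(
        sum(comb(na, j) * comb(universe - na, nb - j)
            for j in range(k, min(na, nb) + 1) if nb - j <= universe - na),
        total,
    )


class TestHypergeometricOverlap:
    def test_identical_five_gene_sets_in_universe_twenty(self):
        genes = {f"g{i}" for i in range(5)}
        res = cc.intersect_candidates(genes, genes, 20)
        assert len(res.overlap) == 5
        assert res.p_value == pytest.approx(1 / 15504, rel=1e-12)

    def test_disjoint_sets_give_p_one(self):
        res = cc.intersect_candidates({"a", "b"}, {"c", "d"}, 10)
        assert res.overlap == set()
        assert res.p_value == pytest.approx(1.0)

    @given(
        universe=st.integers(5, 25),
        na=st.integers(1, 12),
        nb=st.integers(1, 12),
        data=st.data(),
    )
    @settings(max_examples=60)
    def test_matches_exact_enumeration_for_small_universes(self, universe, na, nb, data):
        na, nb = min(na, universe), min(nb, universe)
        k = data.draw(st.integers(max(0, na + nb - universe), min(na, nb)))
        expected = float(exact_overlap_tail(k, universe, na, nb))
        got = cc.hypergeom_overlap_pvalue(k, universe, na, nb)
        assert got == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("universe", [500, 2000, 10_000, 45_000])
    def test_cross_implementation_agreement_on_19_40_overlap_10(self, universe):
        # independent route: scipy's hypergeometric survival function
        ours = cc.hypergeom_overlap_pvalue(10, universe, 19, 40)
        ref = float(stats.hypergeom.sf(9, universe, 19, 40))
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_log_space_survives_extreme_tails(self):
        logp = cc.hypergeom_overlap_logp(19, 20_000, 19, 40)
        assert np.isfinite(logp)
        assert logp / np.log(10) < -50  # far below double underflow of naive products

    def test_monotone_in_overlap_size(self):
        ps = [cc.hypergeom_overlap_pvalue(k, 1000, 30, 40) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_agrees_with_monte_carlo_for_moderate_p(self):
        universe, na, nb, k = 50, 10, 10, 4
        p = cc.hypergeom_overlap_pvalue(k, universe, na, nb)
        rng = np.random.default_rng(0)
        n_draws = 20_000
        hits = sum(
            len(set(rng.choice(universe, nb, replace=False)) & set(range(na))) >= k
            for _ in range(n_draws)
        )
        se = np.sqrt(p * (1 - p) / n_draws)
        assert abs(hits / n_draws - p) < 3 * se

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cc.intersect_candidates({"a", "b"}, {"c"}, 2)


def exact_fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher by full enumeration with exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    observed = probs[a]
    return sum(p for p in probs.values() if p <= observed)


class TestBranchCompositionTest:
    def _groups(self, labels):
        return GroupAssignment(
            mode="strict", labels=pd.Series(labels, index=[f"s{i}" for i in range(len(labels))])
        )

    def _branches(self, assignment):
        return pd.Series(assignment, index=[f"s{i}" for i in range(len(assignment))])

    def test_perfect_separation_five_five(self):
        groups = self._groups(["low"] * 5 + ["high"] * 5)
        branches = self._branches([1] * 5 + [2] * 5)
        res = cc.branch_composition_test(branches, groups)
        assert res.branch_counts == [[5, 0], [0, 5]]
        assert res.fisher_p == pytest.approx(2 / 252, rel=1e-9)

    def test_perfectly_balanced_table_gives_p_one(self):
        groups = self._groups(["low", "low", "low", "high", "high", "high"] * 2)
        branches = self._branches([1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2])
        res = cc.branch_composition_test(branches, groups)
        assert res.branch_counts == [[3, 3], [3, 3]]
        assert res.fisher_p == pytest.approx(1.0)

    def test_swapping_branch_labels_preserves_p(self):
        groups = self._groups(["low"] * 4 + ["high"] * 6)
        branches = self._branches([1, 1, 2, 1, 2, 2, 2, 1, 2, 2])
        res1 = cc.branch_composition_test(branches, groups)
        res2 = cc.branch_composition_test(3 - branches, groups)
        assert res1.fisher_p == pytest.approx(res2.fisher_p, rel=1e-12)

    def test_matches_exact_enumeration_on_sampled_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            labels = ["low"] * (a + c) + ["high"] * (b + d)
            branch = [1] * a + [2] * c + [1] * b + [2] * d
            groups = self._groups(labels)
            res = cc.branch_composition_test(self._branches(branch), groups)
            expected = float(exact_fisher_two_sided([[a, b], [c, d]]))
            assert res.fisher_p == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin_warns_and_returns_one(self):
        groups = self._groups(["low"] * 6)
        branches = self._branches([1, 1, 1, 2, 2, 2])
        with pytest.warns(UserWarning, match="degenerate"):
            res = cc.branch_composition_test(branches, groups)
        assert res.fisher_p == 1.0


def _two_group_matrix(seed=0, n_features=30, shift=4.0):
    # shared probe-level profile + per-sample noise, with a block shift in
    # half the features for samples s4..s7 — two clean correlation groups
    rng = np.random.default_rng(seed)
    mu = rng.normal(0, 2, n_features)
    data = pd.DataFrame(
        mu[:, None] + rng.normal(0, 0.3, (n_features, 8)),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{i}" for i in range(8)],
    )
    data.iloc[: n_features // 2, 4:] += shift
    return ExprMatrix(data)


class TestHierarchicalCluster:
    def test_separated_groups_recovered_as_main_branches(self):
        res = cc.hierarchical_cluster(_two_group_matrix(), distance="pearson")
        b = res.branches
        assert set(b[["s0", "s1", "s2", "s3"]]) != set(b[["s4", "s5", "s6", "s7"]])
        assert b["s0"] == b["s1"] == b["s2"] == b["s3"]
        assert b["s4"] == b["s5"] == b["s6"] == b["s7"]

    def test_euclidean_variant_agrees_on_well_separated_data(self):
        res = cc.hierarchical_cluster(_two_group_matrix(), distance="euclidean")
        b = res.branches
        assert b["s0"] == b["s3"] and b["s4"] == b["s7"] and b["s0"] != b["s4"]

    def test_duplicate_samples_merge_at_zero_distance(self):
        m = _two_group_matrix()
        data = m.data.copy()
        data["s1"] = data["s0"]
        res = cc.hierarchical_cluster(ExprMatrix(data))
        assert res.branches["s0"] == res.branches["s1"]
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_rejected_under_pearson(self):
        m = _two_group_matrix()
        data = m.data.copy()
        data["s2"] = 1.0
        with pytest.raises(ValueError, match="s2"):
            cc.hierarchical_cluster(ExprMatrix(data), distance="pearson")

    def test_newick_export_round_trips_leaf_names(self):
        from Bio import Phylo

        res = cc.hierarchical_cluster(_two_group_matrix())
        tree = Phylo.read(std_io.StringIO(res.to_newick()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(res.samples)

    def test_missing_features_dropped_before_distances(self):
        m = _two_group_matrix()
        data = m.data.copy()
        data.iloc[0, 0] = np.nan
        res = cc.hierarchical_cluster(ExprMatrix(data))
        assert len(res.samples) == 8  # feature dropped, not the sample


class TestStratifiedClustering:
    def _setup(self):
        m = _two_group_matrix(seed=3)
        samples = make_samples(
            [5, 10, 15, 20, 60, 70, 80, 90],
            sex=["female", "female", "male", "male"] * 2,
        )
        groups = assign_groups(samples, "strict")
        # sample ids must match the matrix columns
        samples.data.index = m.data.columns
        groups.labels.index = m.data.columns
        return m, samples, groups

    def test_single_sex_input_yields_one_stratum(self):
        m, samples, groups = self._setup()
        samples.data["sex"] = "female"
        out = cc.stratified_clustering(m, samples, groups, stratify_by="sex", min_stratum=4)
        assert len(out) == 1 and out[0].stratum == "female"

    def test_stratify_none_equals_plain_clustering(self):
        m, samples, groups = self._setup()
        out = cc.stratified_clustering(m, samples, groups, stratify_by="none")
        plain = cc.branch_composition_test(cc.hierarchical_cluster(m).branches, groups)
        assert out[0].branch_counts == plain.branch_counts
        assert out[0].fisher_p == pytest.approx(plain.fisher_p)

    def test_small_stratum_skipped_with_warning(self):
        m, samples, groups = self._setup()
        samples.data["sex"] = ["female"] * 6 + ["male"] * 2
        with pytest.warns(UserWarning, match="skipped"):
            out = cc.stratified_clustering(m, samples, groups, stratify_by="sex", min_stratum=4)
        assert [t.stratum for t in out] == ["female"]
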