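"""Group assignment, the delta-beta/fold screen, and Wilcoxon validation."""
import numpy as np
import pandas as pd
import pytest

from epidrift import screen as es
from epidrift.preprocess import apply_expression_floor, filter_probes
from epidrift.simulate import SimConfig, simulate_dataset
from epidrift.types import BetaMatrix, ExprMatrix

from conftest import make_annotation, make_samples


class TestAssignGroups:
    @pytest.mark.parametrize(
        "passage,mode,expected",
        [
            (25, "strict", "low"),
            (30, "strict", "excluded"),
            (30, "permissive", "high"),
            (50, "strict", "high"),
            (26, "permissive", "high"),
            (0, "strict", "low"),
        ],
    )
    def test_passage_boundaries(self, passage, mode, expected):
        samples = make_samples([5, 90, passage])
        ga = es.assign_groups(samples, mode)
        assert ga.labels["s2"] == expected

    def test_qc_failures_excluded(self):
        samples = make_samples([5, 10, 90, 95], qc_pass=[True, False, True, True])
        ga = es.assign_groups(samples, "strict")
        assert ga.labels["s1"] == "excluded"
        assert ga.counts() == {"low": 1, "high": 2, "excluded": 1}

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="empty passage group"):
            es.assign_groups(make_samples([5, 10, 15]), "strict")


def _screen_fixture(beta_low, beta_high, expr_low, expr_high, n_per_group=4):
    """One gene, one methylation + one expression probe, constant groups."""
    samples = make_samples([10] * n_per_group + [60] * n_per_group)
    groups = es.assign_groups(samples, "strict")
    cols = list(samples.data.index)
    beta = BetaMatrix(pd.DataFrame(
        [[beta_low] * n_per_group + [beta_high] * n_per_group], index=["b0"], columns=cols
    ))
    expr = ExprMatrix(pd.DataFrame(
        [[expr_low] * n_per_group + [expr_high] * n_per_group], index=["e0"], columns=cols
    ), floor=0.0)
    ann = make_annotation([
        ("b0", "g0", "1", 100, True, "meth27k"),
        ("e0", "g0", "1", 100, False, "expr_array"),
    ])
    return es.screen_probes(beta, expr, ann, groups)


class TestScreenProbes:
    def test_candidate_above_both_cutoffs(self):
        # delta beta 0.25, fold 2 -> candidate
        rec = _screen_fixture(0.10, 0.35, np.log2(8.0), np.log2(4.0))
        assert rec.loc["b0", "delta_beta"] == pytest.approx(0.25)
        assert rec.loc["b0", "expr_fold"] == pytest.approx(2.0)
        assert bool(rec.loc["b0", "candidate"])
        assert rec.loc["b0", "quadrant"] == "hyper_down"

    def test_cutoffs_are_strict_inequalities(self):
        rec = _screen_fixture(0.10, 0.30, np.log2(8.0), np.log2(4.0))  # delta = 0.2 exactly
        assert rec.loc["b0", "delta_beta"] == pytest.approx(0.2)
        assert not bool(rec.loc["b0", "candidate"])
        rec = _screen_fixture(0.10, 0.35, np.log2(6.0), np.log2(4.0))  # fold = 1.5 exactly
        assert rec.loc["b0", "expr_fold"] == pytest.approx(1.5)
        assert not bool(rec.loc["b0", "candidate"])

    def test_hypomethylated_upregulated_quadrant_reported_not_flagged(self):
        rec = _screen_fixture(0.60, 0.20, np.log2(4.0), np.log2(16.0))
        assert rec.loc["b0", "quadrant"] == "hypo_up"
        assert not bool(rec.loc["b0", "candidate"])

    def test_too_few_samples_marks_unevaluable(self):
        samples = make_samples([10, 10, 10, 10, 60, 60, 60, 60])
        groups = es.assign_groups(samples, "strict")
        cols = list(samples.data.index)
        b = pd.DataFrame([[0.1] * 4 + [0.4] * 4], index=["b0"], columns=cols)
        b.loc["b0", cols[:2]] = np.nan  # only 2 usable low samples
        expr = ExprMatrix(pd.DataFrame([[3.0] * 4 + [1.0] * 4], index=["e0"], columns=cols), floor=0.0)
        ann = make_annotation([
            ("b0", "g0", "1", 100, True, "meth27k"),
            ("e0", "g0", "1", 100, False, "expr_array"),
        ])
        rec = es.screen_probes(BetaMatrix(b), expr, ann, groups)
        assert rec.loc["b0", "quadrant"] == "unevaluable"
        assert not bool(rec.loc["b0", "candidate"])

    def test_mean_and_median_aggregates_agree_on_symmetric_data(self):
        samples = make_samples([10, 10, 10, 60, 60, 60])
        groups = es.assign_groups(samples, "strict")
        cols = list(samples.data.index)
        # symmetric values around the group centers
        b = pd.DataFrame([[0.1, 0.2, 0.3, 0.5, 0.6, 0.7]], index=["b0"], columns=cols)
        expr = ExprMatrix(pd.DataFrame([[5, 6, 7, 3, 4, 5]], index=["e0"], columns=cols,
                                       dtype=float), floor=0.0)
        ann = make_annotation([
            ("b0", "g0", "1", 100, True, "meth27k"),
            ("e0", "g0", "1", 100, False, "expr_array"),
        ])
        r_mean = es.screen_probes(BetaMatrix(b), expr, ann, groups, beta_aggregate="mean")
        r_median = es.screen_probes(BetaMatrix(b), expr, ann, groups, beta_aggregate="median")
        assert r_mean.loc["b0", "delta_beta"] == pytest.approx(r_median.loc["b0", "delta_beta"])

    def test_multi_probe_gene_uses_highest_expressed_probe(self):
        samples = make_samples([10, 10, 10, 60, 60, 60])
        groups = es.assign_groups(samples, "strict")
        cols = list(samples.data.index)
        b = BetaMatrix(pd.DataFrame([[0.1, 0.1, 0.1, 0.5, 0.5, 0.5]], index=["b0"], columns=cols))
        e = pd.DataFrame(
            [[1.0] * 6, [8, 8, 8, 5, 5, 5]], index=["e_low", "e_high"], columns=cols, dtype=float
        )
        ann = make_annotation([
            ("b0", "g0", "1", 100, True, "meth27k"),
            ("e_low", "g0", "1", 100, False, "expr_array"),
            ("e_high", "g0", "1", 150, False, "expr_array"),
        ])
        rec = es.screen_probes(b, ExprMatrix(e, floor=0.0), ann, groups)
        assert rec.loc["b0", "expr_fold"] == pytest.approx(8.0)  # from e_high

    def test_invariant_to_sample_and_probe_order(self, small_sim, small_cfg):
        expr = apply_expression_floor(small_sim.expr, small_cfg.expr_floor)
        groups = es.assign_groups(small_sim.samples, "strict")
        rec1 = es.screen_probes(small_sim.beta, expr, small_sim.annotation, groups)
        rng = np.random.default_rng(3)
        bperm = BetaMatrix(small_sim.beta.data.sample(frac=1, random_state=5)[
            rng.permutation(small_sim.beta.data.columns)
        ])
        eperm = ExprMatrix(
            small_sim.expr.data.sample(frac=1, random_state=6)[bperm.data.columns],
            floor=None,
        )
        rec2 = es.screen_probes(
            bperm, apply_expression_floor(eperm, small_cfg.expr_floor),
            small_sim.annotation, groups,
        )
        pd.testing.assert_frame_equal(rec1, rec2)


class TestNoiseFreeRecovery:
    def test_drift_genes_candidates_with_perfect_anticorrelation(self, noise_free_sim):
        # floor below the data range: correlation is exactly linear (no
        # floor flattening), so drift probes anticorrelate perfectly
        floor = float(noise_free_sim.expr.data.min().min()) - 1.0
        expr = apply_expression_floor(noise_free_sim.expr, floor)
        groups = es.assign_groups(noise_free_sim.samples, "strict")
        filt = filter_probes(noise_free_sim.beta, expr, noise_free_sim.annotation,
                             noise_free_sim.samples, groups)
        rec = es.screen_probes(filt.beta, filt.expr, noise_free_sim.annotation, groups)
        genes, report = es.candidate_gene_set(rec)
        assert genes == set(noise_free_sim.truth.drift_genes)
        drift_probes = [p for p in noise_free_sim.truth.drift_island_probes if p in rec.index]
        assert (rec.loc[drift_probes, "meth_expr_corr"] <= -0.99).all()


class TestCandidateGeneSet:
    def test_many_probes_map_to_one_gene(self):
        rec = pd.DataFrame(
            {"gene": ["g1", "g1", "g2"], "candidate": [True, True, False],
             "evaluable": [True, True, True]},
            index=["p1", "p2", "p3"],
        )
        genes, report = es.candidate_gene_set(rec)
        assert genes == {"g1"}
        assert report["candidate_probes"] == 2
        assert report["candidate_genes"] == 1

    def test_empty_records_give_empty_set(self):
        rec = pd.DataFrame(
            {
                "gene": pd.Series(dtype=str),
                "candidate": pd.Series(dtype=bool),
                "evaluable": pd.Series(dtype=bool),
            }
        )
        genes, report = es.candidate_gene_set(rec)
        assert genes == set() and report["candidate_probes"] == 0


class TestCompendiumValidation:
    def test_identical_distributions_give_p_one(self):
        samples = make_samples([5, 10, 15, 30, 40, 50])
        cols = list(samples.data.index)
        expr = ExprMatrix(pd.DataFrame([[7.0] * 6], index=["e0"], columns=cols), floor=0.0)
        ann = make_annotation([("e0", "g0", "1", 100, False, "expr_array")])
        res, validated = es.validate_expression_compendium(expr, samples, {"g0"}, ann)
        assert res.loc["e0", "p_value"] == pytest.approx(1.0)
        assert validated == set()

    def test_generator_drift_genes_validate(self, small_sim, small_cfg):
        expr = apply_expression_floor(small_sim.expr, small_cfg.expr_floor)
        res, validated = es.validate_expression_compendium(
            expr, small_sim.samples, set(small_sim.truth.drift_genes), small_sim.annotation
        )
        assert validated == set(small_sim.truth.drift_genes)
        assert (res["q_value"] < 0.05).all()
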