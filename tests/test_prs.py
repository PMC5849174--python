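"""PRS construction, scoring, quartile/trend/AUC evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrisk.association import AssocResult
from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable, SnpRecord
from polyrisk.ld import LdMatrix
from polyrisk.prs import (
    EmptyModelError,
    PrsModelSpec,
    auc,
    build_model,
    quartile_analysis,
    quartile_table_from_counts,
    score_samples,
    trend_analysis,
)


def _mk_gm(dosage, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    m = dosage.shape[1]
    ids = ids or [f"rs{j}" for j in range(m)]
    snps = [SnpRecord(s, "1", 100 * (j + 1), "A", "G") for j, s in enumerate(ids)]
    return GenotypeMatrix([f"s{i}" for i in range(dosage.shape[0])], snps, dosage)


def _model(ids, weights, eaf=None):
    return PrsModelSpec(
        "custom", list(ids), np.asarray(weights, dtype=float), "unadjusted",
        dict.fromkeys(ids, 0.25) if eaf is None else eaf,
    )


class TestScoring:
    def test_all_zero_dosages_score_zero(self):
        gm = _mk_gm(np.zeros((3, 2)))
        model = _model(["rs0", "rs1"], [0.5, -0.2])
        np.testing.assert_array_equal(score_samples(gm, model), np.zeros(3))

    def test_single_snp_arithmetic(self):
        gm = _mk_gm([[2.0]])
        model = _model(["rs0"], [np.log(2)])
        assert score_samples(gm, model)[0] == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_hand_summed_three_snp_fixture(self):
        w = [np.log(1.5), np.log(1.2), -np.log(1.1)]
        gm = _mk_gm([[2.0, 1.0, 1.0]])
        expected = 2 * np.log(1.5) + np.log(1.2) - np.log(1.1)
        assert score_samples(gm, _model(["rs0", "rs1", "rs2"], w))[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_imputed_with_control_frequency(self):
        gm = _mk_gm([[np.nan]])
        model = _model(["rs0"], [1.0], eaf={"rs0": 0.3})
        assert score_samples(gm, model)[0] == pytest.approx(0.6)

    def test_renormalize_policy(self):
        gm = _mk_gm([[2.0, np.nan]])
        model = _model(["rs0", "rs1"], [0.5, 0.7])
        # observed sum 1.0 rescaled by 2/1
        assert score_samples(gm, model, "renormalize")[0] == pytest.approx(2.0)

    def test_absent_model_snp_raises(self):
        gm = _mk_gm(np.zeros((2, 1)))
        with pytest.raises(KeyError, match="rs_missing"):
            score_samples(gm, _model(["rs_missing"], [0.1]))

    def test_zero_weight_snp_changes_nothing(self):
        rng = np.random.default_rng(0)
        gm = _mk_gm(rng.binomial(2, 0.4, size=(30, 3)).astype(float))
        base = _model(["rs0", "rs1"], [0.3, -0.1])
        extended = _model(["rs0", "rs1", "rs2"], [0.3, -0.1, 0.0])
        np.testing.assert_allclose(
            score_samples(gm, base), score_samples(gm, extended), atol=1e-12
        )

    def test_score_linearity(self):
        rng = np.random.default_rng(1)
        gm = _mk_gm(rng.binomial(2, 0.4, size=(20, 3)).astype(float))
        w1, w2 = np.array([0.1, 0.2, -0.3]), np.array([0.5, -0.1, 0.05])
        ids = ["rs0", "rs1", "rs2"]
        s = score_samples(gm, _model(ids, w1 + w2))
        np.testing.assert_allclose(
            s, score_samples(gm, _model(ids, w1)) + score_samples(gm, _model(ids, w2)),
            atol=1e-12,
        )


class TestQuartiles:
    def test_243_controls_split_61_61_61_60(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=243 + 301)
        status = np.array([False] * 243 + [True] * 301)
        phen = PhenotypeTable.from_arrays([f"s{i}" for i in range(544)], status)
        table = quartile_analysis(scores, phen)
        assert [r.n_controls for r in table.rows] == [61, 61, 61, 60]
        assert sum(r.n_cases for r in table.rows) == 301

    def test_or_equals_crude_cross_product(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=400)
        status = rng.random(400) < 0.5
        if status.all() or not status.any():
            status[0] = ~status[0]
        phen = PhenotypeTable.from_arrays([f"s{i}" for i in range(400)], status)
        table = quartile_analysis(scores, phen)
        r1 = table.row(1)
        for q in (2, 3, 4):
            r = table.row(q)
            crude = (r.n_cases / r.n_controls) / (r1.n_cases / r1.n_controls)
            assert r.or_ == pytest.approx(crude, rel=1e-6)

    def test_published_counts_reproduce_published_ors(self):
        """Quartile ORs/CIs/p recomputed from printed counts match the
        printed values at printed precision (saturated-model identity)."""
        table = quartile_table_from_counts([53, 72, 78, 98], [61, 61, 61, 60])
        assert table.row(2).or_ == pytest.approx(1.358, abs=5e-4)
        assert table.row(3).or_ == pytest.approx(1.472, abs=5e-4)
        assert table.row(4).or_ == pytest.approx(1.880, abs=5e-4)
        lo, hi = table.row(4).ci95
        assert lo == pytest.approx(1.153, abs=5e-4)
        assert hi == pytest.approx(3.064, abs=5e-4)
        assert table.row(4).p == pytest.approx(0.011, abs=5e-4)

    def test_identical_scores_error(self):
        phen = PhenotypeTable.from_arrays(
            [f"s{i}" for i in range(8)], [True] * 4 + [False] * 4
        )
        with pytest.raises(ValueError, match="degenerate"):
            quartile_analysis(np.ones(8), phen)

    def test_boundary_ties_to_lower_quartile(self):
        # score exactly at a cutpoint lands in the lower quartile
        scores = np.array([1.0, 2.0, 3.0, 4.0, 2.0])
        status = np.array([False, False, False, False, True])
        phen = PhenotypeTable.from_arrays([f"s{i}" for i in range(5)], status)
        table = quartile_analysis(scores, phen)
        # control cutpoints from {1,2,3,4}; the case scores 2.0 == median -> q2
        assert table.row(2).n_cases == 1


class TestTrend:
    def test_null_trend_or_near_one(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=2000)
        status = rng.random(2000) < 0.5
        phen = PhenotypeTable.from_arrays([f"s{i}" for i in range(2000)], status)
        res = trend_analysis(scores, phen)
        lo, hi = res.ci95
        assert lo < 1.0 < hi

    def test_causal_trend_detected(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=2000)
        p = 1 / (1 + np.exp(-(scores - 0.2)))
        status = rng.random(2000) < p
        phen = PhenotypeTable.from_arrays([f"s{i}" for i in range(2000)], status)
        res = trend_analysis(scores, phen)
        assert res.or_ > 1.5 and res.p < 1e-10

    def test_constant_prs_error(self):
        phen = PhenotypeTable.from_arrays(["a", "b"], [True, False])
        with pytest.raises(ValueError, match="constant"):
            trend_analysis(np.ones(2), phen)


class TestAuc:
    def test_perfect_separation_is_one(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert auc(scores, labels).auc == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        res = auc(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.03)
        assert res.ci95[0] < 0.5 < res.ci95[1]

    @given(
        case_scores=st.lists(st.integers(0, 8), min_size=1, max_size=10),
        ctrl_scores=st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_exhaustive_pair_counting(self, case_scores, ctrl_scores):
        """AUC equals concordant-pair fraction (ties 1/2) by enumeration."""
        scores = np.array(case_scores + ctrl_scores, dtype=float)
        labels = np.array([1] * len(case_scores) + [0] * len(ctrl_scores))
        wins = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x, y in itertools.product(case_scores, ctrl_scores)
        )
        expected = wins / (len(case_scores) * len(ctrl_scores))
        assert auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        base = auc(scores, labels).auc
        assert auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert auc(3 * scores - 7, labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestBuildModel:
    def _inputs(self):
        ids = [f"rs{j}" for j in range(6)]
        ps = [1e-4, 0.01, 0.2, 0.5, 0.03, 0.8]
        betas = [0.4, 0.3, 0.05, 0.01, 0.25, -0.02]
        unadj = [AssocResult(s, b, 0.1, p, False, 100, 0.3) for s, b, p in zip(ids, betas, ps)]
        adj = [AssocResult(s, b * 1.1, 0.1, p, True, 100, 0.3) for s, b, p in zip(ids, betas, ps)]
        m = len(ids)
        r2 = np.eye(m)
        r2[0, 1] = r2[1, 0] = 0.8  # rs0-rs1 in LD
        lm = LdMatrix(ids, r2, np.full((m, m), 100))
        rng = np.random.default_rng(0)
        gm = _mk_gm(rng.binomial(2, 0.3, size=(40, m)).astype(float), ids)
        phen = PhenotypeTable.from_arrays(gm.sample_ids, [i < 20 for i in range(40)])
        return unadj, adj, lm, gm, phen

    def test_model1_keeps_all_model2_significant_model3_pruned(self):
        unadj, adj, lm, gm, phen = self._inputs()
        m1 = build_model(unadj, adj, lm, gm, phen, "model1")
        m2 = build_model(unadj, adj, lm, gm, phen, "model2")
        m3 = build_model(unadj, adj, lm, gm, phen, "model3")
        assert m1.n_snps == 6
        assert m2.snp_ids == ["rs0", "rs1", "rs4"]
        assert m3.snp_ids == ["rs0", "rs4"]  # rs1 pruned (worse p in block)
        assert set(m3.snp_ids) <= set(m2.snp_ids) <= set(m1.snp_ids)

    def test_weight_source_selects_analysis(self):
        unadj, adj, lm, gm, phen = self._inputs()
        m_u = build_model(unadj, adj, lm, gm, phen, "model2", "unadjusted")
        m_a = build_model(unadj, adj, lm, gm, phen, "model2", "age_adjusted")
        np.testing.assert_allclose(m_a.weights, 1.1 * m_u.weights)

    def test_empty_model2_raises(self):
        unadj, adj, lm, gm, phen = self._inputs()
        null = [AssocResult(r.snp_id, r.beta, r.se, 0.9, False, 100, 0.3) for r in unadj]
        with pytest.raises(EmptyModelError):
            build_model(null, null, lm, gm, phen, "model2")
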