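"""Simulator: determinism, frequency/LD calibration, disease model, preset."""

import numpy as np
import pytest

from polyrisk.ld import ld_matrix
from polyrisk.qc import apply_snp_filters
from polyrisk.synthetic_data import (
    CalibrationError,
    SimConfig,
    SnpSpec,
    paper_like_panel,
    simulate_case_control,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
)


def _cfg(panel, seed=0, **kw):
    kw.setdefault("missing_rate", 0.0)
    return SimConfig(seed=seed, snp_panel=tuple(panel), **kw)


class TestGenotypes:
    def test_determinism_same_seed(self):
        cfg = _cfg([SnpSpec("a", 0.3, 1.2), SnpSpec("b", 0.1, 1.0)], seed=5)
        gm1, t1 = simulate_genotypes(cfg, 500)
        gm2, t2 = simulate_genotypes(cfg, 500)
        assert gm1.equals(gm2)
        np.testing.assert_array_equal(t1.linear_predictor, t2.linear_predictor)

    def test_realized_eaf_matches_target(self):
        cfg = _cfg([SnpSpec("a", 0.3, 1.0)], seed=1)
        gm, _ = simulate_genotypes(cfg, 5000)
        eaf = gm.dosage[:, 0].mean() / 2
        assert eaf == pytest.approx(0.30, abs=0.01)

    def test_block_r2_calibration(self):
        panel = [SnpSpec(f"b{k}", 0.25, 1.0, block_id=0) for k in range(4)]
        cfg = _cfg(panel, seed=2, block_r2=0.8)
        gm, _ = simulate_genotypes(cfg, 2000)
        lm = ld_matrix(gm)
        off = lm.r2[np.triu_indices(4, 1)]
        assert ((off > 0.70) & (off < 0.90)).all()

    def test_unblocked_snps_independent(self):
        cfg = _cfg([SnpSpec("a", 0.3, 1.0), SnpSpec("b", 0.3, 1.0)], seed=3)
        gm, _ = simulate_genotypes(cfg, 5000)
        lm = ld_matrix(gm)
        assert lm.r2[0, 1] < 0.01

    def test_infeasible_frequency_r2_pair_raises(self):
        # r=0.95 unattainable between EAF 0.01 and EAF 0.5 alleles
        panel = [SnpSpec("a", 0.01, 1.0, block_id=0), SnpSpec("b", 0.5, 1.0, block_id=0)]
        with pytest.raises(CalibrationError):
            simulate_genotypes(_cfg(panel, block_r2=0.9), 100)

    def test_missingness_rate(self):
        cfg = _cfg([SnpSpec(f"s{j}", 0.3, 1.0) for j in range(10)], missing_rate=0.05)
        gm, _ = simulate_genotypes(cfg, 2000)
        assert np.isnan(gm.dosage).mean() == pytest.approx(0.05, abs=0.01)

    def test_dropout_snp_fails_call_rate(self):
        cfg = _cfg(
            [SnpSpec("ok", 0.3, 1.0), SnpSpec("bad", 0.3, 1.0)],
            missing_rate=0.0,
            dropout_snps=("bad",),
        )
        gm, _ = simulate_genotypes(cfg, 2000)
        assert np.isnan(gm.column("bad")).mean() == pytest.approx(0.10, abs=0.03)
        assert np.isnan(gm.column("ok")).mean() == 0.0


class TestPhenotypes:
    def test_null_model_prevalence(self):
        cfg = _cfg([SnpSpec("a", 0.3, 1.0)], prevalence=0.10)
        gm, truth = simulate_genotypes(cfg, 20000)
        phen = simulate_phenotypes(gm, truth, cfg)
        assert phen.n_cases / 20000 == pytest.approx(0.10, abs=0.01)

    def test_age_means_match_configuration(self):
        cfg = _cfg([SnpSpec("a", 0.3, 1.0)])
        gm, truth = simulate_genotypes(cfg, 20000)
        phen = simulate_phenotypes(gm, truth, cfg)
        df = phen.df
        assert df[df.status].age.mean() == pytest.approx(50.2, abs=1.0)
        assert df[~df.status].age.mean() == pytest.approx(42.7, abs=0.5)

    def test_null_association_independent_of_status(self):
        from polyrisk.association import snp_association

        cfg = _cfg([SnpSpec("a", 0.3, 1.0)], seed=6)
        cohort = simulate_case_control(cfg, 1000, 1000, n_calib=4000)
        res = snp_association(cohort.gm, cohort.phen, "a")
        assert res.p > 1e-3  # no genuine association to detect


class TestCohorts:
    def test_exact_quotas(self, preset_cohorts):
        c1, c2 = preset_cohorts
        assert (c1.phen.n_cases, c1.phen.n_controls) == (1294, 885)
        assert (c2.phen.n_cases, c2.phen.n_controls) == (301, 243)

    def test_risk_allele_enriched_in_cases(self, preset_cohorts):
        c1 = preset_cohorts[0]
        y = c1.phen.status_array()
        g = c1.gm.column("rs_blk1")
        case_eaf = np.nanmean(g[y]) / 2
        ctrl_eaf = np.nanmean(g[~y]) / 2
        assert case_eaf > ctrl_eaf + 0.02

    def test_cohorts_disjoint_sample_ids(self, preset_cohorts):
        c1, c2 = preset_cohorts
        assert not set(c1.gm.sample_ids) & set(c2.gm.sample_ids)

    def test_samples_meet_call_rate_floor(self, preset_cohorts):
        from polyrisk.qc import sample_call_rates

        for cohort in preset_cohorts:
            assert (sample_call_rates(cohort.gm) >= 0.95).all()

    def test_deterministic_rerun(self):
        cfg = paper_like_panel(seed=21, n_cases_1=60, n_controls_1=50,
                               n_cases_2=30, n_controls_2=25)
        a1, b1 = simulate_cohort(cfg)
        a2, b2 = simulate_cohort(cfg)
        assert a1.gm.equals(a2.gm) and b1.gm.equals(b2.gm)
        assert a1.phen.df.equals(a2.phen.df)


class TestPreset:
    def test_panel_composition(self):
        cfg = paper_like_panel()
        assert len(cfg.snp_panel) == 51
        rare = [s for s in cfg.snp_panel if s.eaf < 0.005]
        assert len(rare) == 5
        assert all(2.5 < s.or_ < 5.0 for s in rare)
        block = [s for s in cfg.snp_panel if s.block_id == 0]
        assert len(block) == 4
        causal_common = [s for s in cfg.snp_panel if s.block_id is None and s.or_ > 1
                         and s.eaf >= 0.005]
        assert len(causal_common) == 7

    def test_preset_qc_keeps_46(self, preset_cohorts):
        c1 = preset_cohorts[0]
        filtered, _ = apply_snp_filters(c1.gm, c1.phen)
        assert filtered.n_snps == 46

    def test_all_null_switch(self):
        cfg = paper_like_panel(all_null=True)
        assert all(s.or_ == 1.0 for s in cfg.snp_panel)
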