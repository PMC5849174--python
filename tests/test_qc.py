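"""Quality control: call rates, MAF, exact and chi-square HWE tests."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable, SnpRecord
from polyrisk.qc import (
    QcConfig,
    apply_sample_filter,
    apply_snp_filters,
    hwe_test,
    minor_allele_frequency,
    sample_call_rates,
    snp_call_rate,
)


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Brute-force exact HWE p by enumerating heterozygote configurations
    conditional on the allele counts, in exact rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    n_major = 2 * n - n_minor

    def prob(h: int) -> Fraction:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        ways = Fraction(
            2**h * comb(n, h) * comb(n - h, hom_min)
        )  # multinomial over genotypes, het phase factor 2^h
        return ways / Fraction(comb(2 * n, n_minor))

    hets = range(n_minor % 2, n_minor + 1, 2)
    probs = {h: prob(h) for h in hets}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def _mk_matrix(columns, snps=None):
    columns = np.asarray(columns, dtype=float)
    n, m = columns.shape
    if snps is None:
        snps = [SnpRecord(f"rs{j}", "1", 100 * (j + 1), "A", "G") for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], snps, columns)


class TestCallRates:
    def test_no_missing_is_one(self, tiny_gm):
        assert snp_call_rate(tiny_gm, "rs1") == 1.0

    def test_sample_call_rate_arithmetic(self):
        # 3 missing of 46 SNPs -> 43/46 < 0.95 -> excluded
        row = [1.0] * 43 + [np.nan] * 3
        gm = _mk_matrix([row, [0.0] * 46])
        rates = sample_call_rates(gm)
        assert rates[0] == pytest.approx(43 / 46)
        filtered, dropped = apply_sample_filter(gm)
        assert dropped == ["s0"]

    def test_all_missing_sample_excluded(self):
        gm = _mk_matrix([[np.nan, np.nan], [0.0, 1.0]])
        assert sample_call_rates(gm)[0] == 0.0
        assert apply_sample_filter(gm)[1] == ["s0"]

    def test_exactly_at_threshold_passes(self):
        # 5 missing of 100 samples -> call rate exactly 0.95 passes
        col = [np.nan] * 5 + [1.0] * 95
        gm = _mk_matrix(np.array(col)[:, None])
        assert snp_call_rate(gm, "rs0") == pytest.approx(0.95)
        phen = PhenotypeTable.from_arrays(gm.sample_ids, [False] * 100)
        _, results = apply_snp_filters(gm, phen)
        assert "low_call_rate" not in results[0].fail_reasons


class TestHwe:
    def test_monomorphic_p_one(self):
        assert hwe_test(61, 0, 0) == 1.0
        assert hwe_test(61, 0, 0, method="chi2") == 1.0

    def test_chi2_at_expectation_p_one(self):
        assert hwe_test(25, 50, 25, method="chi2") == pytest.approx(1.0)

    def test_exact_small_example_matches_enumeration(self):
        assert hwe_test(3, 5, 2) == pytest.approx(hwe_exact_oracle(3, 5, 2), abs=1e-12)

    @given(
        a=st.integers(0, 30), b=st.integers(0, 30), c=st.integers(0, 30)
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_label_swap_invariance(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_test(a, b, c) == pytest.approx(hwe_test(c, b, a), abs=1e-12)

    def test_exact_matches_oracle_on_grid(self):
        for a in range(0, 12):
            for b in range(0, 12):
                for c in range(0, 12):
                    if a + b + c == 0:
                        continue
                    assert hwe_test(a, b, c) == pytest.approx(
                        hwe_exact_oracle(a, b, c), abs=1e-10
                    ), (a, b, c)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 0)


class TestMafAndFilters:
    def test_maf_never_exceeds_half(self):
        assert minor_allele_frequency(np.array([2.0, 2.0, 1.0])) == pytest.approx(1 / 6)
        assert minor_allele_frequency(np.array([0.0, 0.0])) == 0.0

    def test_maf_uses_non_missing_only(self):
        col = np.array([1.0, np.nan, 0.0, np.nan])
        assert minor_allele_frequency(col) == pytest.approx(0.25)

    def test_rare_snp_excluded_by_maf(self, preset_cohorts):
        c1 = preset_cohorts[0]
        _, results = apply_snp_filters(c1.gm, c1.phen)
        rare = {r.snp_id: r for r in results if r.snp_id.startswith("rs_rare")}
        assert len(rare) == 5
        for r in rare.values():
            assert r.fail_reasons == {"low_maf"}
            assert r.maf < 0.01

    def test_common_snp_passes(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.3, size=200).astype(float)
        gm = _mk_matrix(col[:, None])
        phen = PhenotypeTable.from_arrays(gm.sample_ids, [i < 100 for i in range(200)])
        filtered, results = apply_snp_filters(gm, phen)
        assert results[0].passed and filtered.n_snps == 1

    def test_51_to_46_narrative(self, preset_cohorts):
        """The 51-SNP preset panel loses exactly its 5 rare SNPs to the MAF
        filter, leaving 46 analyzable."""
        c1 = preset_cohorts[0]
        filtered, _ = apply_snp_filters(c1.gm, c1.phen)
        assert c1.gm.n_snps == 51
        assert filtered.n_snps == 46

    def test_hwe_skipped_without_controls(self):
        gm = _mk_matrix(np.array([[0.0], [1.0], [2.0], [1.0]]))
        phen = PhenotypeTable.from_arrays(gm.sample_ids, [True] * 4)
        _, results = apply_snp_filters(gm, phen)
        assert results[0].hwe_p_controls is None
        assert "hwe_violation" not in results[0].fail_reasons

    def test_hwe_violation_flagged(self):
        # 50 hom-ref + 50 hom-alt, no hets: gross HWE violation in controls
        col = np.array([0.0] * 50 + [2.0] * 50)
        gm = _mk_matrix(col[:, None])
        phen = PhenotypeTable.from_arrays(gm.sample_ids, [False] * 100)
        _, results = apply_snp_filters(gm, phen, QcConfig(hwe_p_threshold=1e-4))
        assert "hwe_violation" in results[0].fail_reasons
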