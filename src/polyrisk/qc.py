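"""Sample- and SNP-level quality control.

Filters mirror standard case-control genotyping practice on small SNP
panels: samples and assays below a 95% call rate are excluded, SNPs with a
minor allele frequency below 1% in the analysis cohort are dropped from
scoring, and Hardy-Weinberg equilibrium is tested in controls (departures
there signal genotyping artifacts rather than disease association).

The exact HWE test conditions on the observed allele counts and sums the
probability of every heterozygote configuration no more likely than the
observed one (the standard two-sided exact test); a 1-df chi-square
goodness-of-fit alternative is kept for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "QcConfig",
    "SnpQcResult",
    "sample_call_rates",
    "snp_call_rate",
    "snp_call_rates",
    "minor_allele_frequency",
    "hwe_test",
    "apply_sample_filter",
    "apply_snp_filters",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the QC stage.

    call_rate_threshold : minimum per-sample and per-SNP call rate
        (inclusive: exactly at threshold passes).
    maf_threshold : SNPs with MAF strictly below this are excluded.
    hwe_p_threshold : SNPs with control-HWE p strictly below this are
        excluded.  The default (1e-6) only catches gross assay failure.
    hwe_method : exact (default) or chi2.
    """

    call_rate_threshold: float = 0.95
    maf_threshold: float = 0.01
    hwe_p_threshold: float = 1e-6
    hwe_method: Literal["exact", "chi2"] = "exact"

    def __post_init__(self) -> None:
        for name in ("call_rate_threshold", "maf_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.hwe_p_threshold <= 1:
            raise ValueError("hwe_p_threshold outside [0, 1]")


@dataclass
class SnpQcResult:
    """Per-SNP QC metrics and pass/fail decision."""

    snp_id: str
    call_rate: float
    maf: float
    hwe_p_controls: float | None
    fail_reasons: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def sample_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per sample (over all SNP columns)."""
    if gm.n_snps == 0:
        raise ValueError("call rate undefined with zero SNPs")
    return 1.0 - np.isnan(gm.dosage).mean(axis=1)


def snp_call_rates(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP (over all samples)."""
    if gm.n_samples == 0:
        raise ValueError("call rate undefined with zero samples")
    return 1.0 - np.isnan(gm.dosage).mean(axis=0)


def snp_call_rate(gm: GenotypeMatrix, snp_id: str) -> float:
    return float(snp_call_rates(gm)[gm.snp_index(snp_id)])


def minor_allele_frequency(dosage: np.ndarray) -> float:
    """MAF from a dosage vector, using non-missing calls only.

    Returns NaN when every call is missing.
    """
    g = dosage[~np.isnan(dosage)]
    if g.size == 0:
        return float("nan")
    p = g.sum() / (2 * g.size)  # effect-allele frequency
    return float(min(p, 1.0 - p))


def hwe_test(
    n_hom_ref: int,
    n_het: int,
    n_hom_alt: int,
    method: Literal["exact", "chi2"] = "exact",
) -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    The exact method conditions on the observed allele counts and sums, over
    all heterozygote counts of the same parity, the probabilities of the
    configurations no more likely than the observed one (two-sided).  The
    chi2 method is the classic 1-df goodness-of-fit statistic.  Both are
    invariant to swapping the homozygote labels.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("HWE test undefined for zero genotypes")
    if method == "exact":
        return _hwe_exact(n_hom_ref, n_het, n_hom_alt)
    if method == "chi2":
        return _hwe_chi2(n_hom_ref, n_het, n_hom_alt)
    raise ValueError(f"unknown HWE method {method!r}")


def _log_prob_het(n_het: int, n_minor: int, n: int) -> float:
    """log P(het count | minor allele count) under the exact conditional."""
    n_major = 2 * n - n_minor
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n - n_het - n_hom_minor
    return (
        n_het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(n_hom_major + 1)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )


def _hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    logp = np.array([_log_prob_het(int(h), n_minor, n) for h in hets])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.nonzero(hets == n_het)[0][0]]
    # sum all configurations with probability <= observed (tiny slack for
    # floating-point ties)
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def _hwe_chi2(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if p == 0 or q == 0:  # monomorphic: single attainable configuration
        return 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    g = dosage[~np.isnan(dosage)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def apply_sample_filter(
    gm: GenotypeMatrix, config: QcConfig | None = None
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples below the call-rate threshold; returns (matrix, dropped ids)."""
    config = config or QcConfig()
    rates = sample_call_rates(gm)
    keep = [s for s, r in zip(gm.sample_ids, rates) if r >= config.call_rate_threshold]
    dropped = [s for s in gm.sample_ids if s not in set(keep)]
    return gm.subset(samples=keep), dropped


def apply_snp_filters(
    gm: GenotypeMatrix,
    phen: PhenotypeTable,
    config: QcConfig | None = None,
) -> tuple[GenotypeMatrix, list[SnpQcResult]]:
    """Apply per-SNP call-rate, MAF and control-HWE filters.

    MAF is computed on the full analysis cohort (cases + controls,
    non-missing calls); HWE on controls only.  With no controls present the
    HWE filter is skipped and recorded as None.  Returns the filtered matrix
    plus one :class:`SnpQcResult` per input SNP (removals carry reasons).
    """
    config = config or QcConfig()
    phen = phen.aligned_to(gm.sample_ids)
    is_control = ~phen.status_array()
    have_controls = bool(is_control.any())
    call = snp_call_rates(gm)
    results: list[SnpQcResult] = []
    for j, snp in enumerate(gm.snps):
        col = gm.dosage[:, j]
        maf = minor_allele_frequency(col)
        hwe_p: float | None = None
        reasons: set[str] = set()
        if call[j] < config.call_rate_threshold:
            reasons.add("low_call_rate")
        if np.isnan(maf) or maf < config.maf_threshold:
            reasons.add("low_maf")
        if have_controls:
            counts = _genotype_counts(col[is_control])
            if sum(counts) > 0:
                hwe_p = hwe_test(*counts, method=config.hwe_method)
                if hwe_p < config.hwe_p_threshold:
                    reasons.add("hwe_violation")
        results.append(SnpQcResult(snp.snp_id, float(call[j]), maf, hwe_p, reasons))
    kept = [r.snp_id for r in results if r.passed]
    return gm.subset(snp_ids=kept), results


def qc_report_frame(results: Sequence[SnpQcResult]):
    """QC results as a DataFrame for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "call_rate": [r.call_rate for r in results],
            "maf": [r.maf for r in results],
            "hwe_p_controls": [r.hwe_p_controls for r in results],
            "passed": [r.passed for r in results],
            "fail_reasons": [",".join(sorted(r.fail_reasons)) for r in results],
        }
    )
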