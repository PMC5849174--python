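"""Two-cohort case-control cohort simulator with known truth.

The generator emulates the structure of a small curated SNP panel typed in
two independent case-control cohorts: ~50 biallelic SNPs with effect-allele
frequencies from <1% to ~50%, LD blocks of 3-4 SNPs with dosage r-squared
up to ~0.9, per-allele disease ORs of ~1.1-1.5 for common variants (up to
~2.6-4.9 for rare ones), cases on average older than controls, sporadic
missing genotype calls, and occasional whole-assay dropout.

Genotypes: each individual carries two haplotypes.  Within an LD block,
alleles arise from a latent-Gaussian threshold copula -- a multivariate
normal draw per haplotype, thresholded at the allele-frequency quantile --
with the latent correlation calibrated (per SNP pair, by root finding on
the bivariate normal orthant probability) so realized dosage r-squared hits
the requested block value.  Unblocked SNPs are independent binomials.

Disease: additive logistic model on the log-odds scale,
P(case) = logistic(alpha + sum_j ln(OR_j) g_ij [+ gamma * age]), with alpha
tuned by bisection so the population prevalence matches the configured
baseline (default 10%).  Case-control cohorts are filled by rejection
sampling from this population until the case and control quotas are met;
odds ratios are invariant to this outcome-dependent sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable, SnpRecord

__all__ = [
    "SnpSpec",
    "SimConfig",
    "TruthTable",
    "Cohort",
    "CalibrationError",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_case_control",
    "paper_like_panel",
]

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


class CalibrationError(ValueError):
    """The requested (frequency, r-squared) pair is unattainable."""


@dataclass(frozen=True)
class SnpSpec:
    """Ground truth for one simulated SNP."""

    snp_id: str
    eaf: float  # effect-allele frequency in (0, 1)
    or_: float  # true per-allele odds ratio, > 0
    block_id: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: EAF {self.eaf} outside (0, 1)")
        if self.or_ <= 0:
            raise ValueError(f"{self.snp_id}: OR must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a two-cohort simulation.

    Cohort-size defaults mirror a realistic two-stage design: a large
    training cohort (1294 cases / 885 controls) for association and a
    smaller evaluation cohort (301 cases / 243 controls) for PRS scoring.
    Ages are class-conditional truncated normals (cases older, means
    50.2 / 42.7 years) unless an age-risk slope couples age into the
    disease model.  ``dropout_snps`` suffer whole-assay dropout: their
    missingness is raised to ``dropout_missing_rate`` so they fail a 95%
    call-rate filter.
    """

    seed: int
    snp_panel: tuple[SnpSpec, ...]
    n_cases_1: int = 1294
    n_controls_1: int = 885
    n_cases_2: int = 301
    n_controls_2: int = 243
    block_r2: float = 0.85
    missing_rate: float = 0.009
    age_case_mean: float = 50.2
    age_case_sd: float = 10.0
    age_control_mean: float = 42.7
    age_control_sd: float = 10.0
    age_risk_slope: float = 0.0
    prevalence: float = 0.10
    dropout_snps: tuple[str, ...] = ()
    dropout_missing_rate: float = 0.10
    # cohort quotas are post-exclusion sizes: quota filling only admits
    # samples whose realized call rate clears this floor
    min_sample_call_rate: float = 0.95

    def __post_init__(self) -> None:
        for n in (self.n_cases_1, self.n_controls_1, self.n_cases_2, self.n_controls_2):
            if n <= 0:
                raise ValueError("cohort sizes must be positive")
        if not 0 <= self.block_r2 < 1:
            raise ValueError("block_r2 outside [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate outside [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence outside (0, 1)")
        ids = [s.snp_id for s in self.snp_panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp ids in panel")


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated data."""

    snp_frame: pd.DataFrame  # snp_id, true_or, true_eaf, block_id
    sample_ids: list[str]
    linear_predictor: np.ndarray  # genetic log-odds contribution per sample

    def frame(self) -> pd.DataFrame:
        return self.snp_frame.copy()


@dataclass
class Cohort:
    """One simulated case-control cohort with its truth."""

    gm: GenotypeMatrix
    phen: PhenotypeTable
    truth: TruthTable


def _bvn_cdf(z1: float, z2: float, rho: float) -> float:
    cov = [[1.0, rho], [rho, 1.0]]
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([z1, z2]))


@lru_cache(maxsize=4096)
def _calibrate_rho(p1: float, p2: float, target_r: float) -> float:
    """Latent normal correlation giving allele correlation ``target_r``
    between two thresholded Bernoullis with frequencies p1, p2."""
    if target_r == 0.0:
        return 0.0
    z1, z2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    r_max = (min(p1, p2) - p1 * p2) / denom  # Frechet upper bound
    if target_r >= r_max - 1e-9:
        raise CalibrationError(
            f"allele correlation {target_r:.3f} unattainable for frequencies "
            f"({p1}, {p2}); maximum is {r_max:.3f}"
        )

    def gap(rho: float) -> float:
        return (_bvn_cdf(z1, z2, rho) - p1 * p2) / denom - target_r

    return float(optimize.brentq(gap, -0.999, 0.999, xtol=1e-10))


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= 1e-10:
        return mat
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _block_latent_chol(freqs: Sequence[float], target_r2: float) -> np.ndarray:
    """Cholesky factor of the latent correlation matrix for one block."""
    k = len(freqs)
    target_r = float(np.sqrt(target_r2))
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            latent[i, j] = latent[j, i] = _calibrate_rho(freqs[i], freqs[j], target_r)
    return np.linalg.cholesky(_nearest_psd(latent))


def _panel_records(panel: Sequence[SnpSpec]) -> list[SnpRecord]:
    recs = []
    for j, s in enumerate(panel):
        eff, oth = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]
        recs.append(SnpRecord(s.snp_id, str(j % 22 + 1), (j + 1) * 10_000, eff, oth))
    return recs


def _draw_dosages(
    panel: Sequence[SnpSpec], block_r2: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Complete (no missingness) n x m dosage matrix honouring LD blocks."""
    m = len(panel)
    dosage = np.empty((n, m))
    blocks: dict[int, list[int]] = {}
    for j, s in enumerate(panel):
        if s.block_id is None:
            dosage[:, j] = rng.binomial(2, s.eaf, size=n)
        else:
            blocks.setdefault(s.block_id, []).append(j)
    for cols in blocks.values():
        freqs = [panel[j].eaf for j in cols]
        chol = _block_latent_chol(freqs, block_r2)
        z = rng.standard_normal((2 * n, len(cols))) @ chol.T
        alleles = z < stats.norm.ppf(freqs)[None, :]
        dosage[:, cols] = alleles.reshape(n, 2, len(cols)).sum(axis=1)
    return dosage


def _apply_missingness(
    dosage: np.ndarray,
    panel: Sequence[SnpSpec],
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    out = dosage.astype(float).copy()
    if config.missing_rate > 0:
        out[rng.random(out.shape) < config.missing_rate] = np.nan
    dropout = set(config.dropout_snps)
    for j, s in enumerate(panel):
        if s.snp_id in dropout:
            extra = rng.random(out.shape[0]) < config.dropout_missing_rate
            out[extra, j] = np.nan
    return out


def _truth_snp_frame(panel: Sequence[SnpSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in panel],
            "true_or": [s.or_ for s in panel],
            "true_eaf": [s.eaf for s in panel],
            "block_id": [s.block_id for s in panel],
        }
    )


def simulate_genotypes(
    config: SimConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "S",
) -> tuple[GenotypeMatrix, TruthTable]:
    """Population sample of genotypes plus truth (no case-control sampling).

    ``n_samples`` defaults to the combined cohort quotas.  The truth table
    carries the per-sample genetic log-odds contribution computed from the
    complete (pre-missingness) dosages.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = (
            config.n_cases_1 + config.n_controls_1 + config.n_cases_2 + config.n_controls_2
        )
    panel = config.snp_panel
    complete = _draw_dosages(panel, config.block_r2, n_samples, rng)
    log_or = np.log([s.or_ for s in panel])
    eta = complete @ log_or
    observed = _apply_missingness(complete, panel, config, rng)
    ids = [f"{id_prefix}{i:06d}" for i in range(n_samples)]
    gm = GenotypeMatrix(ids, _panel_records(panel), observed)
    truth = TruthTable(_truth_snp_frame(panel), ids, eta)
    return gm, truth


def _tune_alpha(eta: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean logistic(alpha + eta) equals prevalence."""

    def gap(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta))))) - prevalence

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(f"case fraction {prevalence} unattainable")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _truncnorm(
    mean: float, sd: float, n: int, rng: np.random.Generator, lo: float = 20.0, hi: float = 90.0
) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Bernoulli disease status under the additive logistic model, plus ages.

    With a zero age-risk slope (default), ages are drawn per class from the
    configured truncated normals after status assignment.  With a nonzero
    slope, a pre-status age is drawn for everyone from the control-class
    normal and enters the linear predictor, producing genuine
    age-confounded risk.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    eta = np.asarray(truth.linear_predictor, dtype=float)
    if eta.size != gm.n_samples:
        raise ValueError("truth table does not match genotype matrix")
    n = eta.size
    if config.age_risk_slope != 0.0:
        age = _truncnorm(config.age_control_mean, config.age_control_sd, n, rng)
        eta = eta + config.age_risk_slope * age
        alpha = _tune_alpha(eta, config.prevalence)
        status = rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + eta)))
    else:
        alpha = _tune_alpha(eta, config.prevalence)
        status = rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + eta)))
        age = np.empty(n)
        n_case = int(status.sum())
        age[status] = _truncnorm(config.age_case_mean, config.age_case_sd, n_case, rng)
        age[~status] = _truncnorm(
            config.age_control_mean, config.age_control_sd, n - n_case, rng
        )
    return PhenotypeTable.from_arrays(gm.sample_ids, status.tolist(), age.tolist())


def _fill_quota(
    config: SimConfig,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    id_prefix: str,
    alpha: float,
) -> Cohort:
    """Rejection-sample a case-control cohort to exact quotas."""
    panel = config.snp_panel
    log_or = np.log([s.or_ for s in panel])
    confounded = config.age_risk_slope != 0.0
    need_c, need_u = n_cases, n_controls
    batch = max(500, int(1.2 * max(n_cases / config.prevalence, n_controls)))
    rows_d, rows_eta, rows_status, rows_age = [], [], [], []
    guard = 0
    while need_c > 0 or need_u > 0:
        guard += 1
        if guard > 200:
            raise CalibrationError("rejection sampling failed to fill quotas")
        complete = _draw_dosages(panel, config.block_r2, batch, rng)
        eta = complete @ log_or
        if confounded:
            age = _truncnorm(config.age_control_mean, config.age_control_sd, batch, rng)
            eta_full = eta + config.age_risk_slope * age
        else:
            age = np.full(batch, np.nan)
            eta_full = eta
        status = rng.random(batch) < 1.0 / (1.0 + np.exp(-(alpha + eta_full)))
        masked = _apply_missingness(complete, panel, config, rng)
        call_rate = 1.0 - np.isnan(masked).mean(axis=1)
        for i in range(batch):
            if call_rate[i] < config.min_sample_call_rate:
                continue
            if status[i] and need_c > 0:
                need_c -= 1
            elif not status[i] and need_u > 0:
                need_u -= 1
            else:
                continue
            rows_d.append(masked[i])
            rows_eta.append(eta[i])
            rows_status.append(bool(status[i]))
            rows_age.append(float(age[i]))
        batch = max(500, int(1.5 * need_c / config.prevalence) + need_u)
    observed = np.array(rows_d)
    n = observed.shape[0]
    status = np.array(rows_status, dtype=bool)
    ages = np.array(rows_age)
    if not confounded:
        ages[status] = _truncnorm(
            config.age_case_mean, config.age_case_sd, int(status.sum()), rng
        )
        ages[~status] = _truncnorm(
            config.age_control_mean, config.age_control_sd, int((~status).sum()), rng
        )
    ids = [f"{id_prefix}{i:06d}" for i in range(n)]
    gm = GenotypeMatrix(ids, _panel_records(panel), observed)
    phen = PhenotypeTable.from_arrays(ids, status.tolist(), ages.tolist())
    truth = TruthTable(_truth_snp_frame(panel), ids, np.array(rows_eta))
    return Cohort(gm, phen, truth)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, Cohort]:
    """Simulate the full two-cohort design: (training, evaluation).

    Both cohorts are drawn independently from the same population model and
    filled to their exact case/control quotas.  Deterministic for a fixed
    config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    alpha = _population_alpha(config, rng)
    c1 = _fill_quota(config, config.n_cases_1, config.n_controls_1, rng, "C1_", alpha)
    c2 = _fill_quota(config, config.n_cases_2, config.n_controls_2, rng, "C2_", alpha)
    return c1, c2


def _population_alpha(
    config: SimConfig, rng: np.random.Generator, n_calib: int = 20_000
) -> float:
    """Tune the disease-model intercept once on a calibration population."""
    log_or = np.log([s.or_ for s in config.snp_panel])
    complete = _draw_dosages(config.snp_panel, config.block_r2, n_calib, rng)
    eta = complete @ log_or
    if config.age_risk_slope != 0.0:
        age = _truncnorm(config.age_control_mean, config.age_control_sd, n_calib, rng)
        eta = eta + config.age_risk_slope * age
    return _tune_alpha(eta, config.prevalence)


def simulate_case_control(
    config: SimConfig,
    n_cases: int,
    n_controls: int,
    seed: int | None = None,
    n_calib: int = 20_000,
    id_prefix: str = "S",
) -> Cohort:
    """One case-control cohort of arbitrary size from the config's
    population model (rejection-sampled to exact quotas)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    alpha = _population_alpha(config, rng, n_calib=n_calib)
    return _fill_quota(config, n_cases, n_controls, rng, id_prefix, alpha)


def paper_like_panel(
    seed: int = 0,
    all_null: bool = False,
    **overrides,
) -> SimConfig:
    """Preset 51-SNP panel emulating a curated breast-cancer panel.

    Composition: 5 rare SNPs (EAF < 0.5%) with large ORs (2.6-4.9) that a
    1% MAF filter removes, leaving 46 analyzable; one 4-SNP LD block at
    r-squared ~0.85 containing a single causal SNP (OR 1.4) plus three
    tags; 7 further independent causal SNPs (OR 1.15-1.3); and 35 null
    common SNPs.  At the default cohort sizes roughly 11 SNPs reach
    nominal significance in expectation.  ``all_null`` sets every OR to 1
    for end-to-end null experiments.
    """
    panel: list[SnpSpec] = []
    # population EAFs chosen so the case-enriched cohort MAF stays far below
    # 1% (case oversampling inflates a rare risk allele's sample frequency
    # by roughly 1 + w_case*(OR-1))
    rare = [(0.002, 2.6), (0.0015, 3.1), (0.001, 3.7), (0.001, 4.3), (0.001, 4.9)]
    for k, (eaf, or_) in enumerate(rare):
        panel.append(SnpSpec(f"rs_rare{k + 1}", eaf, or_))
    block_freq = 0.30
    panel.append(SnpSpec("rs_blk1", block_freq, 1.4, block_id=0))  # causal
    for k in (2, 3, 4):
        panel.append(SnpSpec(f"rs_blk{k}", block_freq, 1.0, block_id=0))  # tags
    causal = [
        (0.15, 1.30), (0.20, 1.30), (0.25, 1.25), (0.30, 1.25),
        (0.35, 1.20), (0.40, 1.20), (0.45, 1.15),
    ]
    for k, (eaf, or_) in enumerate(causal):
        panel.append(SnpSpec(f"rs_causal{k + 1}", eaf, or_))
    null_freqs = np.linspace(0.05, 0.50, 35)
    for k, eaf in enumerate(null_freqs):
        panel.append(SnpSpec(f"rs_null{k + 1}", round(float(eaf), 4), 1.0))
    if all_null:
        panel = [replace(s, or_=1.0) for s in panel]
    return SimConfig(seed=seed, snp_panel=tuple(panel), **overrides)
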