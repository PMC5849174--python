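"""Polygenic risk score construction and evaluation.

A PRS is the per-individual sum over selected SNPs of the SNP's log-OR
weight times the individual's effect-allele count (0-2).  Three model
selection rules are supported, all trained on one cohort and evaluated on
an independent one:

* ``model1`` — every SNP that passed QC, weighted by its log-OR;
* ``model2`` — only SNPs significant at alpha = 0.05 in the training
  association analysis;
* ``model3`` — the model2 set after LD pruning (one SNP per block).

Evaluation stratifies the evaluation cohort into quartiles of the control
score distribution (type-6 sample percentiles; boundary ties fall to the
lower quartile), fits a one-hot logistic model for per-quartile ORs versus
the bottom quartile, fits a continuous-trend logistic model for the OR per
unit PRS, and computes ROC AUC (Mann-Whitney, ties counted 1/2) with a
DeLong 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from polyrisk.association import AssocResult, fit_logistic, significant_snps
from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable
from polyrisk.ld import LdMatrix, prune_by_ld

__all__ = [
    "PrsModelSpec",
    "QuartileRow",
    "QuartileTable",
    "PrsEvaluation",
    "build_model",
    "score_samples",
    "quartile_analysis",
    "quartile_table_from_counts",
    "trend_analysis",
    "auc",
    "evaluate_model",
]

_Z95 = stats.norm.ppf(0.975)

MissingPolicy = Literal["impute_control_freq", "renormalize"]


class EmptyModelError(ValueError):
    """A selection rule produced a model with no SNPs."""


@dataclass
class PrsModelSpec:
    """A named PRS model: SNP ids, log-OR weights, and their provenance.

    ``train_control_eaf`` carries per-SNP effect-allele frequencies among
    training-cohort controls, used for mean imputation of missing genotypes
    at scoring time.
    """

    name: str
    snp_ids: list[str]
    weights: np.ndarray
    weight_source: Literal["unadjusted", "age_adjusted", "external"]
    train_control_eaf: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != self.weights.size:
            raise ValueError("snp_ids and weights length mismatch")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in model")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weight in model")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class QuartileRow:
    quartile: int  # 1..4
    n_cases: int
    n_controls: int
    or_: float  # 1.0 for the reference quartile
    ci95: tuple[float, float] | None
    p: float | None
    flagged: str = ""


@dataclass
class QuartileTable:
    rows: list[QuartileRow]
    cutpoints: tuple[float, float, float]

    def row(self, q: int) -> QuartileRow:
        return self.rows[q - 1]


@dataclass
class TrendResult:
    or_: float
    ci95: tuple[float, float]
    p: float
    adjusted: bool


@dataclass
class AucResult:
    auc: float
    ci95: tuple[float, float]


@dataclass
class PrsEvaluation:
    """Full evaluation of one PRS model on one cohort."""

    model: PrsModelSpec
    scores: np.ndarray
    quartiles: QuartileTable
    trend: TrendResult
    auc: AucResult


def build_model(
    assoc_unadj: Sequence[AssocResult],
    assoc_adj: Sequence[AssocResult],
    ld: LdMatrix,
    gm_train: GenotypeMatrix,
    phen_train: PhenotypeTable,
    rule: Literal["model1", "model2", "model3"],
    weight_source: Literal["unadjusted", "age_adjusted"] = "unadjusted",
    alpha: float = 0.05,
    ld_threshold: float = 0.5,
) -> PrsModelSpec:
    """Select SNPs and weights under one of the three model rules.

    Association results must come from the training cohort; weights are the
    log-ORs of the chosen analysis (unadjusted or age-adjusted).  Model 3
    prunes the model2 set so that each LD block contributes its single most
    strongly associated SNP.
    """
    assoc = list(assoc_adj if weight_source == "age_adjusted" else assoc_unadj)
    by_id = {r.snp_id: r for r in assoc}
    if rule == "model1":
        selected = [r for r in assoc if r.valid]
    elif rule in ("model2", "model3"):
        selected = significant_snps(assoc, alpha=alpha)
        if not selected:
            raise EmptyModelError(f"no SNP significant at alpha={alpha}; {rule} is empty")
        if rule == "model3":
            kept, _log = prune_by_ld(selected, ld, gm_train, threshold=ld_threshold)
            selected = [by_id[s] for s in kept]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    snp_ids = [r.snp_id for r in selected]
    weights = np.array([r.beta for r in selected])
    controls = ~phen_train.aligned_to(gm_train.sample_ids).status_array()
    eaf = {}
    for s in snp_ids:
        col = gm_train.column(s)[controls]
        col = col[~np.isnan(col)]
        eaf[s] = float(col.sum() / (2 * col.size)) if col.size else 0.0
    return PrsModelSpec(rule, snp_ids, weights, weight_source, eaf)


def score_samples(
    gm: GenotypeMatrix,
    model: PrsModelSpec,
    missing_policy: MissingPolicy = "impute_control_freq",
) -> np.ndarray:
    """PRS per sample: sum of weight x effect-allele dosage.

    Missing genotypes are handled per policy: ``impute_control_freq``
    (default) substitutes 2 x the SNP's effect-allele frequency among
    training controls; ``renormalize`` rescales each sample's observed sum
    by m / m_observed.
    """
    missing_from_gm = [s for s in model.snp_ids if s not in gm.snp_ids]
    if missing_from_gm:
        raise KeyError(f"model SNPs absent from genotype matrix: {missing_from_gm}")
    cols = np.column_stack([gm.column(s) for s in model.snp_ids]) if model.n_snps else np.zeros(
        (gm.n_samples, 0)
    )
    w = model.weights
    nan = np.isnan(cols)
    if missing_policy == "impute_control_freq":
        fill = np.array([2.0 * model.train_control_eaf.get(s, 0.0) for s in model.snp_ids])
        filled = np.where(nan, fill[None, :], cols)
        return filled @ w
    if missing_policy == "renormalize":
        observed = np.where(nan, 0.0, cols) @ w
        m_obs = (~nan).sum(axis=1)
        scale = np.divide(
            model.n_snps, m_obs, out=np.zeros(gm.n_samples), where=m_obs > 0
        )
        return observed * scale
    raise ValueError(f"unknown missing policy {missing_policy!r}")


def _quartile_assign(
    scores: np.ndarray, cutpoints: tuple[float, float, float]
) -> np.ndarray:
    """Quartile labels 1..4; a score equal to a cutpoint goes to the lower
    quartile."""
    c1, c2, c3 = cutpoints
    return np.select(
        [scores <= c1, scores <= c2, scores <= c3], [1, 2, 3], default=4
    )


def quartile_analysis(
    scores: np.ndarray,
    phen: PhenotypeTable,
    cutpoint_source: Literal["controls", "combined"] = "controls",
) -> QuartileTable:
    """Quartile stratification with per-quartile ORs versus the bottom
    quartile.

    Cutpoints are the 25/50/75th type-6 (Weibull) sample percentiles of the
    control score distribution (or of the combined cohort with
    ``cutpoint_source="combined"``).  ORs come from a one-hot logistic fit,
    which for a saturated categorical model equals the crude cross-product
    ratio of the 2x2 quartile-vs-reference table.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y = phen.status_array().astype(float)
    if scores.size != y.size:
        raise ValueError("scores and phenotype table length mismatch")
    ref = scores[y == 0] if cutpoint_source == "controls" else scores
    if ref.size < 4:
        raise ValueError("need at least 4 reference samples for quartiles")
    if np.ptp(scores) == 0 or np.ptp(ref) == 0:
        raise ValueError("degenerate cutpoints: all scores identical")
    cut = tuple(np.percentile(ref, (25, 50, 75), method="weibull"))
    q = _quartile_assign(scores, cut)
    counts = [
        (int(((q == k) & (y == 1)).sum()), int(((q == k) & (y == 0)).sum()))
        for k in (1, 2, 3, 4)
    ]
    rows = [QuartileRow(1, counts[0][0], counts[0][1], 1.0, None, None)]
    dummies = np.column_stack([(q == k).astype(float) for k in (2, 3, 4)])
    fit_ok = True
    try:
        fit = fit_logistic(y, dummies)
        fit_ok = fit.converged
    except ValueError:
        fit_ok = False
    for idx, k in enumerate((2, 3, 4)):
        n_case, n_ctrl = counts[k - 1]
        if not fit_ok or n_case == 0 or n_ctrl == 0:
            rows.append(
                QuartileRow(k, n_case, n_ctrl, float("nan"), None, None,
                            flagged="empty cell or degenerate fit")
            )
            continue
        b, se = float(fit.betas[1 + idx]), float(fit.ses[1 + idx])
        rows.append(
            QuartileRow(
                k,
                n_case,
                n_ctrl,
                float(np.exp(b)),
                (float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
                float(2 * stats.norm.sf(abs(b / se))),
            )
        )
    return QuartileTable(rows, cut)


def quartile_table_from_counts(
    n_cases: Sequence[int], n_controls: Sequence[int]
) -> QuartileTable:
    """Recompute per-quartile ORs/CIs/p from printed quartile counts.

    Builds the categorical dataset the counts summarize and runs the same
    one-hot logistic fit as :func:`quartile_analysis`; because that model is
    saturated, the ORs equal the crude cross-product ratios and a published
    quartile table can be reproduced exactly from its counts.
    """
    if len(n_cases) != 4 or len(n_controls) != 4:
        raise ValueError("need counts for exactly 4 quartiles")
    qs, ys = [], []
    for k in range(4):
        qs += [k + 1] * (n_cases[k] + n_controls[k])
        ys += [1.0] * n_cases[k] + [0.0] * n_controls[k]
    q = np.array(qs)
    y = np.array(ys)
    dummies = np.column_stack([(q == k).astype(float) for k in (2, 3, 4)])
    fit = fit_logistic(y, dummies)
    rows = [QuartileRow(1, int(n_cases[0]), int(n_controls[0]), 1.0, None, None)]
    for idx, k in enumerate((2, 3, 4)):
        b, se = float(fit.betas[1 + idx]), float(fit.ses[1 + idx])
        rows.append(
            QuartileRow(
                k,
                int(n_cases[idx + 1]),
                int(n_controls[idx + 1]),
                float(np.exp(b)),
                (float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
                float(2 * stats.norm.sf(abs(b / se))),
            )
        )
    return QuartileTable(rows, (1.0, 2.0, 3.0))


def trend_analysis(
    scores: np.ndarray,
    phen: PhenotypeTable,
    adjust_age: bool = False,
) -> TrendResult:
    """Logistic fit of status on the continuous PRS (plus age if adjusted);
    OR per unit PRS with Wald CI and p."""
    scores = np.asarray(scores, dtype=float)
    y = phen.status_array().astype(float)
    keep = np.ones(y.size, dtype=bool)
    cols = [scores]
    if adjust_age:
        age = phen.age_array()
        keep = ~np.isnan(age)
        cols.append(age)
    X = np.column_stack(cols)[keep]
    if np.ptp(X[:, 0]) == 0:
        raise ValueError("constant PRS: trend undefined")
    fit = fit_logistic(y[keep], X)
    if not fit.converged:
        raise RuntimeError(f"trend fit did not converge: {fit.message}")
    b, se = float(fit.betas[1]), float(fit.ses[1])
    return TrendResult(
        float(np.exp(b)),
        (float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
        float(2 * stats.norm.sf(abs(b / se))),
        adjust_age,
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> AucResult:
    """ROC AUC by the Mann-Whitney estimator (ties counted 1/2) with a
    DeLong 95% confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    x = scores[labels]  # cases
    ycon = scores[~labels]  # controls
    m, n = x.size, ycon.size
    if m == 0 or n == 0:
        raise ValueError("AUC needs both classes")
    # mid-rank placements (DeLong structural components)
    order = stats.rankdata(np.concatenate([x, ycon]))
    rx = order[:m]
    a = (rx.sum() - m * (m + 1) / 2) / (m * n)
    # V10_i = P(case_i beats a random control); from global and within-class ranks
    v10 = (rx - stats.rankdata(x)) / n
    ry = order[m:]
    v01 = 1.0 - (ry - stats.rankdata(ycon)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo, hi = max(0.0, a - _Z95 * se), min(1.0, a + _Z95 * se)
    return AucResult(float(a), (lo, hi))


def evaluate_model(
    gm_eval: GenotypeMatrix,
    phen_eval: PhenotypeTable,
    model: PrsModelSpec,
    missing_policy: MissingPolicy = "impute_control_freq",
    adjust_age_trend: bool = False,
    cutpoint_source: Literal["controls", "combined"] = "controls",
) -> PrsEvaluation:
    """Score the evaluation cohort and run the full quartile / trend / AUC
    battery for one model."""
    phen = phen_eval.aligned_to(gm_eval.sample_ids)
    scores = score_samples(gm_eval, model, missing_policy)
    return PrsEvaluation(
        model=model,
        scores=scores,
        quartiles=quartile_analysis(scores, phen, cutpoint_source=cutpoint_source),
        trend=trend_analysis(scores, phen, adjust_age=adjust_age_trend),
        auc=auc(scores, phen.status_array()),
    )
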