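"""Per-SNP additive logistic association.

Each SNP is tested one at a time by maximum-likelihood logistic regression
of case status on effect-allele dosage (0/1/2), optionally with age as a
linear covariate on the logit scale.  Missing genotypes (and, when
adjusting, missing ages) are excluded pairwise per SNP, matching the
per-assay call-rate framing of panel genotyping.  Estimates are reported as
log-OR (beta), OR, Wald 95% CI and a two-sided Wald p-value.

No multiple-testing correction is applied when selecting significant SNPs
(p <= alpha); a Bonferroni-adjusted column is available for transparency
but never drives selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from polyrisk.genotype_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "AssocResult",
    "LogisticFit",
    "fit_logistic",
    "snp_association",
    "associate_all",
    "significant_snps",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class LogisticFit:
    """Raw ML logistic fit: coefficient vector, Wald SEs, convergence flag."""

    betas: np.ndarray
    ses: np.ndarray
    converged: bool
    n_obs: int
    message: str = ""


@dataclass
class AssocResult:
    """Association of one SNP with case status."""

    snp_id: str
    beta: float
    se: float
    p: float
    adjusted: bool
    n_used: int
    eaf: float
    converged: bool = True
    note: str = ""

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.beta - _Z95 * self.se)),
            float(np.exp(self.beta + _Z95 * self.se)),
        )

    @property
    def valid(self) -> bool:
        return self.converged and np.isfinite(self.beta) and np.isfinite(self.se)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


def fit_logistic(y: np.ndarray, X: np.ndarray, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald standard errors.

    Newton-Raphson (equivalently iteratively reweighted least squares) with
    convergence tolerance 1e-8 and at most 100 iterations; SEs come from the
    inverse observed information at the MLE.  Constant predictor columns
    (other than the intercept) and rank deficiency raise ``ValueError``;
    separation is flagged as non-converged rather than silently reported.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("y and X have inconsistent shapes")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if classes.size < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        raise ValueError(f"constant predictor column(s) {np.nonzero(constant)[0].tolist()}")
    design = sm.add_constant(X, prepend=True) if add_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False
            )
        except Exception as exc:  # PerfectSeparation and numeric failures
            return LogisticFit(
                betas=np.full(design.shape[1], np.nan),
                ses=np.full(design.shape[1], np.nan),
                converged=False,
                n_obs=y.size,
                message=f"fit failed: {exc}",
            )
    betas = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    message = ""
    # quasi-complete separation drifts to huge coefficients / exploding SEs
    if converged and (np.abs(betas).max() > 15 or not np.isfinite(ses).all()):
        converged = False
        message = "separation suspected: unbounded coefficient estimate"
    return LogisticFit(betas, ses, converged, y.size, message)


def snp_association(
    gm: GenotypeMatrix,
    phen: PhenotypeTable,
    snp_id: str,
    adjust_age: bool = False,
) -> AssocResult:
    """Additive logistic association of one SNP, pairwise-complete.

    Samples missing the genotype at this SNP (and missing age when
    ``adjust_age``) are excluded.  A SNP monomorphic after exclusions yields
    a result with NaN effect and an explanatory note instead of an error.
    """
    phen = phen.aligned_to(gm.sample_ids)
    dose = gm.column(snp_id)
    y = phen.status_array().astype(float)
    keep = ~np.isnan(dose)
    cols = [dose]
    if adjust_age:
        age = phen.age_array()
        keep &= ~np.isnan(age)
        cols.append(age)
    X = np.column_stack(cols)[keep]
    y_use, n_used = y[keep], int(keep.sum())
    g = X[:, 0]
    eaf = float(g.sum() / (2 * g.size)) if g.size else float("nan")
    if g.size == 0 or np.ptp(g) == 0:
        return AssocResult(
            snp_id, np.nan, np.nan, np.nan, adjust_age, n_used, eaf,
            converged=False, note="monomorphic after exclusions",
        )
    fit = fit_logistic(y_use, X)
    if not fit.converged:
        return AssocResult(
            snp_id, np.nan, np.nan, np.nan, adjust_age, n_used, eaf,
            converged=False, note=fit.message or "non-convergence",
        )
    beta, se = float(fit.betas[1]), float(fit.ses[1])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssocResult(snp_id, beta, se, p, adjust_age, n_used, eaf)


def associate_all(
    gm: GenotypeMatrix, phen: PhenotypeTable, adjust_age: bool = False
) -> list[AssocResult]:
    """Run :func:`snp_association` for every SNP in the matrix."""
    return [snp_association(gm, phen, s, adjust_age=adjust_age) for s in gm.snp_ids]


def significant_snps(
    results: Sequence[AssocResult], alpha: float = 0.05
) -> list[AssocResult]:
    """SNPs with two-sided Wald p <= alpha (no multiplicity correction).

    Non-converged / monomorphic results never qualify.
    """
    if not results:
        raise ValueError("empty result list")
    return [r for r in results if r.valid and r.p <= alpha]


def association_frame(results: Sequence[AssocResult]):
    """Association results as a DataFrame (one adjustment mode per call)."""
    import pandas as pd

    n = max(len(results), 1)
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "n_used": [r.n_used for r in results],
            "eaf": [r.eaf for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "or": [r.or_ for r in results],
            "ci95_low": [r.ci95[0] for r in results],
            "ci95_high": [r.ci95[1] for r in results],
            "p": [r.p for r in results],
            "p_bonferroni": [min(1.0, r.p * n) if np.isfinite(r.p) else np.nan for r in results],
            "adjusted": [r.adjusted for r in results],
            "note": [r.note for r in results],
        }
    )
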