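"""Covariate-adjusted marginal association scan.

Each variant is tested with a maximum-likelihood logistic regression of
case status on its dosage plus the covariates (sex, age, BMI, smoking, and
the SAS/EUR/AFR ancestry proportions — the EAS component is the implicit
reference and is dropped to avoid the sum-to-one collinearity).  Continuous
covariates are standardized for conditioning; this leaves the dosage
effect's Wald test unchanged.  P-values are two-sided Wald.  Genome-wide
flagging uses the conventional 5e-8 threshold; known-variant replication is
flagged at p < 0.05, with effects re-oriented to the catalog risk allele
when it matches REF or ALT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DosageDataset, KnownVariantCatalog
from .errors import DesignError
from .qc import minor_allele_frequency

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "bmi", "smoking", "sas", "eur", "afr")
CONTINUOUS_COVARIATES = ("age", "bmi", "sas", "eur", "afr", "eas")

#: |beta| beyond which a still-moving fit is treated as (quasi-)separated
_SEPARATION_BOUND = 15.0


@dataclass
class AssocResult:
    """Marginal fit for one variant (effect on the alt-dosage scale)."""

    vid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    beta: float
    se: float
    z: float
    p: float
    or_: float
    n: int
    converged: bool


@dataclass
class ReplicationHit:
    """Scan lookup for one catalog entry."""

    vid: str
    chrom: str
    pos: int
    risk_allele: str
    found: bool
    reason: str  # "", "filtered-or-absent"
    beta_risk: float  # effect re-signed to the risk allele (NaN if unknown/absent)
    p: float
    flagged: bool
    orientation: str  # "alt", "ref-flipped", "unknown"


def fit_logistic(
    y: np.ndarray, X: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson maximum-likelihood logistic regression.

    Returns ``(coef, cov, loglik, converged)`` with ``cov`` the inverse
    observed information at the optimum.  Convergence: max |score| < 1e-8
    or relative log-likelihood change < 1e-10.  Perfect or quasi-perfect
    separation (coefficients diverging past a bound with a non-vanishing
    score) is reported as ``converged=False``.  A rank-deficient design
    raises :class:`DesignError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise DesignError(f"need more samples ({n}) than parameters ({k})")
    if np.linalg.matrix_rank(X) < k:
        raise DesignError("design matrix is rank deficient")

    beta = np.zeros(k)
    eta = X @ beta
    loglik = -n * math.log(2.0)
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the log-likelihood non-decreasing
        step_scale = 1.0
        for _ in range(30):
            cand = beta + step_scale * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= loglik - 1e-12:
                break
            step_scale *= 0.5
        beta, eta = cand, eta_c
        max_score = float(np.abs(score).max())
        rel = abs(ll_c - loglik) / (abs(loglik) + 1e-12)
        loglik = ll_c
        if max_score < 1e-8 or rel < 1e-10:
            converged = True
            break
        if np.abs(beta).max() > _SEPARATION_BOUND:
            converged = False  # (quasi-)separation: estimates diverging
            break

    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return beta, cov, loglik, converged


def build_covariate_matrix(
    dataset: DosageDataset, covariates=DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Design columns for the named covariates, continuous ones standardized.

    Raises :class:`DesignError` naming any covariate constant across samples.
    """
    frame = dataset.covariate_frame()
    cols = []
    for name in covariates:
        if name not in frame.columns:
            raise DesignError(f"unknown covariate {name!r}")
        x = frame[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            raise DesignError(f"covariate {name!r} is constant across samples")
        if name in CONTINUOUS_COVARIATES:
            x = (x - x.mean()) / x.std(ddof=0)
        cols.append(x)
    matrix = np.column_stack(cols) if cols else np.empty((dataset.n_samples, 0))
    return matrix, list(covariates)


def mean_impute(column: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the variant's mean dosage."""
    col = np.asarray(column, dtype=float).copy()
    miss = ~np.isfinite(col)
    if miss.any():
        col[miss] = col[~miss].mean()
    return col


def scan(
    dataset: DosageDataset, covariates=DEFAULT_COVARIATES, max_iter: int = 100
) -> list[AssocResult]:
    """Marginal scan: one covariate-adjusted logistic fit per variant.

    Non-converged fits (separation, monomorphic dosage) are returned with
    NaN statistics and ``converged=False``.
    """
    y = dataset.status_vector()
    n = dataset.n_samples
    covmat, _ = build_covariate_matrix(dataset, covariates)
    base = np.column_stack([np.ones(n), np.zeros(n), covmat])  # dosage in col 1

    results: list[AssocResult] = []
    for j, v in enumerate(dataset.variants):
        dose = mean_impute(dataset.dosages[:, j])
        maf = minor_allele_frequency(dose)
        base[:, 1] = dose
        try:
            coef, cov, _, ok = fit_logistic(y, base, max_iter=max_iter)
        except DesignError:
            ok = False
        if ok and np.isfinite(cov[1, 1]) and cov[1, 1] > 0:
            beta = float(coef[1])
            se = float(math.sqrt(cov[1, 1]))
            z = beta / se
            p = 2.0 * stats.norm.sf(abs(z))
            p = max(p, np.finfo(float).tiny)
            results.append(
                AssocResult(v.vid, v.chrom, v.pos, v.ref, v.alt, maf,
                            beta, se, z, p, math.exp(beta), n, True)
            )
        else:
            results.append(
                AssocResult(v.vid, v.chrom, v.pos, v.ref, v.alt, maf,
                            np.nan, np.nan, np.nan, np.nan, np.nan, n, False)
            )
    return results


def flag_genome_wide(results: list[AssocResult], alpha: float = 5e-8) -> list[AssocResult]:
    """Results with p strictly below ``alpha``, sorted ascending by p."""
    hits = [r for r in results if r.converged and np.isfinite(r.p) and r.p < alpha]
    return sorted(hits, key=lambda r: r.p)


def replicate_known(
    results: list[AssocResult],
    catalog: KnownVariantCatalog,
    dataset: DosageDataset | None = None,
) -> list[ReplicationHit]:
    """Look up catalog variants in the scan; flag replication at p < 0.05.

    Matching is by variant id, falling back to chrom+pos.  The effect is
    re-signed so it counts the catalog risk allele: unchanged when the risk
    allele is ALT, negated when it is REF, and orientation is marked
    unknown otherwise.
    """
    by_vid = {r.vid: r for r in results}
    by_locus = {(r.chrom, r.pos): r for r in results}
    hits: list[ReplicationHit] = []
    for entry in catalog:
        r = by_vid.get(entry.vid) or by_locus.get((entry.chrom, entry.pos))
        if r is None:
            hits.append(
                ReplicationHit(entry.vid, entry.chrom, entry.pos, entry.risk_allele,
                               False, "filtered-or-absent", np.nan, np.nan, False, "unknown")
            )
            continue
        if entry.risk_allele == r.alt:
            beta_risk, orientation = r.beta, "alt"
        elif entry.risk_allele == r.ref:
            beta_risk, orientation = -r.beta, "ref-flipped"
        else:
            beta_risk, orientation = np.nan, "unknown"
        flagged = bool(r.converged and np.isfinite(r.p) and r.p < 0.05)
        hits.append(
            ReplicationHit(entry.vid, entry.chrom, entry.pos, entry.risk_allele,
                           True, "", beta_risk, r.p, flagged, orientation)
        )
    return hits


def region_extract(
    results: list[AssocResult], center_vid: str, flank: int = 100_000
) -> list[AssocResult]:
    """All scan results within ``flank`` bp of the named variant, same
    chromosome only, sorted by position (the table regional association
    plots are drawn from)."""
    center = next((r for r in results if r.vid == center_vid), None)
    if center is None:
        raise KeyError(f"center variant {center_vid!r} not in results")
    rows = [
        r for r in results
        if r.chrom == center.chrom and abs(r.pos - center.pos) <= flank
    ]
    return sorted(rows, key=lambda r: r.pos)
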