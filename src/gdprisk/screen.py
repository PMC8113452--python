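"""Approximate Bayes-factor screening of the marginal scan.

Variants are ranked by a single-SNP Bayes factor for the marginal model
(dosage + covariates) against the covariate-only null, then the top K
(default 200, chosen to keep the candidate count near the sample size) are
passed to the joint polygenic model.  The screening covariate set is sex,
age, BMI and smoking — ancestry proportions are deliberately not included
at this stage.

Two standard approximations computable from the marginal Wald fit are
offered: Wakefield's asymptotic Bayes factor under a N(0, W) effect prior
(default, prior SD 0.5 on the log-odds scale), and a BIC-based factor
exp((BIC_null - BIC_alt)/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datatypes import DosageDataset
from .errors import DesignError, UsageError
from .scan import AssocResult, build_covariate_matrix, fit_logistic, mean_impute, scan

SCREEN_COVARIATES = ("sex", "age", "bmi", "smoking")
DEFAULT_PRIOR_W = 0.25  # prior effect variance: SD 0.5 on the log-odds scale
DEFAULT_K = 200


@dataclass
class ScreenResult:
    vid: str
    log10_bf: float  # NaN when the marginal fit failed
    rank: int  # 1-based; failed fits rank last
    selected: bool


def wakefield_bf(beta_hat: float, se: float, prior_w: float = DEFAULT_PRIOR_W) -> float:
    """log10 Wakefield approximate Bayes factor, alternative over null.

    With V = se^2 and z = beta_hat/se:
    BF10 = sqrt(V/(V+W)) * exp(z^2 W / (2 (V+W))).
    W = 0 collapses the prior onto the null and gives BF10 = 1.
    """
    if se <= 0:
        raise UsageError(f"se must be positive, got {se}")
    if prior_w < 0:
        raise UsageError(f"prior_w must be non-negative, got {prior_w}")
    V = se * se
    z2 = (beta_hat / se) ** 2
    log_bf = 0.5 * math.log(V / (V + prior_w)) + z2 * prior_w / (2.0 * (V + prior_w))
    return log_bf / math.log(10.0)


def bic_bf(loglik_alt: float, loglik_null: float, n: int) -> float:
    """log10 BIC-approximated Bayes factor for one extra parameter."""
    bic_alt = -2.0 * loglik_alt + math.log(n)  # relative: only the extra df matters
    bic_null = -2.0 * loglik_null
    return (bic_null - bic_alt) / (2.0 * math.log(10.0))


def screen(
    dataset: DosageDataset,
    covariates=SCREEN_COVARIATES,
    K: int = DEFAULT_K,
    prior_w: float = DEFAULT_PRIOR_W,
    mode: str = "wakefield",
    results: list[AssocResult] | None = None,
) -> list[ScreenResult]:
    """Rank all variants by log10 Bayes factor and select the top K.

    Ties are broken by ascending p-value, then genomic position, so the
    ranking is deterministic.  If fewer than K variants exist, all are
    selected.  Pass precomputed ``results`` (from a scan with the same
    covariates) to skip refitting.
    """
    if K < 1:
        raise UsageError(f"K must be >= 1, got {K}")
    if mode not in ("wakefield", "bic"):
        raise UsageError(f"unknown Bayes-factor mode {mode!r}")

    if results is None:
        results = scan(dataset, covariates=covariates)

    if mode == "wakefield":
        bfs = [
            wakefield_bf(r.beta, r.se, prior_w) if r.converged else np.nan for r in results
        ]
    else:
        bfs = _bic_bfs(dataset, covariates, results)

    order = sorted(
        range(len(results)),
        key=lambda j: (
            not results[j].converged,
            -(bfs[j] if np.isfinite(bfs[j]) else -np.inf),
            results[j].p if np.isfinite(results[j].p) else np.inf,
            results[j].chrom,
            results[j].pos,
        ),
    )
    out: list[ScreenResult | None] = [None] * len(results)
    for rank0, j in enumerate(order):
        out[j] = ScreenResult(
            vid=results[j].vid,
            log10_bf=float(bfs[j]),
            rank=rank0 + 1,
            selected=rank0 < K,
        )
    return out  # type: ignore[return-value]


def _bic_bfs(dataset, covariates, results) -> list[float]:
    y = dataset.status_vector()
    n = dataset.n_samples
    covmat, _ = build_covariate_matrix(dataset, covariates)
    X0 = np.column_stack([np.ones(n), covmat])
    _, _, ll0, _ = fit_logistic(y, X0)
    bfs: list[float] = []
    for j, r in enumerate(results):
        if not r.converged:
            bfs.append(np.nan)
            continue
        X1 = np.column_stack([np.ones(n), mean_impute(dataset.dosages[:, j]), covmat])
        try:
            _, _, ll1, ok = fit_logistic(y, X1)
        except DesignError:
            ok = False
        bfs.append(bic_bf(ll1, ll0, n) if ok else np.nan)
    return bfs


def selected_variant_indices(screen_results: list[ScreenResult], dataset: DosageDataset) -> np.ndarray:
    """Column indices of selected variants, in rank order."""
    idx = dataset.variant_index()
    chosen = sorted((s for s in screen_results if s.selected), key=lambda s: s.rank)
    return np.array([idx[s.vid] for s in chosen], dtype=int)
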