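"""Latent-confounder estimation for the EWAS and clock designs.

Unmeasured structure (cell-type composition, batch, ancestry beyond the
recorded covariates) inflates array-wide association statistics. We
estimate it by residualizing the methylation matrix on the known
covariates and taking the top left singular vectors of the residual as
factor scores, with the number of factors chosen by parallel analysis
(each leading singular value is kept while it is significant at the 5%
level against column-wise permutations of the residual matrix).

Two flavors are offered. The outcome-agnostic estimator (no ``outcome``
argument) can absorb a dense trait-aligned direction — including real
signal when many CpGs track the trait — but is the only one able to
remove confounding that is collinear with the trait. Passing the trait
as ``outcome`` residualizes it away first (as surrogate-variable methods
do with the full model), so sparse true signal is protected at the cost
of leaving trait-collinear confounding in place. The analysis pipeline
uses the protected flavor; the agnostic one is what restores null
calibration on trait-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LatentFactors", "estimate_num_factors", "estimate_latent_factors"]


@dataclass
class LatentFactors:
    """Estimated factor scores for the cohort samples.

    ``scores`` is samples x K, columns centered and mutually orthogonal;
    ``variance_explained`` is each factor's share of the residual-matrix
    variance.
    """

    scores: np.ndarray
    K: int
    method_tag: str = "residual-svd"
    variance_explained: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _covariate_matrix(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not np.any(np.all(C == C[0], axis=0)):  # ensure an intercept column
        C = np.column_stack([np.ones(n), C])
    return C


def _residualize(Y: np.ndarray, covariates) -> np.ndarray:
    """Residual of Y (samples x probes) on the covariate design (with intercept)."""
    C = _covariate_matrix(Y.shape[0], covariates)
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ coef


def estimate_num_factors(
    m, covariates=None, max_k: int = 10, n_perm: int = 20, seed: int = 0
) -> int:
    """Parallel-analysis choice of the number of latent factors.

    ``m`` is probes x samples. The residual matrix's k-th singular value
    is compared against k-th singular values from ``n_perm`` datasets in
    which each probe's residuals are independently permuted across
    samples (destroying cross-probe structure, preserving marginals); K
    is the count of leading factors significant at the 5% level under
    this permutation null, stopping at the first failure and capped at
    ``max_k``.
    """
    if max_k <= 0:
        raise ValueError("max_k must be positive")
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19 for a 5%-level permutation test")
    Y = np.asarray(m, dtype=float).T  # samples x probes
    if max_k >= min(Y.shape):
        raise ValueError("max_k must be smaller than both matrix dimensions")
    R = _residualize(Y, covariates)
    sv = np.linalg.svd(R, compute_uv=False)[:max_k]
    rng = np.random.default_rng(seed)
    null_sv = np.empty((n_perm, max_k))
    col_norms = np.linalg.norm(R, axis=0)
    for b in range(n_perm):
        P = rng.permuted(R, axis=0)  # permute each column (probe) independently
        # re-residualize so the null matrices live in the same
        # covariate-orthogonal subspace as the observed residual, then
        # restore column norms (projection removes ~q/n of each column's
        # variance a second time, which would bias the null downward)
        P = _residualize(P, covariates)
        norms = np.linalg.norm(P, axis=0)
        np.divide(col_norms, norms, out=norms, where=norms > 0)
        P = P * norms
        null_sv[b] = np.linalg.svd(P, compute_uv=False)[:max_k]
    # finite-sample-exact version of the 95th-percentile cut: the k-th
    # factor is kept when at most floor(0.05*(B+1)) - 1 of B permutation
    # draws reach the observed singular value
    K = 0
    for k in range(max_k):
        p_perm = (1 + int((null_sv[:, k] >= sv[k]).sum())) / (n_perm + 1)
        if p_perm <= 0.05:
            K += 1
        else:
            break
    return K


def estimate_latent_factors(m, covariates=None, outcome=None, K: int = 0) -> LatentFactors:
    """Top-K left singular vectors of the residualized methylation matrix.

    When ``outcome`` (the GA vector) is supplied it joins the
    residualization design, so the estimated factors are orthogonal to the
    outcome in-sample and cannot absorb sparse true signal — the same
    protection surrogate-variable methods apply by residualizing on the
    full model. Without it the estimator is outcome-agnostic (see module
    docstring for the tradeoff). Scores are centered, orthogonal, and
    sign-fixed so each factor's largest-magnitude probe loading is
    positive, making runs reproducible. ``K = 0`` yields an empty factor
    set.
    """
    Y = np.asarray(m, dtype=float).T  # samples x probes
    n = Y.shape[0]
    if K == 0:
        return LatentFactors(scores=np.zeros((n, 0)), K=0)
    C = _covariate_matrix(n, covariates)
    if outcome is not None:
        C = np.column_stack([C, np.asarray(outcome, dtype=float)])
    R = _residualize(Y, C)
    rank = np.linalg.matrix_rank(R)
    if K > rank:
        raise ValueError(f"K={K} exceeds residual-matrix rank {rank}")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    scores = U[:, :K] * s[:K]
    for k in range(K):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    scores = scores - scores.mean(axis=0)
    var_exp = (s[:K] ** 2) / float(np.sum(s**2))
    tag = "residual-svd" + ("+outcome-protected" if outcome is not None else "")
    return LatentFactors(scores=scores, K=K, method_tag=tag, variance_explained=var_exp)
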