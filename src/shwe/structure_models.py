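"""Estimators of the individual-specific allele-frequency surface F.

Each estimator maps a genotype matrix X (m SNPs x n individuals) and a
latent dimensionality K to an m x n matrix of individual-specific allele
frequencies pi_ij with x_ij ~ Binomial(2, pi_ij). The intercept (SNP-wise
mean frequency) counts as the first latent dimension for every bundled
estimator, so K=1 is the unstructured model and reproduces the marginal
allele frequencies.

Bundled estimators:

* ``marginal`` — pi_ij = p_i for all j (K must be 1).
* ``pca`` — truncated PCA: rank-K reconstruction of X (row mean plus the
  top K-1 principal components of the row-centered matrix), scaled by 1/2
  and clipped to [1/(2n), 1 - 1/(2n)].
* ``lfa`` — logistic factor analysis, factorizing logit(F) = A H with an
  explicit intercept row in H. The logistic factors are extracted from the
  logit of the clipped rank-K reconstruction, and per-SNP loadings are fit
  by binomial logistic regression (vectorized Newton iterations).

Additional estimators (e.g. wrappers around external admixture fitters) can
be plugged in through :func:`register_estimator`; their outputs are
validated against the FrequencySurface invariants on every call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import svd as _full_svd
from scipy.special import expit, logit
from sklearn.utils.extmath import randomized_svd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

# SVD strategy: exact below this size, seeded randomized above (deterministic
# either way).
FULL_SVD_MAX_DIM = 500
RANDOMIZED_SVD_SEED = 1905
RANDOMIZED_SVD_ITER = 7

# LFA logistic-regression settings.
LFA_MAX_ITER = 40
LFA_STEP_TOL = 1e-8
LFA_MAX_STEP = 4.0
LFA_MAX_COEF = 30.0
LFA_RIDGE = 1e-10
_ETA_CAP = 15.0


class SurfaceValidationError(ValueError):
    """An estimator produced a surface violating a FrequencySurface invariant."""


class LFAConvergenceError(RuntimeError):
    """LFA logistic regression produced non-finite values."""


@dataclass
class FrequencySurface:
    """A fitted m x n allele-frequency surface.

    Attributes
    ----------
    freqs
        Matrix of pi_ij, clipped to ``clip_bounds``.
    K
        Latent dimensionality used (intercept counted as the first).
    estimator_id
        Name of the fitting method.
    clip_bounds
        (1/(2n), 1 - 1/(2n)); the frequency of a single allele copy.
    """

    freqs: np.ndarray
    K: int
    estimator_id: str
    clip_bounds: tuple[float, float]

    @property
    def m(self) -> int:
        return self.freqs.shape[0]

    @property
    def n(self) -> int:
        return self.freqs.shape[1]


def clip_bounds_for(n: int) -> tuple[float, float]:
    return (1.0 / (2 * n), 1.0 - 1.0 / (2 * n))


def _validate_surface(surf: FrequencySurface, g: GenotypeMatrix, K: int) -> None:
    if not isinstance(surf, FrequencySurface):
        raise SurfaceValidationError("estimator must return a FrequencySurface")
    if surf.freqs.shape != g.values.shape:
        raise SurfaceValidationError(
            f"surface shape {surf.freqs.shape} does not match genotype "
            f"matrix shape {g.values.shape}"
        )
    lo, hi = clip_bounds_for(g.n)
    fmin, fmax = float(surf.freqs.min()), float(surf.freqs.max())
    if fmin < lo - 1e-12 or fmax > hi + 1e-12:
        raise SurfaceValidationError(
            f"surface values [{fmin:.6g}, {fmax:.6g}] violate clip bounds "
            f"[{lo:.6g}, {hi:.6g}]"
        )
    if surf.K != K:
        raise SurfaceValidationError(f"surface reports K={surf.K}, expected {K}")


# ----------------------------------------------------------------------
# Shared numerics
# ----------------------------------------------------------------------

def _imputed_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Float copy of the dosage matrix with per-SNP mean imputation."""
    x = g.values.astype(np.float64)
    miss = g.missing_mask
    if miss.any():
        obs = ~miss
        counts = obs.sum(axis=1)
        if (counts == 0).any():
            i = int(np.argmax(counts == 0))
            raise ValueError(f"SNP {g.snp_ids[i]!r} has no non-missing calls")
        means = np.where(obs, x, 0.0).sum(axis=1) / counts
        x = np.where(miss, means[:, None], x)
    return x


def _svd_lowrank(mat: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-``rank`` SVD: exact for small matrices, seeded randomized otherwise."""
    if rank == 0:
        m, n = mat.shape
        return np.zeros((m, 0)), np.zeros(0), np.zeros((0, n))
    if min(mat.shape) <= FULL_SVD_MAX_DIM:
        u, s, vt = _full_svd(mat, full_matrices=False)
        return u[:, :rank], s[:rank], vt[:rank]
    return randomized_svd(
        mat,
        n_components=rank,
        n_iter=RANDOMIZED_SVD_ITER,
        random_state=RANDOMIZED_SVD_SEED,
    )


def _rank_k_reconstruction(x: np.ndarray, K: int) -> np.ndarray:
    """Row mean plus top K-1 principal components of the row-centered matrix."""
    mu = x.mean(axis=1, keepdims=True)
    if K == 1:
        return np.broadcast_to(mu, x.shape).copy()
    u, s, vt = _svd_lowrank(x - mu, K - 1)
    return mu + (u * s) @ vt


# ----------------------------------------------------------------------
# Bundled estimators
# ----------------------------------------------------------------------

def fit_marginal(g: GenotypeMatrix) -> FrequencySurface:
    """Unstructured model: pi_ij = p_i, the SNP's observed allele frequency."""
    p = g.allele_freqs()
    if np.isnan(p).any():
        i = int(np.argmax(np.isnan(p)))
        raise ValueError(f"SNP {g.snp_ids[i]!r} has no non-missing calls")
    lo, hi = clip_bounds_for(g.n)
    freqs = np.clip(np.repeat(p[:, None], g.n, axis=1), lo, hi)
    return FrequencySurface(freqs, K=1, estimator_id="marginal", clip_bounds=(lo, hi))


def fit_truncated_pca(g: GenotypeMatrix, K: int) -> FrequencySurface:
    """Truncated-PCA surface: rank-K reconstruction of X scaled by 1/2.

    Values outside the clip bounds are replaced by 1/(2n) or 1 - 1/(2n).
    """
    _check_k(g, K)
    x = _imputed_matrix(g)
    lo, hi = clip_bounds_for(g.n)
    freqs = np.clip(_rank_k_reconstruction(x, K) / 2.0, lo, hi)
    return FrequencySurface(freqs, K=K, estimator_id="pca", clip_bounds=(lo, hi))


def fit_lfa(g: GenotypeMatrix, K: int) -> FrequencySurface:
    """Logistic factor analysis: logit(F) = A H with an intercept row in H.

    For K=1 the factorization is intercept-only and the maximum-likelihood
    fit is exactly the marginal allele frequency, so the marginal surface is
    returned directly.
    """
    _check_k(g, K)
    lo, hi = clip_bounds_for(g.n)
    if K == 1:
        surf = fit_marginal(g)
        return FrequencySurface(surf.freqs, K=1, estimator_id="lfa", clip_bounds=(lo, hi))

    x = _imputed_matrix(g)
    # Logistic factors: logit of the clipped rank-K dosage reconstruction,
    # row-centered (the explicit intercept column absorbs the means).
    z = np.clip(_rank_k_reconstruction(x, K) / 2.0, lo, hi)
    l_mat = logit(z)
    _, _, vt = _svd_lowrank(l_mat - l_mat.mean(axis=1, keepdims=True), K - 1)
    design = np.column_stack([vt.T, np.ones(g.n)])  # n x K, intercept last

    coef = _binomial_logistic_fit(g, design)
    eta = np.clip(coef @ design.T, -_ETA_CAP, _ETA_CAP)
    freqs = np.clip(expit(eta), lo, hi)
    return FrequencySurface(freqs, K=K, estimator_id="lfa", clip_bounds=(lo, hi))


def _check_k(g: GenotypeMatrix, K: int) -> None:
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > min(g.m, g.n):
        raise ValueError(f"K={K} exceeds min(m, n) = {min(g.m, g.n)}")


def _binomial_logistic_fit(g: GenotypeMatrix, design: np.ndarray) -> np.ndarray:
    """Per-SNP Newton fit of x_ij ~ Binomial(2, expit(a_i . h_j)).

    All m regressions share the n x K design and are advanced together.
    Missing calls carry zero weight. Steps and coefficients are clamped so
    separated/monomorphic SNPs stabilize at the probability bounds instead
    of diverging; an error is raised only if non-finite values appear.
    """
    m, n = g.values.shape
    k = design.shape[1]
    obs = (~g.missing_mask).astype(np.float64)
    x = np.where(g.missing_mask, 0, g.values).astype(np.float64)

    p_hat = np.clip(g.allele_freqs(), 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    coef = np.zeros((m, k))
    coef[:, -1] = logit(p_hat)

    diag = np.arange(k)
    for it in range(LFA_MAX_ITER):
        eta = np.clip(coef @ design.T, -_ETA_CAP, _ETA_CAP)
        p = expit(eta)
        w = 2.0 * p * (1.0 - p) * obs
        grad = ((x - 2.0 * p) * obs) @ design
        hess = np.einsum("ij,jk,jl->ikl", w, design, design, optimize=True)
        hess[:, diag, diag] += LFA_RIDGE
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        np.clip(step, -LFA_MAX_STEP, LFA_MAX_STEP, out=step)
        coef += step
        np.clip(coef, -LFA_MAX_COEF, LFA_MAX_COEF, out=coef)
        if not np.isfinite(coef).all():
            raise LFAConvergenceError(
                f"non-finite LFA coefficients at Newton iteration {it + 1}"
            )
        if np.max(np.abs(step)) < LFA_STEP_TOL:
            break
    return coef


# ----------------------------------------------------------------------
# Estimator registry
# ----------------------------------------------------------------------

EstimatorFn = Callable[[GenotypeMatrix, int], FrequencySurface]

_ESTIMATORS: dict[str, EstimatorFn] = {}


def register_estimator(estimator_id: str, fit_fn: EstimatorFn) -> None:
    """Make ``fit_fn`` available to the pipeline under ``estimator_id``."""
    if estimator_id in _ESTIMATORS:
        raise ValueError(f"estimator id {estimator_id!r} is already registered")
    _ESTIMATORS[estimator_id] = fit_fn


def unregister_estimator(estimator_id: str) -> None:
    _ESTIMATORS.pop(estimator_id, None)


def available_estimators() -> tuple[str, ...]:
    return tuple(sorted(_ESTIMATORS))


def fit_surface(g: GenotypeMatrix, estimator_id: str, K: int) -> FrequencySurface:
    """Fit a frequency surface by name, validating the output invariants."""
    try:
        fit_fn = _ESTIMATORS[estimator_id]
    except KeyError:
        raise KeyError(
            f"unknown estimator {estimator_id!r}; available: {available_estimators()}"
        ) from None
    surf = fit_fn(g, K)
    _validate_surface(surf, g, K)
    return surf


def _fit_marginal_estimator(g: GenotypeMatrix, K: int) -> FrequencySurface:
    if K != 1:
        raise ValueError("the marginal estimator only supports K=1")
    return fit_marginal(g)


register_estimator("marginal", _fit_marginal_estimator)
register_estimator("pca", fit_truncated_pca)
register_estimator("lfa", fit_lfa)
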