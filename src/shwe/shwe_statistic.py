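"""The structural HWE test statistic for a single SNP.

Under the structural null each genotype x_j is an independent
Binomial(2, pi_j) draw with its own allele frequency pi_j, so the genotype
class probabilities for individual j are

    p_j(0) = (1 - pi_j)^2,  p_j(1) = 2 pi_j (1 - pi_j),  p_j(2) = pi_j^2.

With v = (N(0), N(1)) the first two genotype counts, the CLT gives v an
asymptotic bivariate Normal law with mean mu = (sum_j p_j(0), sum_j p_j(1))
and covariance

    Sigma = [[ sum p_j(0)(1-p_j(0)),  -sum p_j(0) p_j(1) ],
             [ -sum p_j(0) p_j(1),     sum p_j(1)(1-p_j(1)) ]],

and the quadratic form T = (v - mu)^T Sigma^{-1} (v - mu) is asymptotically
chi-squared with 2 degrees of freedom regardless of the pi_j (a pivotal
statistic). When all pi_j are equal, T reduces exactly to the usual
three-category Pearson chi-squared goodness-of-fit statistic for HWE.

Missing calls drop individual j from the counts, mean, and covariance. When
Sigma is numerically singular (condition number beyond
``SIGMA_CONDITION_MAX``) the statistic is flagged undefined (NaN) rather
than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING

#: Sigma condition-number tolerance beyond which T is flagged undefined.
SIGMA_CONDITION_MAX = 1e12


@dataclass
class GenotypeCounts:
    """Genotype class counts among non-missing calls."""

    n0: int
    n1: int
    n2: int

    @property
    def n_eff(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass
class NullMoments:
    """Asymptotic moments of v = (N(0), N(1)) under the structural null."""

    mu: np.ndarray        # length 2
    sigma: np.ndarray     # 2 x 2
    condition: float      # eigenvalue ratio of sigma


def count_genotypes(x: np.ndarray) -> GenotypeCounts:
    x = np.asarray(x)
    return GenotypeCounts(
        n0=int((x == 0).sum()), n1=int((x == 1).sum()), n2=int((x == 2).sum())
    )


def genotype_probs(pi):
    """Genotype class probabilities ((1-pi)^2, 2 pi (1-pi), pi^2).

    ``pi`` may be a scalar or array; values must lie strictly in (0, 1)
    (clipping to the open interval is the frequency estimator's job).
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    q = 1.0 - pi
    return q * q, 2.0 * pi * q, pi * pi


def null_moments(pi: np.ndarray) -> NullMoments:
    """Moments of (N(0), N(1)) for one SNP given its frequency vector."""
    pi = np.asarray(pi, dtype=float)
    if pi.size == 0:
        raise ValueError("empty frequency vector")
    p0, p1, _ = genotype_probs(pi)
    mu = np.array([p0.sum(), p1.sum()])
    a = float((p0 * (1.0 - p0)).sum())
    b = float((p1 * (1.0 - p1)).sum())
    c = float(-(p0 * p1).sum())
    sigma = np.array([[a, c], [c, b]])
    return NullMoments(mu=mu, sigma=sigma, condition=float(_condition_2x2(a, b, c)))


def _condition_2x2(a, b, c):
    """Eigenvalue-ratio condition number of [[a, c], [c, b]] (symmetric PSD)."""
    tr = a + b
    disc = np.sqrt((a - b) ** 2 + 4.0 * c * c)
    lam_min = (tr - disc) / 2.0
    lam_max = (tr + disc) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(lam_min > 0.0, lam_max / lam_min, np.inf)


def shwe_statistic(x: np.ndarray, pi: np.ndarray) -> float:
    """The sHWE statistic T for one SNP; NaN flags an undefined statistic.

    ``x`` is the genotype vector (``MISSING`` entries dropped together with
    their ``pi`` entries); ``pi`` the matching allele-frequency vector.
    """
    x = np.asarray(x)
    pi = np.asarray(pi, dtype=float)
    if x.shape != pi.shape:
        raise ValueError(f"length mismatch: x has {x.shape}, pi has {pi.shape}")
    keep = x != MISSING
    if not keep.any():
        return float("nan")
    t, defined = shwe_statistics(x[None, keep], pi[None, keep])
    return float(t[0]) if defined[0] else float("nan")


def shwe_statistics(
    X: np.ndarray, F: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP statistics for an m x n genotype matrix.

    Parameters
    ----------
    X
        Genotype matrix with ``MISSING`` sentinels allowed.
    F
        Matching m x n allele-frequency matrix, entries strictly in (0, 1).

    Returns
    -------
    (T, defined)
        Length-m statistic array (NaN where undefined) and a boolean mask of
        defined entries. A statistic is undefined when the SNP has no
        non-missing calls or Sigma has condition number beyond tolerance.
    """
    X = np.asarray(X)
    F = np.asarray(F, dtype=float)
    if X.shape != F.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs F {F.shape}")
    obs = X != MISSING
    p0, p1, _ = genotype_probs(F)
    p0 = np.where(obs, p0, 0.0)
    p1 = np.where(obs, p1, 0.0)

    mu0 = p0.sum(axis=1)
    mu1 = p1.sum(axis=1)
    a = (p0 * (1.0 - p0) * obs).sum(axis=1)
    b = (p1 * (1.0 - p1) * obs).sum(axis=1)
    c = -(p0 * p1).sum(axis=1)

    d0 = (X == 0).sum(axis=1) - mu0
    d1 = (X == 1).sum(axis=1) - mu1

    det = a * b - c * c
    cond = _condition_2x2(a, b, c)
    defined = obs.any(axis=1) & (det > 0.0) & (cond <= SIGMA_CONDITION_MAX)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b * d0 * d0 - 2.0 * c * d0 * d1 + a * d1 * d1) / det
    t = np.where(defined, t, np.nan)
    # quadratic form in a PD matrix; clamp tiny negative round-off
    return np.where(defined & (t < 0.0), 0.0, t), defined
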