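"""Storey-type FDR machinery: pi0 estimation and q-values.

pi0 — the proportion of truly null hypotheses (SNPs in structural HWE) — is
estimated by the bootstrap variant of the Storey estimator: for each lambda
on a grid, pihat0(lambda) = #{p > lambda} / (m (1 - lambda)); bootstrap
resampling picks the lambda whose estimate has the smallest estimated MSE
against the minimum pihat0 over the grid. q-values follow the usual
step-up construction q_i = min_{p_j >= p_i} pi0 * m * p_j / rank(p_j),
clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)
N_BOOTSTRAP = 100
MIN_PVALUES = 100


@dataclass
class FDRSummary:
    pi0: float
    q_values: np.ndarray
    n_significant_at: dict[float, int] = field(default_factory=dict)


def estimate_pi0(
    p: np.ndarray,
    lambdas: np.ndarray = LAMBDA_GRID,
    n_bootstrap: int = N_BOOTSTRAP,
    seed: int = 0,
) -> float:
    """Bootstrap-selected Storey estimate of the null proportion pi0.

    NaN entries (undefined p-values) are dropped first. Raises if fewer
    than ``MIN_PVALUES`` defined p-values remain (the estimator is unstable
    on tiny inputs).
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < MIN_PVALUES:
        raise ValueError(
            f"need at least {MIN_PVALUES} defined p-values to estimate pi0, got {p.size}"
        )
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size

    p_sorted = np.sort(p)
    tail = m - np.searchsorted(p_sorted, lambdas, side="right")
    pi0_lam = tail / (m * (1.0 - lambdas))
    min_pi0 = pi0_lam.min()

    rng = np.random.default_rng(seed)
    mse = np.zeros_like(lambdas)
    for _ in range(n_bootstrap):
        boot = np.sort(rng.choice(p_sorted, size=m, replace=True))
        tail_b = m - np.searchsorted(boot, lambdas, side="right")
        pi0_b = tail_b / (m * (1.0 - lambdas))
        mse += (pi0_b - min_pi0) ** 2
    best = int(np.argmin(mse))
    return float(np.clip(pi0_lam[best], 0.0, 1.0))


def qvalues(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Step-up q-values; NaN p-values yield NaN q-values.

    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j), clamped to 1.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must be in [0, 1], got {pi0}")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    if np.any(pv < 0.0) or np.any(pv > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * pi0 * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    restored = np.empty(m)
    restored[order] = q
    out[mask] = restored
    return out


def fdr_summary(
    p: np.ndarray,
    thresholds: tuple[float, ...] = (0.05, 0.2),
    seed: int = 0,
) -> FDRSummary:
    """Convenience wrapper: pi0, q-values, and counts at q thresholds."""
    pi0 = estimate_pi0(p, seed=seed)
    q = qvalues(p, pi0=pi0)
    counts = {t: int(np.nansum(q <= t)) for t in thresholds}
    return FDRSummary(pi0=pi0, q_values=q, n_significant_at=counts)
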