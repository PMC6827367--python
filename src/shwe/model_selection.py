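"""Entropy-based selection of the latent dimensionality K.

A well-specified structure model yields genome-wide sHWE p-values that are
Uniform(0, 1) apart from a spike near zero (the truly deviating SNPs). The
selection procedure quantifies this: bin the p-values for each candidate K
into C equal bins on [0, 1], drop the first bin [0, 1/C) (it holds the
genuinely significant SNPs), renormalize the remaining C-1 bin proportions
to sum to one, and compute their Shannon entropy -sum f_c log f_c (natural
log; 0 log 0 = 0). Under-fit models skew p-values toward zero, over-fit
models toward one; both depress the entropy, which is maximal (log(C-1))
for a uniform profile. The chosen K is where the entropy plateaus,
preferring the smallest K on the plateau.

Plateau detection: by default a candidate K belongs to the plateau when its
entropy is within a noise-scaled band of the maximum. For N p-values spread
near-uniformly over C-1 bins, the plug-in entropy sits below log(C-1) by a
chi-square-like deficit with standard error sqrt(2 (C-2)) / (2 N); the band
is ``PLATEAU_Z`` times that. A fixed relative tolerance (entropy within
``(1 - plateau_tolerance) * max``) can be requested instead by passing a
number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .empirical_null import DEFAULT_B, SHWEResult, run_shwe
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_C = 150
#: Multiplier on the entropy-deficit standard error in the default plateau band.
PLATEAU_Z = 3.0
#: Advisory: with fewer than this many p-values per bin, shrink C.
MIN_PVALUES_PER_BIN = 50


@dataclass
class EntropyProfile:
    """Entropy of the p-value distribution per candidate K, and the choice.

    ``plateau_tolerance`` records the relative tolerance when one was given,
    or NaN when the default noise-scaled band was used (the per-candidate
    absolute bands are then in ``plateau_band``).
    """

    k_values: np.ndarray
    entropies: np.ndarray
    C: int
    selected_k: int
    plateau_tolerance: float
    plateau_band: np.ndarray | None = None


def entropy_of_pvalues(p: np.ndarray, C: int = DEFAULT_C) -> float:
    """Entropy of the binned p-value distribution after dropping bin [0, 1/C).

    Bin edges are [c/C, (c+1)/C) with the final bin closed at 1. NaN entries
    (undefined p-values) are excluded before binning. Returns 0 with a
    warning if no p-values remain outside the dropped bin.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if C < 2:
        raise ValueError(f"C must be >= 2, got {C}")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size / C < MIN_PVALUES_PER_BIN:
        warnings.warn(
            f"only {p.size / C:.1f} p-values per bin (< {MIN_PVALUES_PER_BIN}); "
            "consider a smaller C for small data sets",
            stacklevel=2,
        )
    counts, _ = np.histogram(p, bins=C, range=(0.0, 1.0))
    remaining = counts[1:]
    total = remaining.sum()
    if total == 0:
        warnings.warn("all p-values fall in the dropped first bin", stacklevel=2)
        return 0.0
    f = remaining / total
    nz = f[f > 0]
    return float(-(nz * np.log(nz)).sum())


def select_k(
    results_by_k: Mapping[int, np.ndarray],
    C: int = DEFAULT_C,
    plateau_tolerance: float | None = None,
) -> EntropyProfile:
    """Choose K from per-K p-value vectors by the entropy plateau rule.

    The selected K is the smallest candidate on the plateau — erring toward
    smaller K. With ``plateau_tolerance=None`` (default) the plateau is
    "entropy within ``PLATEAU_Z`` standard errors of the maximum", with the
    entropy-deficit standard error sqrt(2 (C-2)) / (2 N_K) for the N_K
    p-values the candidate has outside the dropped bin. Passing a fraction
    uses the fixed relative rule ``entropy >= (1 - tol) * max`` instead.
    """
    if len(results_by_k) < 2:
        raise ValueError("need at least 2 candidate K values")
    k_values = np.array(sorted(results_by_k))
    entropies = np.empty(len(k_values))
    n_kept = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        p = np.asarray(results_by_k[k], dtype=float)
        p = p[np.isfinite(p)]
        if p.size == 0:
            raise ValueError(f"no defined p-values for K={k}")
        entropies[i] = entropy_of_pvalues(p, C=C)
        n_kept[i] = max(int((p >= 1.0 / C).sum()), 1)
    if plateau_tolerance is None:
        band = PLATEAU_Z * np.sqrt(2.0 * max(C - 2, 1)) / (2.0 * n_kept)
        on_plateau = entropies >= entropies.max() - band
        tol_recorded = float("nan")
    else:
        band = None
        on_plateau = entropies >= (1.0 - plateau_tolerance) * entropies.max()
        tol_recorded = plateau_tolerance
    selected = int(k_values[np.argmax(on_plateau)])
    return EntropyProfile(
        k_values=k_values,
        entropies=entropies,
        C=C,
        selected_k=selected,
        plateau_tolerance=tol_recorded,
        plateau_band=band,
    )


def sweep_k(
    g: GenotypeMatrix,
    k_values: Sequence[int],
    estimator_id: str = "lfa",
    B: int = DEFAULT_B,
    C: int = DEFAULT_C,
    seed: int = 0,
    plateau_tolerance: float | None = None,
) -> tuple[EntropyProfile, dict[int, SHWEResult]]:
    """Run the full sHWE test for each K and select one by entropy.

    Every candidate K reuses the same master seed, so the underlying null
    replicates are paired across K. Pairing cancels the shared Monte-Carlo
    noise in the entropy differences between candidates, which sharpens the
    plateau comparison at no extra cost.
    """
    k_values = sorted(set(int(k) for k in k_values))
    if len(k_values) < 2:
        raise ValueError("K sweep needs at least 2 distinct values")
    results: dict[int, SHWEResult] = {}
    for k in k_values:
        logger.info("sweep: running sHWE at K=%d", k)
        results[k] = run_shwe(g, estimator_id=estimator_id, K=k, B=B, seed=seed)
    profile = select_k(
        {k: r.p_values for k, r in results.items()},
        C=C,
        plateau_tolerance=plateau_tolerance,
    )
    logger.info("sweep: selected K=%d", profile.selected_k)
    return profile, results
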