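"""Parametric-bootstrap empirical null and pooled p-values.

The sHWE statistic is pivotal (chi-squared with 2 df under the null no
matter the allele frequencies), but estimating the frequency surface from
the data being tested perturbs that null. The test therefore builds an
empirical null: simulate B complete genotype matrices from the fitted
surface (x0_ij ~ Binomial(2, pihat_ij)), refit the structure model on each
simulated matrix with the same estimator and K, compute the null
statistics, and pool them across SNPs and replicates. Pivotality is what
licenses the pooling, which buys p-value resolution 1/(mB) from only a few
replicates.

The per-SNP p-value is the pooled-null exceedance fraction

    p_i = #{T0 >= T_i} / (m B)

(undefined statistics excluded from both sides, so the denominator is the
count of defined null statistics). ``marginal_null_pvalues`` computes the
non-pooled per-SNP version as a diagnostic for validating the pooling.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, write_results
from .shwe_statistic import shwe_statistics
from .structure_models import FrequencySurface, fit_surface

logger = logging.getLogger(__name__)

DEFAULT_B = 3
MARGINAL_MIN_B = 100


@dataclass
class SHWEResult:
    """Genome-wide sHWE test output."""

    snp_ids: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    defined: np.ndarray
    K: int
    B: int
    estimator_id: str
    seed: int
    n_null_defined: int = 0
    q_values: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "statistic": self.statistics,
                "p_value": self.p_values,
                "q_value": np.full(self.m, np.nan) if self.q_values is None else self.q_values,
                "flag": np.where(self.defined, "ok", "undefined"),
            }
        )
        return df

    def save(self, results_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the result TSV and a JSON metadata sidecar."""
        write_results(
            results_path,
            self.snp_ids,
            self.statistics,
            self.p_values,
            q_values=self.q_values,
            flags=np.where(self.defined, "ok", "undefined"),
        )
        if sidecar_path is not None:
            meta = {
                "K": self.K,
                "B": self.B,
                "estimator_id": self.estimator_id,
                "seed": self.seed,
                "m": self.m,
                "n_undefined": self.n_undefined,
                "n_null_defined": self.n_null_defined,
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def replicate_seeds(seed: int, B: int) -> list[np.random.SeedSequence]:
    """Per-replicate seed sequences; replicate b's stream is independent of B."""
    return [np.random.SeedSequence(seed, spawn_key=(b,)) for b in range(B)]


def simulate_null_matrix(
    f: FrequencySurface, seed: int | np.random.SeedSequence | np.random.Generator
) -> GenotypeMatrix:
    """Draw a complete genotype matrix with x_ij ~ Binomial(2, pihat_ij)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.binomial(2, f.freqs).astype(np.int8)
    m, n = values.shape
    return GenotypeMatrix(
        values,
        snp_ids=np.array([f"null_snp{i}" for i in range(m)], dtype=object),
        sample_ids=np.array([f"null_smp{j}" for j in range(n)], dtype=object),
    )


def pooled_pvalues(
    t_obs: np.ndarray, t_null: np.ndarray, smooth: bool = False
) -> np.ndarray:
    """Empirical exceedance p-values against a pooled null sample.

    NaN entries (undefined statistics) are excluded on both sides; an
    undefined observed statistic yields a NaN p-value. With ``smooth`` the
    add-one estimate (count + 1)/(total + 1) is returned instead of the
    plain exceedance fraction (off by default).
    """
    t_obs = np.asarray(t_obs, dtype=float)
    null_sorted = np.sort(np.asarray(t_null, dtype=float))
    null_sorted = null_sorted[np.isfinite(null_sorted)]
    total = null_sorted.size
    if total == 0:
        raise ValueError("no defined null statistics to pool")
    defined = np.isfinite(t_obs)
    count = total - np.searchsorted(null_sorted, t_obs, side="left")
    if smooth:
        p = (count + 1.0) / (total + 1.0)
    else:
        p = count / total
    return np.where(defined, p, np.nan)


def run_shwe(
    g: GenotypeMatrix,
    estimator_id: str = "lfa",
    K: int = 1,
    B: int = DEFAULT_B,
    seed: int = 0,
    smooth: bool = False,
) -> SHWEResult:
    """Genome-wide sHWE test with a pooled parametric-bootstrap null.

    Fits the structure model at dimensionality ``K``, computes the observed
    statistics, then for each of ``B`` replicates simulates a complete null
    matrix from the fitted surface, refits the model on it with the same
    estimator and settings, and pools the resulting null statistics into the
    empirical null used for the p-values.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    surf = fit_surface(g, estimator_id, K)
    t_obs, defined = shwe_statistics(g.values, surf.freqs)

    t_null_parts = []
    for b, ss in enumerate(replicate_seeds(seed, B)):
        t0 = time.perf_counter()
        g0 = simulate_null_matrix(surf, np.random.default_rng(ss))
        try:
            surf0 = fit_surface(g0, estimator_id, K)
        except Exception as exc:
            raise RuntimeError(
                f"estimator {estimator_id!r} failed on null replicate {b}: {exc}"
            ) from exc
        t_null_b, defined_b = shwe_statistics(g0.values, surf0.freqs)
        t_null_parts.append(t_null_b[defined_b])
        logger.info(
            "null replicate %d/%d: %d defined statistics, %.2fs",
            b + 1, B, int(defined_b.sum()), time.perf_counter() - t0,
        )
    t_null = np.concatenate(t_null_parts)
    p = pooled_pvalues(t_obs, t_null, smooth=smooth)
    n_und = int((~defined).sum())
    if n_und:
        logger.info("%d of %d observed statistics undefined (excluded)", n_und, g.m)
    return SHWEResult(
        snp_ids=g.snp_ids.copy(),
        statistics=t_obs,
        p_values=p,
        defined=defined & np.isfinite(p),
        K=K,
        B=B,
        estimator_id=estimator_id,
        seed=seed,
        n_null_defined=int(t_null.size),
    )


def marginal_null_pvalues(
    g: GenotypeMatrix,
    estimator_id: str = "lfa",
    K: int = 1,
    B_large: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Per-SNP (non-pooled) empirical-null p-values; pooling diagnostic.

    Each SNP is compared only against its own ``B_large`` null statistics,
    so the p-value resolution is 1/B_large and the cost is B_large model
    refits — intended for small data only.
    """
    if B_large < MARGINAL_MIN_B:
        raise ValueError(
            f"B_large must be >= {MARGINAL_MIN_B} for usable resolution, got {B_large}"
        )
    surf = fit_surface(g, estimator_id, K)
    t_obs, defined = shwe_statistics(g.values, surf.freqs)

    count = np.zeros(g.m)
    denom = np.zeros(g.m)
    for b, ss in enumerate(replicate_seeds(seed, B_large)):
        g0 = simulate_null_matrix(surf, np.random.default_rng(ss))
        surf0 = fit_surface(g0, estimator_id, K)
        t_null_b, defined_b = shwe_statistics(g0.values, surf0.freqs)
        use = defined_b & defined
        count[use] += t_null_b[use] >= t_obs[use]
        denom[use] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        p = count / denom
    return np.where(defined & (denom > 0), p, np.nan)
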