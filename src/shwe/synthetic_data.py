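"""Synthetic admixed genotype data with known ground truth.

The generator implements the admixture parameterization of population
structure: K ancestral populations with per-SNP allele frequencies drawn
from the Balding–Nichols model around a shared base frequency, individual
admixture proportions q_j ~ Dirichlet(alpha), individual-specific
frequencies pi_ij = sum_k p_ik q_kj, and genotypes x_ij ~ Binomial(2,
pi_ij). Every draw is recorded so downstream accuracy and power claims can
be checked against the truth.

Two HWE-violation mechanisms can be injected into a labeled subset of SNPs:

* ``inbreeding`` with coefficient f — genotype class probabilities become
  ((1-pi)^2 + f pi (1-pi), 2 pi (1-pi)(1-f), pi^2 + f pi (1-pi)); f > 0 is
  a heterozygote deficit, f < 0 an excess.
* ``genotype_error`` with rate eps — each call is independently replaced by
  a uniform random genotype with probability eps.

Defaults (alpha=0.1, fst=0.15, base MAF ~ Uniform(0.1, 0.5)) emulate a
strongly differentiated admixed human cohort of the kind the test is
designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

DEFAULT_ALPHA = 0.1
DEFAULT_FST = 0.15
DEFAULT_MAF_RANGE = (0.1, 0.5)
_FREQ_EPS = 1e-6  # keep ancestral frequencies strictly inside (0, 1)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    true_freqs: np.ndarray       # m x n pi_ij
    admixture: np.ndarray        # K x n, columns sum to 1
    ancestral_freqs: np.ndarray  # m x K
    violated: np.ndarray         # length-m bool
    mechanism: np.ndarray        # length-m str: none | inbreeding | genotype_error
    param: np.ndarray            # length-m float (f or eps; 0 where none)
    seed: int


def simulate_admixture(
    m: int,
    n: int,
    K: int,
    alpha: float = DEFAULT_ALPHA,
    fst: float = DEFAULT_FST,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Simulate an admixed cohort with K ancestral populations.

    Ancestral allele frequencies follow Balding–Nichols: for base frequency
    p and differentiation fst, p_k ~ Beta(p (1-fst)/fst, (1-p)(1-fst)/fst),
    independently per population. Positions are laid out 1 kbp apart on a
    single chromosome so distance-based operations are exercisable.
    """
    if m < 1 or n < 1 or K < 1:
        raise ValueError("m, n, K must all be >= 1")
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must be within (0, 0.5], got {maf_range}")
    if K > 1 and fst < 0.01:
        warnings.warn(
            f"fst={fst} with K={K}: populations nearly undifferentiated, "
            "structure is close to unidentifiable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    base = rng.uniform(lo, hi, size=m)
    ratio = (1.0 - fst) / fst
    anc = rng.beta(base[:, None] * ratio, (1.0 - base[:, None]) * ratio, size=(m, K))
    anc = np.clip(anc, _FREQ_EPS, 1.0 - _FREQ_EPS)

    q = rng.dirichlet(np.full(K, alpha), size=n).T  # K x n
    freqs = anc @ q
    values = rng.binomial(2, freqs).astype(np.int8)

    g = GenotypeMatrix(
        values,
        snp_ids=np.array([f"snp{i:06d}" for i in range(m)], dtype=object),
        sample_ids=np.array([f"ind{j:05d}" for j in range(n)], dtype=object),
        chrom=np.array(["1"] * m, dtype=object),
        pos=(np.arange(m, dtype=np.int64) + 1) * 1000,
    )
    truth = SimulationTruth(
        true_freqs=freqs,
        admixture=q,
        ancestral_freqs=anc,
        violated=np.zeros(m, dtype=bool),
        mechanism=np.array(["none"] * m, dtype=object),
        param=np.zeros(m),
        seed=seed,
    )
    return g, truth


def _inbreeding_probs(pi: np.ndarray, f: float) -> np.ndarray:
    """Genotype class probabilities under inbreeding coefficient f; shape (..., 3)."""
    het = pi * (1.0 - pi)
    probs = np.stack(
        [(1.0 - pi) ** 2 + f * het, 2.0 * het * (1.0 - f), pi**2 + f * het],
        axis=-1,
    )
    if np.any(probs < -1e-12):
        raise ValueError(
            f"inbreeding coefficient f={f} produces a negative genotype probability"
        )
    return np.clip(probs, 0.0, 1.0)


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized draws from per-cell 3-class distributions; probs shape (..., 3)."""
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[:-1])
    return (u[..., None] > cum).sum(axis=-1).astype(np.int8)


def inject_violations(
    g: GenotypeMatrix,
    truth: SimulationTruth,
    fraction: float,
    mechanism: str = "inbreeding",
    f: float = 0.3,
    eps: float = 0.05,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Flag a random ``fraction`` of SNPs and regenerate them out of HWE.

    Inbreeding redraws the flagged rows from the f-perturbed class
    probabilities at the true pi_ij; genotype_error corrupts the existing
    calls in place. Labels and the mechanism parameter are recorded in the
    returned truth.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if mechanism not in ("inbreeding", "genotype_error"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if mechanism == "inbreeding" and not -1.0 < f < 1.0:
        raise ValueError(f"inbreeding f must be in (-1, 1), got {f}")
    if mechanism == "genotype_error" and not 0.0 <= eps <= 0.5:
        raise ValueError(f"error rate eps must be in [0, 0.5], got {eps}")
    rng = np.random.default_rng(seed)
    flagged = rng.random(g.m) < fraction
    values = g.values.copy()

    if flagged.any():
        pi = truth.true_freqs[flagged]
        if mechanism == "inbreeding":
            values[flagged] = _draw_categorical(rng, _inbreeding_probs(pi, f))
        else:
            rows = values[flagged]
            corrupt = rng.random(rows.shape) < eps
            rows = np.where(corrupt, rng.integers(0, 3, size=rows.shape, dtype=np.int8), rows)
            values[flagged] = rows

    g_out = GenotypeMatrix(
        values, g.snp_ids.copy(), g.sample_ids.copy(),
        chrom=None if g.chrom is None else g.chrom.copy(),
        pos=None if g.pos is None else g.pos.copy(),
    )
    mech = truth.mechanism.copy()
    mech[flagged] = mechanism
    param = truth.param.copy()
    param[flagged] = f if mechanism == "inbreeding" else eps
    truth_out = SimulationTruth(
        true_freqs=truth.true_freqs,
        admixture=truth.admixture,
        ancestral_freqs=truth.ancestral_freqs,
        violated=truth.violated | flagged,
        mechanism=mech,
        param=param,
        seed=seed,
    )
    return g_out, truth_out


def write_truth(truth: SimulationTruth, snp_ids: np.ndarray, path: str | Path) -> None:
    """Write the per-SNP violation labels as TSV (snp_id, violated, mechanism, parameter)."""
    pd.DataFrame(
        {
            "snp_id": snp_ids,
            "violated": truth.violated.astype(int),
            "mechanism": truth.mechanism,
            "parameter": truth.param,
        }
    ).to_csv(Path(path), sep="\t", index=False, float_format="%.10g")
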