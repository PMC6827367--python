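import numpy as np
import pytest

from shwe import GenotypeMatrix, simulate_admixture


@pytest.fixture
def small_matrix() -> GenotypeMatrix:
    """3 SNPs x 4 samples, one missing call, with positions."""
    values = np.array(
        [
            [0, 1, 2, 1],
            [0, 0, 1, -1],
            [2, 2, 1, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        values,
        snp_ids=np.array(["rs1", "rs2", "rs3"], dtype=object),
        sample_ids=np.array(["a", "b", "c", "d"], dtype=object),
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos=np.array([100, 600, 150], dtype=np.int64),
    )


@pytest.fixture(scope="session")
def admixed_k2():
    """Two-population admixture simulation with known truth (session-wide)."""
    return simulate_admixture(m=500, n=150, K=2, seed=11)
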