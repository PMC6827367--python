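"""Genotype matrix I/O, validation, and per-SNP filtering.

Genotypes are diallelic dosages coded 0/1/2 (copies of the counted allele;
for VCF input this is the ALT allele) with ``MISSING = -1`` as the single
reserved sentinel. Three plain-text formats are supported:

* ``matrix-tsv`` — SNPs as rows; first column ``snp_id``, optional ``chrom``
  and ``pos`` columns, then one column per sample. Missing calls written as
  ``NA``. This is the package's native round-trip dialect.
* ``vcf`` — standard VCF restricted to biallelic SNPs; multi-allelic records
  are skipped with a logged count. Half-missing diploid calls are missing.
* ``plink-text`` — PLINK ``--recode A-transpose`` (.traw) style: header
  ``CHR SNP (C)M POS COUNTED ALT`` followed by per-sample dosages.

Filters (minor-allele frequency, completeness, distance thinning) operate on
rows and preserve row order; each logs the number of SNPs removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved sentinel for a missing genotype call.
MISSING = -1

_NA_TOKENS = {"NA", "na", "NaN", "nan", ".", ""}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under the named format."""


class GenotypeValidationError(ValueError):
    """Raised when genotype data violate a GenotypeMatrix invariant."""


@dataclass
class GenotypeMatrix:
    """An m SNPs x n individuals dosage matrix with identifiers.

    Parameters
    ----------
    values
        Integer matrix with entries in {0, 1, 2} or :data:`MISSING`.
    snp_ids, sample_ids
        Unique row / column identifiers.
    chrom, pos
        Optional per-SNP chromosome labels and base-pair positions (both
        present or both absent). Positions are expected sorted within each
        chromosome for distance thinning.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            vals = np.asarray(self.values, dtype=float)
            if np.any(vals != np.floor(vals)):
                raise GenotypeValidationError("genotype dosages must be integers")
            self.values = vals.astype(np.int8)
        else:
            self.values = self.values.astype(np.int8, copy=False)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise GenotypeValidationError("genotype values must be a 2-D matrix")
        m, n = self.values.shape
        if n < 2:
            raise GenotypeValidationError(f"need at least 2 samples, got {n}")
        # m == 0 is tolerated so filters may empty a matrix; readers reject it
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"entry ({i}, {j}) = {self.values[i, j]} is not in {{0, 1, 2}} "
                f"or the missing sentinel {MISSING}"
            )
        if len(self.snp_ids) != m:
            raise GenotypeValidationError("snp_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise GenotypeValidationError("sample_ids length does not match column count")
        if len(set(self.snp_ids)) != m:
            raise GenotypeValidationError("snp_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError("sample_ids are not unique")
        if (self.chrom is None) != (self.pos is None):
            raise GenotypeValidationError("chrom and pos must be given together")
        if self.pos is not None and (len(self.pos) != m or len(self.chrom) != m):
            raise GenotypeValidationError("positions length does not match row count")

    # -- derived quantities ---------------------------------------------

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean m x n mask, True where the call is missing."""
        return self.values == MISSING

    @property
    def has_positions(self) -> bool:
        return self.pos is not None

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP counted-allele frequency over non-missing calls.

        Returns NaN for a SNP with no non-missing calls.
        """
        obs = ~self.missing_mask
        counts = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(
                counts > 0,
                np.where(obs, self.values, 0).sum(axis=1) / (2.0 * np.maximum(counts, 1)),
                np.nan,
            )

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row-subset preserving order; used by all filters."""
        return replace(
            self,
            values=self.values[index],
            snp_ids=self.snp_ids[index],
            chrom=None if self.chrom is None else self.chrom[index],
            pos=None if self.pos is None else self.pos[index],
        )


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "matrix-tsv") -> GenotypeMatrix:
    """Read and validate a genotype matrix from ``path``.

    ``format`` is one of ``matrix-tsv``, ``vcf``, ``plink-text``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {path}")
    if format == "matrix-tsv":
        g = _read_matrix_tsv(path)
    elif format == "vcf":
        g = _read_vcf(path)
    elif format == "plink-text":
        g = _read_plink_text(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if g.m < 1:
        raise FormatError(f"{path}: no SNP rows found")
    return g


def _dosage_frame_to_values(df: pd.DataFrame, path: Path, header_rows: int) -> np.ndarray:
    """Convert a frame of dosage strings to int8, naming the offending line."""
    raw = df.to_numpy(dtype=object)
    out = np.empty(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(raw[i, j]).strip()
            if tok in _NA_TOKENS:
                out[i, j] = MISSING
                continue
            try:
                val = int(tok)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {i + 1 + header_rows}: cannot parse genotype {tok!r}"
                ) from exc
            out[i, j] = val
    return out


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: not parseable as TSV: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: line 1: expected snp_id column plus >= 2 samples")
    cols = list(df.columns)
    snp_ids = df.iloc[:, 0].to_numpy(dtype=object)
    chrom = pos = None
    first_sample = 1
    if len(cols) >= 3 and cols[1].lower() == "chrom" and cols[2].lower() == "pos":
        chrom = df.iloc[:, 1].to_numpy(dtype=object)
        try:
            pos = df.iloc[:, 2].astype(np.int64).to_numpy()
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer value in pos column") from exc
        first_sample = 3
    sample_ids = np.asarray(cols[first_sample:], dtype=object)
    values = _dosage_frame_to_values(df.iloc[:, first_sample:], path, header_rows=1)
    return GenotypeMatrix(values, snp_ids, sample_ids, chrom=chrom, pos=pos)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    # gts012=True codes gt_types as the ALT dosage 0/1/2, with 3 = unknown.
    vcf = VCF(str(path), gts012=True)
    sample_ids = np.asarray(vcf.samples, dtype=object)
    rows, snp_ids, chrom, pos = [], [], [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        dosage = variant.gt_types.astype(np.int8)
        dosage[dosage == 3] = MISSING
        rows.append(dosage)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    if not rows:
        raise FormatError(f"{path}: no biallelic SNP records found")
    return GenotypeMatrix(
        np.vstack(rows),
        np.asarray(snp_ids, dtype=object),
        sample_ids,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
    )


_TRAW_META_COLS = 6  # CHR SNP (C)M POS COUNTED ALT


def _read_plink_text(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{path}: not parseable as PLINK transposed text: {exc}") from exc
    if df.shape[1] <= _TRAW_META_COLS:
        raise FormatError(
            f"{path}: line 1: expected {_TRAW_META_COLS} metadata columns plus samples"
        )
    try:
        pos = df.iloc[:, 3].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer POS column") from exc
    values = _dosage_frame_to_values(df.iloc[:, _TRAW_META_COLS:], path, header_rows=1)
    return GenotypeMatrix(
        values,
        df.iloc[:, 1].to_numpy(dtype=object),
        np.asarray(df.columns[_TRAW_META_COLS:], dtype=object),
        chrom=df.iloc[:, 0].to_numpy(dtype=object),
        pos=pos,
    )


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write ``g`` in the matrix-tsv dialect (round-trips bit-exactly)."""
    path = Path(path)
    data = {"snp_id": g.snp_ids}
    if g.has_positions:
        data["chrom"] = g.chrom
        data["pos"] = g.pos
    body = g.values.astype(object)
    body[g.values == MISSING] = "NA"
    for j, sid in enumerate(g.sample_ids):
        data[str(sid)] = body[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_results(
    path: str | Path,
    snp_ids: np.ndarray,
    statistics: np.ndarray,
    p_values: np.ndarray,
    q_values: np.ndarray | None = None,
    flags: np.ndarray | None = None,
) -> None:
    """Write the per-SNP result table (snp_id, statistic, p_value, q_value, flag)."""
    m = len(snp_ids)
    if flags is None:
        flags = np.where(np.isfinite(np.asarray(p_values, dtype=float)), "ok", "undefined")
    q = np.full(m, np.nan) if q_values is None else q_values
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "statistic": statistics,
            "p_value": p_values,
            "q_value": q,
            "flag": flags,
        }
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.10g", na_rep="NA")


# ----------------------------------------------------------------------
# Filters
# ----------------------------------------------------------------------

def filter_maf(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep SNPs whose minor-allele frequency is >= ``min_maf``.

    Frequencies are computed over non-missing calls; a SNP exactly at the
    threshold is kept. SNPs with no non-missing calls are dropped with a
    warning.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    p = g.allele_freqs()
    all_missing = np.isnan(p)
    if all_missing.any():
        logger.warning("excluding %d SNPs with all calls missing", int(all_missing.sum()))
    maf = np.minimum(p, 1.0 - p)
    keep = ~all_missing & (maf >= min_maf)
    logger.info("MAF filter (>= %g): removed %d of %d SNPs", min_maf, g.m - keep.sum(), g.m)
    return g.take_snps(np.flatnonzero(keep))


def filter_completeness(g: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Keep SNPs whose fraction of non-missing calls is >= ``min_rate``."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    rate = (~g.missing_mask).sum(axis=1) / g.n
    keep = rate >= min_rate
    logger.info(
        "completeness filter (>= %g): removed %d of %d SNPs", min_rate, g.m - keep.sum(), g.m
    )
    return g.take_snps(np.flatnonzero(keep))


def thin_by_distance(g: GenotypeMatrix, min_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right thinning: keep a SNP only if it lies >= ``min_bp``
    base pairs after the last kept SNP on the same chromosome.

    The scan restarts on each chromosome, so the first SNP of every
    chromosome is always kept. Requires positions sorted within chromosome.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be a positive integer, got {min_bp}")
    if not g.has_positions:
        raise ValueError("thin_by_distance requires SNP positions")
    keep = []
    last_chrom, last_pos = None, None
    for i in range(g.m):
        c, p = g.chrom[i], g.pos[i]
        if c == last_chrom:
            if p < last_pos:
                raise ValueError(
                    f"positions not sorted within chromosome {c!r} at row {i}"
                )
            if p - last_pos < min_bp:
                continue
        keep.append(i)
        last_chrom, last_pos = c, p
    logger.info("distance thinning (>= %d bp): kept %d of %d SNPs", min_bp, len(keep), g.m)
    return g.take_snps(np.asarray(keep, dtype=int))
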