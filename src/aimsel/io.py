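"""PLINK text PED/MAP input/output and additive minor-allele-count recoding.

The pipeline's central object is a samples x SNPs matrix of minor-allele
counts (0/1/2, missing = :data:`MISSING`), equivalent to the output of
PLINK's ``--recodeA``.  The minor allele of each variant is the allele with
the lower total count over all non-missing calls in the whole dataset;
frequency ties at exactly 0.5 are broken in favour of the alphabetically
first allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in the additive matrix.
MISSING: int = -1


class PedMapParseError(ValueError):
    """Raised when a PED/MAP file pair is structurally malformed."""


@dataclass
class VariantRecord:
    """One MAP line: a biallelic SNP and its genomic coordinates."""

    chrom: str
    rsid: str
    genetic_distance: float = 0.0
    bp_position: int = 0
    alleles: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        if self.bp_position < 0:
            raise ValueError(f"bp_position must be >= 0, got {self.bp_position}")


@dataclass
class SampleRecord:
    """One PED prefix: family/individual ids plus opaque sex/phenotype codes."""

    family_id: str
    individual_id: str
    sex: int = 0
    phenotype: int = -9


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive (minor-allele-count) genotype matrix.

    ``values[i, j]`` is the number of copies of ``minor_allele[j]`` carried
    by sample ``i`` at variant ``j`` (0, 1 or 2), or :data:`MISSING`.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    values: np.ndarray  # int8, shape (n_samples, n_snps)
    minor_allele: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            raise ValueError("genotype values must be in {0, 1, 2, MISSING}")
        if not self.minor_allele:
            self.minor_allele = [v.alleles[0] for v in self.variants]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.individual_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        """Additive matrix as a DataFrame (missing -> NaN)."""
        vals = self.values.astype(float)
        vals[self.values == MISSING] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.rsids)


# ---------------------------------------------------------------------------
# PED/MAP parsing


def read_map(map_path: str | Path) -> list[VariantRecord]:
    """Read a PLINK MAP file (chrom, rsid, genetic distance, bp position)."""
    variants: list[VariantRecord] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise PedMapParseError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            variants.append(
                VariantRecord(
                    chrom=fields[0],
                    rsid=fields[1],
                    genetic_distance=float(fields[2]),
                    bp_position=int(fields[3]),
                )
            )
    return variants


def read_ped_map(
    ped_path: str | Path, map_path: str | Path
) -> tuple[list[SampleRecord], list[VariantRecord], np.ndarray]:
    """Parse a PED/MAP pair into sample records, variant records and allele pairs.

    Returns ``(samples, variants, pairs)`` where ``pairs`` has shape
    ``(n_samples, n_variants, 2)`` of allele letters; the PLINK convention
    ``"0 0"`` denotes a missing call.  A half-missing pair (one allele
    ``"0"``) is a malformed call and raises :class:`PedMapParseError`.
    """
    variants = read_map(map_path)
    n_var = len(variants)
    samples: list[SampleRecord] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_var:
                raise PedMapParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_var} fields "
                    f"(6 + 2 x {n_var} MAP variants), got {len(fields)}"
                )
            samples.append(
                SampleRecord(
                    family_id=fields[0],
                    individual_id=fields[1],
                    sex=int(fields[4]),
                    phenotype=int(fields[5]),
                )
            )
            geno = fields[6:]
            for j in range(n_var):
                a, b = geno[2 * j], geno[2 * j + 1]
                if (a == "0") != (b == "0"):
                    raise PedMapParseError(
                        f"{ped_path}:{lineno}: half-missing call '{a} {b}' "
                        f"at variant {variants[j].rsid}"
                    )
            rows.append(geno)
    pairs = np.asarray(rows, dtype=object).reshape(len(samples), n_var, 2)
    return samples, variants, pairs


def recode_additive(
    samples: Sequence[SampleRecord],
    variants: Sequence[VariantRecord],
    pairs: np.ndarray,
) -> GenotypeMatrix:
    """Recode allele-pair records into the additive minor-allele-count matrix.

    The minor allele is determined per variant from the full dataset (the
    allele with the lower total count over non-missing calls; tie at 0.5 ->
    alphabetically first).  Monomorphic variants are coded all-0 with a
    warning; all-missing columns stay entirely missing.
    """
    n, m = len(samples), len(variants)
    values = np.full((n, m), MISSING, dtype=np.int8)
    minor_alleles: list[str] = []
    variants = [
        VariantRecord(v.chrom, v.rsid, v.genetic_distance, v.bp_position, v.alleles)
        for v in variants
    ]
    for j, var in enumerate(variants):
        col = pairs[:, j, :]
        flat = col.ravel()
        observed = flat[flat != "0"]
        letters, counts = np.unique(observed, return_counts=True)
        if letters.size == 0:
            warnings.warn(
                f"variant {var.rsid}: all calls missing; column left missing",
                stacklevel=2,
            )
            minor_alleles.append(var.alleles[0])
            continue
        if letters.size == 1:
            warnings.warn(
                f"variant {var.rsid}: monomorphic ({letters[0]}); coded all-0",
                stacklevel=2,
            )
            major = str(letters[0])
            var.alleles = (major, major)
            minor_alleles.append(major)
            nonmiss = col[:, 0] != "0"
            values[nonmiss, j] = 0
            continue
        if letters.size > 2:
            raise PedMapParseError(
                f"variant {var.rsid}: more than two alleles observed "
                f"({', '.join(map(str, letters))})"
            )
        # Lower total count wins; exact tie -> alphabetically first letter.
        if counts[0] < counts[1]:
            minor = str(letters[0])
        elif counts[1] < counts[0]:
            minor = str(letters[1])
        else:
            minor = str(min(letters))
        var.alleles = (str(letters[0]), str(letters[1]))
        minor_alleles.append(minor)
        nonmiss = col[:, 0] != "0"
        values[nonmiss, j] = (col[nonmiss] == minor).sum(axis=1)
    return GenotypeMatrix(list(samples), variants, values, minor_alleles)


def write_ped_map(matrix: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write a GenotypeMatrix back to ``<prefix>.ped`` / ``<prefix>.map``.

    Genotype 2 -> minor/minor, 1 -> minor/major, 0 -> major/major,
    missing -> ``0 0``.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.rsid}\t{v.genetic_distance:g}\t{v.bp_position}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(matrix.samples):
            fields = [s.family_id, s.individual_id, "0", "0", str(s.sex), str(s.phenotype)]
            for j, v in enumerate(matrix.variants):
                minor = matrix.minor_allele[j]
                a, b = v.alleles
                major = b if a == minor else a
                g = matrix.values[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 2:
                    fields += [minor, minor]
                elif g == 1:
                    fields += [minor, major]
                else:
                    fields += [major, major]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Additive-matrix and label TSVs


def write_matrix_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the additive matrix as TSV (header = rsids, first column = sample id,
    empty cell = missing)."""
    df = matrix.to_frame()
    df.index.name = "sample_id"
    # Integer rendering with empty cells for missing calls.
    df.to_csv(path, sep="\t", float_format="%.0f", na_rep="")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an additive-matrix TSV back into ``(values, sample_ids, rsids)``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    out = np.full(values.shape, MISSING, dtype=np.int8)
    mask = ~np.isnan(values)
    out[mask] = values[mask].astype(np.int8)
    return out, [str(i) for i in df.index], [str(c) for c in df.columns]


def write_labels_tsv(sample_ids: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "population": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a sample -> population table; returns a Series indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("sample_id")["population"]
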