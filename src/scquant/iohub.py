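"""Readers/writers for the external formats the pipeline touches, and the
annotation-bearing core containers.

The central object is :class:`ExpressionMatrix`: a genes x samples table of
nonnegative expression values on a declared unit scale (FPKM, tpm, RMA_log2
or arbitrary). Zeros — not missing values — encode non-detection on the
FPKM/tpm scales, because every detection rule downstream is a threshold on
the expression value itself. All readers validate and reject malformed input
rather than silently coercing it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_UNITS = ("FPKM", "tpm", "RMA_log2", "arbitrary")
NONNEGATIVE_UNITS = ("FPKM", "tpm")

CELL_CYCLE_PHASES = ("G1", "S", "G2M", "NA")
SAMPLE_CLASSES = ("single_cell", "pooled_equivalent", "bulk_reference")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    unit : str
        One of ``FPKM``, ``tpm``, ``RMA_log2``, ``arbitrary``. FPKM/tpm
        values must be nonnegative and dense (no NaN).
    gene_meta : pandas.DataFrame, optional
        Per-gene metadata indexed like ``values`` (columns such as
        ``transcript_length`` in bp and ``gc_fraction`` in [0, 1]).
    """

    values: pd.DataFrame
    unit: str = "FPKM"
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicated gene id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value for gene {idx[i]!r}, sample {cols[j]!r} "
                "(encode non-detection as 0)"
            )
        if self.unit in NONNEGATIVE_UNITS and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative value under unit {self.unit} at gene {idx[i]!r}, sample {cols[j]!r}"
            )
        if self.gene_meta is not None and not self.gene_meta.index.equals(idx):
            self.gene_meta = self.gene_meta.reindex(idx)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit, self.gene_meta)

    def linear_values(self) -> pd.DataFrame:
        """Values on the linear scale (RMA_log2 exponentiated)."""
        if self.unit == "RMA_log2":
            return 2.0 ** self.values
        return self.values


@dataclass
class SampleAnnotation:
    """Per-sample annotation: cell type, cell-cycle phase, class, batch.

    ``table`` must have exactly the columns ``sample_id``, ``cell_type``,
    ``cycle_phase``, ``sample_class``, ``batch``; each sample id appears once.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cell_type", "cycle_phase", "sample_class", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        sid = self.table["sample_id"]
        if sid.duplicated().any():
            dup = sid[sid.duplicated()].iloc[0]
            raise FormatError(f"duplicated sample_id {dup!r} in annotation")
        bad_phase = set(self.table["cycle_phase"]) - set(CELL_CYCLE_PHASES)
        if bad_phase:
            raise FormatError(f"unknown cycle_phase values: {sorted(bad_phase)}")
        bad_class = set(self.table["sample_class"]) - set(SAMPLE_CLASSES)
        if bad_class:
            raise FormatError(f"unknown sample_class values: {sorted(bad_class)}")

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids matching all equality conditions, in table order."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in conditions.items():
            if col not in self.table.columns:
                raise KeyError(f"no annotation column {col!r}")
            mask &= self.table[col] == value
        return list(self.table.loc[mask, "sample_id"])

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        known = set(self.table["sample_id"])
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise FormatError(f"samples without annotation: {unknown[:5]}")


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read: id, bases (A/C/G/T/N), Phred+33 quality string."""

    read_id: str
    bases: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise FormatError(
                f"read {self.read_id!r}: base length {len(self.bases)} != "
                f"quality length {len(self.qualities)}"
            )


# ---------------------------------------------------------------------------
# TSV expression matrices


def read_matrix(path, unit: str = "FPKM") -> ExpressionMatrix:
    """Read a genes-in-rows TSV (header = sample ids, first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    ncol = df.shape[1]
    with _maybe_gzip(path) as fh:
        header_fields = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            nfields = line.rstrip("\n").count("\t") + 1
            if nfields != len(header_fields):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header_fields)} fields, got {nfields}"
                )
    if df.shape[1] != ncol:  # pragma: no cover - defensive
        raise FormatError(f"{path}: inconsistent column count")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    values.index = values.index.astype(str)
    values.index.name = None
    try:
        return ExpressionMatrix(values, unit=unit)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ


def _maybe_gzip(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records (plain or gzip) as :class:`ReadRecord`.

    Constant memory in the number of reads; a truncated or malformed record
    raises :class:`FormatError` naming the record index.
    """
    with _maybe_gzip(path) as handle:
        index = 0
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                quals = rec.letter_annotations["phred_quality"]
                yield ReadRecord(
                    read_id=rec.id,
                    bases=str(rec.seq),
                    qualities="".join(chr(q + 33) for q in quals),
                )
                index += 1
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FASTQ at record {index}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{read.qualities}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set name: set of member genes}``.

    Members duplicated within a line are deduplicated; a duplicated set name
    across lines is an error.
    """
    sets: dict[str, set[str]] = {}
    with _maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and >=1 member"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")
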