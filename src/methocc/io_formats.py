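"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are fixed here once and for all: every in-memory
coordinate is 0-based, half-open.  BED and bedGraph are native to that
convention; cytosine reports arrive 1-based and are shifted by exactly one
on ingest (``read_cytosine_report`` keeps the 1-based position so callers
can round-trip the file; :func:`methocc.meth_context.attach_calls` does the
shift).

Genomes are held as plain upper-case strings over ``{A, C, G, T, N}`` —
desk-scale chromosomes (a few Mb) make anything fancier unnecessary.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methocc")

VALID_BASES = frozenset("ACGTN")
DI_CONTEXTS = ("CG", "CA", "CC", "CT")


class FormatError(ValueError):
    """A malformed record in an external file, with its line number."""


# ---------------------------------------------------------------------------
# genome sequences
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """An ordered set of named chromosome sequences.

    Attributes
    ----------
    chrom_names:
        Chromosome identifiers in file order.
    sequences:
        Mapping chromosome -> upper-case sequence over ``{A,C,G,T,N}``.
    """

    chrom_names: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names")
        for name in self.chrom_names:
            seq = self.sequences[name]
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"illegal characters {sorted(bad)} in sequence {name!r}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self.sequences[name]) for name in self.chrom_names}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


def read_fasta(path: str | Path | io.TextIOBase) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Sequences are upper-cased; record order is preserved.  Malformed headers,
    characters outside ``{A,C,G,T,N}``, and duplicate names raise
    :class:`FormatError` naming the offending line.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    names: list[str] = []
    chunks: dict[str, list[str]] = {}
    current: str | None = None
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                if name in chunks:
                    raise FormatError(f"line {lineno}: duplicate record name {name!r}")
                names.append(name)
                chunks[name] = []
                current = name
            else:
                if current is None:
                    raise FormatError(f"line {lineno}: sequence before first header")
                seq = line.upper()
                bad = set(seq) - VALID_BASES
                if bad:
                    raise FormatError(
                        f"line {lineno}: illegal character(s) {sorted(bad)}"
                    )
                chunks[current].append(seq)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not names:
        raise FormatError("no FASTA records found")
    return GenomeSequence(names, {n: "".join(chunks[n]) for n in names})


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genomic intervals (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def read_intervals(
    path: str | Path | io.TextIOBase, dialect: str = "BED6"
) -> list[GenomicInterval]:
    """Read BED3/BED6/BED12 into intervals (strand '.' when absent).

    BED12 exon structure is collapsed to the interval span; callers needing
    exonic lengths use :func:`read_bed12_exon_lengths`.
    """
    if dialect not in {"BED3", "BED6", "BED12"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = {"BED3": 3, "BED6": 4, "BED12": 12}[dialect]
    handle = open(path) if isinstance(path, (str, Path)) else path
    out: list[GenomicInterval] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"line {lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"line {lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            score = 0.0
            if len(fields) > 4 and fields[4] not in {".", ""}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise FormatError(f"line {lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(fields[0], start, end, strand, name, score))
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return out


def read_bed12_exon_lengths(path: str | Path) -> dict[str, int]:
    """Per-record sum of exon block lengths from a BED12 file (for TPM)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"line {lineno}: BED12 needs 12 columns")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            out[fields[3]] = int(sum(sizes))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{_fmt(iv.score)}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",  # 1-based, as in the file
    "strand",
    "count_modified",
    "count_unmodified",
    "di_context",
    "tri_context",
]


def read_cytosine_report(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a Bismark-style cytosine report (7 tab-separated columns).

    Columns: chrom, 1-based position, strand (+/-), modified count,
    unmodified count, di-nucleotide context, tri-nucleotide context (or NA).
    Positions stay 1-based here; conversion to internal 0-based coordinates
    is done where records are joined onto a genome.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        df = pd.read_csv(
            handle,
            sep="\t",
            names=CYTOSINE_REPORT_COLUMNS,
            header=None,
            dtype={
                "chrom": str,
                "pos": np.int64,
                "strand": str,
                "count_modified": np.int64,
                "count_unmodified": np.int64,
                "di_context": str,
                "tri_context": str,
            },
            comment="#",
            keep_default_na=False,  # "NA" tri-contexts are literal strings
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if len(df) == 0:
        warnings.warn("empty cytosine report", stacklevel=2)
        logger.warning("empty cytosine report")
        return pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    if (df["count_modified"] < 0).any() or (df["count_unmodified"] < 0).any():
        bad = df.index[
            (df["count_modified"] < 0) | (df["count_unmodified"] < 0)
        ][0]
        raise FormatError(f"line {bad + 1}: negative basecall count")
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.index[~df["strand"].isin(["+", "-"])][0]
        raise FormatError(f"line {bad + 1}: cytosine strand must be + or -")
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise FormatError(f"line {bad + 1}: 1-based position must be >= 1")
    return df


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(
        path, sep="\t", header=False, index=False, columns=CYTOSINE_REPORT_COLUMNS
    )


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Fixed 6-significant-digit rendering used for all track values."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    """Write a (chrom, start, end, value) frame as bedGraph.

    Intervals must be sorted and non-overlapping within each chromosome.
    Values are rendered with six significant digits, so a write/read
    round-trip reproduces them to within 1e-5 relative.
    """
    required = ["chrom", "start", "end", "value"]
    missing = [c for c in required if c not in track.columns]
    if missing:
        raise ValueError(f"track missing columns {missing}")
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not np.all(starts[1:] >= starts[:-1]):
            raise FormatError(f"bedGraph intervals unsorted on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise FormatError(f"bedGraph intervals overlap on {chrom}")
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{_fmt(row.value)}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "value"],
        header=None,
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        comment="#",
    )
    if (df["start"] >= df["end"]).any():
        raise FormatError("bedGraph record with start >= end")
    return df


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError("negative count in count matrix")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
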