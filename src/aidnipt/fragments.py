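"""Aligned cfDNA fragment input: SAM/BAM and the fragment-TSV dialect.

The analysis consumes already-aligned single-end reads.  At load time
the preprocessing contract is applied: records with mapping quality
below the threshold (default 60) are excluded, PCR/optical duplicates
are excluded, and secondary/supplementary alignments are skipped.

Fragments use 1-based leftmost coordinates (SAM convention); the bin
grid is 0-based half-open — conversion happens at binning time, never
here.

The TSV dialect is tab-separated with a mandatory header line::

    chrom  pos  strand  mapq  dup

``strand`` is ``+``/``-``; ``dup`` is ``0``/``1``; ``pos`` is 1-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import pysam

__all__ = ["FragmentRecord", "FragmentTable", "load_fragments", "write_fragments_tsv"]

DEFAULT_MIN_MAPQ = 60
DEFAULT_READ_LEN = 75

_TSV_COLUMNS = ["chrom", "pos", "strand", "mapq", "dup"]


class FragmentFormatError(ValueError):
    """Raised when a fragment file cannot be parsed or references unknown chromosomes."""


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned single-end cfDNA read."""

    chrom: str
    pos: int          # 1-based leftmost aligned coordinate
    strand: str       # '+' or '-'
    mapq: int
    is_dup: bool = False
    read_len: int = DEFAULT_READ_LEN


class FragmentTable:
    """Columnar container for aligned fragments (order-preserving).

    Thin wrapper over a DataFrame with columns ``chrom, pos, strand,
    mapq, dup``; iteration yields :class:`FragmentRecord`.
    """

    def __init__(self, frame: pd.DataFrame, read_len: int = DEFAULT_READ_LEN):
        missing = [c for c in _TSV_COLUMNS if c not in frame.columns]
        if missing:
            raise FragmentFormatError(f"fragment table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.read_len = read_len

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[FragmentRecord]:
        for row in self.frame.itertuples(index=False):
            yield FragmentRecord(chrom=row.chrom, pos=int(row.pos), strand=row.strand,
                                 mapq=int(row.mapq), is_dup=bool(row.dup),
                                 read_len=self.read_len)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentTable):
            return NotImplemented
        return self.read_len == other.read_len and self.frame.equals(other.frame)

    @classmethod
    def from_records(cls, records, read_len: int = DEFAULT_READ_LEN) -> "FragmentTable":
        rows = [(r.chrom, r.pos, r.strand, r.mapq, int(r.is_dup)) for r in records]
        frame = pd.DataFrame(rows, columns=_TSV_COLUMNS)
        if not rows:
            frame = frame.astype({"chrom": str, "pos": int, "strand": str,
                                  "mapq": int, "dup": int})
        return cls(frame, read_len=read_len)

    @classmethod
    def from_arrays(cls, chrom, pos, strand, mapq=None, dup=None,
                    read_len: int = DEFAULT_READ_LEN) -> "FragmentTable":
        n = len(pos)
        frame = pd.DataFrame({
            "chrom": chrom if isinstance(chrom, pd.Categorical) else np.asarray(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": np.asarray(strand),
            "mapq": np.full(n, DEFAULT_MIN_MAPQ, dtype=np.int64) if mapq is None
                    else np.asarray(mapq, dtype=np.int64),
            "dup": np.zeros(n, dtype=np.int64) if dup is None
                   else np.asarray(dup, dtype=np.int64),
        })
        return cls(frame, read_len=read_len)


def _filter_table(table: FragmentTable, min_mapq: int,
                  known_chroms: set[str] | None) -> FragmentTable:
    frame = table.frame
    if known_chroms is not None:
        unknown = ~frame["chrom"].isin(known_chroms)
        if unknown.any():
            bad = frame[unknown].iloc[0]
            raise FragmentFormatError(
                f"record on unknown chromosome {bad['chrom']!r} at position {bad['pos']}"
            )
    keep = (frame["mapq"] >= min_mapq) & (frame["dup"] == 0)
    return FragmentTable(frame[keep].reset_index(drop=True), read_len=table.read_len)


def _load_tsv(path, read_len: int) -> FragmentTable:
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FragmentFormatError(f"cannot parse fragment TSV {path}: {exc}") from exc
    if list(frame.columns[:5]) != _TSV_COLUMNS:
        raise FragmentFormatError(
            f"fragment TSV {path} must have header {_TSV_COLUMNS}, got {list(frame.columns)}"
        )
    if len(frame):
        frame = frame.astype({"pos": np.int64, "mapq": np.int64, "dup": np.int64})
    else:
        frame = frame.astype({"chrom": str, "pos": np.int64, "strand": str,
                              "mapq": np.int64, "dup": np.int64})
    return FragmentTable(frame, read_len=read_len)


def _load_alignment(path, read_len: int) -> FragmentTable:
    mode = "rb" if os.fspath(path).endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(os.fspath(path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            rows.append((
                aln.reference_name,
                aln.reference_start + 1,  # pysam is 0-based
                "-" if aln.is_reverse else "+",
                aln.mapping_quality,
                int(aln.is_duplicate),
            ))
    frame = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    if not rows:
        frame = frame.astype({"chrom": str, "pos": np.int64, "strand": str,
                              "mapq": np.int64, "dup": np.int64})
    return FragmentTable(frame, read_len=read_len)


def load_fragments(path: str | os.PathLike, min_mapq: int = DEFAULT_MIN_MAPQ,
                   known_chroms: set[str] | None = None,
                   read_len: int = DEFAULT_READ_LEN) -> FragmentTable:
    """Load aligned fragments from SAM/BAM or the fragment TSV dialect.

    Applies the preprocessing filters: keeps primary alignments with
    ``mapq >= min_mapq`` and duplicate flag unset, preserving input
    order.  If ``known_chroms`` is given, a record on any other
    chromosome raises :class:`FragmentFormatError` naming it.
    """
    p = os.fspath(path)
    if p.endswith((".sam", ".bam")):
        table = _load_alignment(p, read_len)
    else:
        table = _load_tsv(p, read_len)
    return _filter_table(table, min_mapq, known_chroms)


def write_fragments_tsv(table: FragmentTable, path: str | os.PathLike) -> None:
    """Write the TSV dialect; a reload reproduces identical records."""
    table.frame.to_csv(path, sep="\t", index=False)
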