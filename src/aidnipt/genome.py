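"""Genome definitions and the 1-Mb analysis bin grid.

A :class:`GenomeBuild` bundles chromosome sizes, excluded-region masks
(centromeres, telomeres, other problematic regions) and per-bin GC /
mappability tracks.  :func:`make_bins` turns it into the non-overlapping
1-Mb :class:`BinSet` on which all fragment-distance and count statistics
are computed, applying the three bin-level exclusion rules:

* overlap with a masked interval (by >= 1 bp),
* mappability <= 80 %,
* GC content <= 30 % or > 50 %.

A bin is *retained* iff none of the flags is set.  Chromosome tails
shorter than the bin width are dropped entirely (a partial bin would bias
distance statistics relative to full-width bins).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomeBuild",
    "BinSet",
    "make_bins",
    "DEFAULT_BIN_WIDTH",
    "MAPPABILITY_MAX_EXCLUDED",
    "GC_MIN_EXCLUDED",
    "GC_MAX_RETAINED",
]

DEFAULT_BIN_WIDTH = 1_000_000
#: bins with mappability <= this percentage are excluded (inclusive bound)
MAPPABILITY_MAX_EXCLUDED = 80.0
#: bins with GC <= this percentage are excluded (inclusive bound)
GC_MIN_EXCLUDED = 30.0
#: bins with GC > this percentage are excluded (bound itself retained)
GC_MAX_RETAINED = 50.0

TARGET_CHROMOSOMES = ("chr13", "chr18", "chr21")
SEX_CHROMOSOMES = ("chrX", "chrY")


class GenomeConfigError(ValueError):
    """Raised when a genome bundle is inconsistent or incomplete."""


@dataclass
class GenomeBuild:
    """Chromosome sizes, masks and per-bin GC/mappability tracks.

    Tracks are defined at 1-Mb bin resolution: entry ``i`` of
    ``gc_track[chrom]`` / ``map_track[chrom]`` describes the bin
    ``[i*1Mb, (i+1)*1Mb)``.  Units are percent in ``[0, 100]``.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    mask_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    gc_track: dict[str, np.ndarray] = field(default_factory=dict)
    map_track: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.chrom_names:
            if chrom not in self.chrom_lengths:
                raise GenomeConfigError(f"no length for chromosome {chrom!r}")
        for chrom, ivals in self.mask_intervals.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise GenomeConfigError(f"mask on unknown chromosome {chrom!r}")
            for start, end in ivals:
                if not (0 <= start < end <= length):
                    raise GenomeConfigError(
                        f"mask interval [{start}, {end}) outside {chrom} (length {length})"
                    )
        for name, track in (("gc", self.gc_track), ("mappability", self.map_track)):
            for chrom, values in track.items():
                arr = np.asarray(values, dtype=float)
                if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 100):
                    raise GenomeConfigError(f"{name} track for {chrom} outside [0, 100]")
                track[chrom] = arr

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_names if c not in SEX_CHROMOSOMES]

    def n_bins(self, chrom: str, width: int = DEFAULT_BIN_WIDTH) -> int:
        """Number of full-width bins on ``chrom`` (short tail dropped)."""
        return self.chrom_lengths[chrom] // width

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "GenomeBuild":
        """Load a genome bundle from a YAML file.

        The YAML maps ``chrom_lengths`` (name -> bp) and, inline or as
        relative file references, ``masks`` (BED path or
        ``{chrom: [[start, end], ...]}``), ``gc`` and ``mappability``
        (bedGraph path or ``{chrom: [per-bin values]}``).
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = os.path.dirname(os.fspath(path))
        lengths = {str(k): int(v) for k, v in doc["chrom_lengths"].items()}
        names = list(lengths)

        masks: dict[str, list[tuple[int, int]]] = {}
        mask_doc = doc.get("masks")
        if isinstance(mask_doc, str):
            masks = read_bed(os.path.join(base, mask_doc))
        elif isinstance(mask_doc, dict):
            masks = {c: [(int(s), int(e)) for s, e in ivals] for c, ivals in mask_doc.items()}

        def _track(key: str) -> dict[str, np.ndarray]:
            entry = doc.get(key)
            if entry is None:
                return {}
            if isinstance(entry, str):
                return read_bedgraph(os.path.join(base, entry))
            return {c: np.asarray(v, dtype=float) for c, v in entry.items()}

        return cls(
            chrom_names=names,
            chrom_lengths=lengths,
            mask_intervals=masks,
            gc_track=_track("gc"),
            map_track=_track("mappability"),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        doc = {
            "chrom_lengths": dict(self.chrom_lengths),
            "masks": {c: [[int(s), int(e)] for s, e in iv] for c, iv in self.mask_intervals.items()},
            "gc": {c: [float(x) for x in v] for c, v in self.gc_track.items()},
            "mappability": {c: [float(x) for x in v] for c, v in self.map_track.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    """Read a 3+-column BED file into per-chromosome interval lists."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
    return out


def read_bedgraph(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph at bin resolution into per-chrom arrays.

    Rows must cover consecutive full bins from position 0; the value of
    row ``i`` becomes track entry ``i``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        out[str(chrom)] = sub["value"].to_numpy(dtype=float)
    return out


def write_bedgraph(track: dict[str, np.ndarray], path: str | os.PathLike,
                   width: int = DEFAULT_BIN_WIDTH) -> None:
    rows = []
    for chrom, values in track.items():
        for i, v in enumerate(values):
            rows.append((chrom, i * width, (i + 1) * width, float(v)))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass
class BinSet:
    """The non-overlapping bin grid with per-bin exclusion flags.

    Backed by a DataFrame with columns ``chrom, start, end, gc,
    mappability, masked, low_mappability, gc_excluded, retained``; bins
    are 0-based half-open ``[start, end)`` and appear in genome order.
    """

    width: int
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, width: int | None = None) -> "BinSet":
        table = pd.read_csv(path, sep="\t")
        for col in ("masked", "low_mappability", "gc_excluded", "retained"):
            table[col] = table[col].astype(bool)
        if width is None:
            width = int((table["end"] - table["start"]).iloc[0])
        return cls(width=width, table=table.reset_index(drop=True))


def _overlaps_mask(start: int, end: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in intervals)


def make_bins(genome: GenomeBuild, width: int = DEFAULT_BIN_WIDTH) -> BinSet:
    """Tile every chromosome with ``width``-bp bins and apply exclusion flags.

    Raises :class:`GenomeConfigError` if a chromosome lacks GC or
    mappability values for any of its bins.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    records = []
    for chrom in genome.chrom_names:
        n = genome.chrom_lengths[chrom] // width
        if n == 0:
            continue
        gc = genome.gc_track.get(chrom)
        mp = genome.map_track.get(chrom)
        if gc is None or len(gc) < n:
            raise GenomeConfigError(f"missing GC track values for {chrom}")
        if mp is None or len(mp) < n:
            raise GenomeConfigError(f"missing mappability track values for {chrom}")
        masks = genome.mask_intervals.get(chrom, [])
        for i in range(n):
            start, end = i * width, (i + 1) * width
            masked = _overlaps_mask(start, end, masks)
            low_map = mp[i] <= MAPPABILITY_MAX_EXCLUDED
            gc_excl = gc[i] <= GC_MIN_EXCLUDED or gc[i] > GC_MAX_RETAINED
            records.append((chrom, start, end, float(gc[i]), float(mp[i]),
                            masked, low_map, gc_excl))
    table = pd.DataFrame(records, columns=[
        "chrom", "start", "end", "gc", "mappability",
        "masked", "low_mappability", "gc_excluded"])
    table["retained"] = ~(table["masked"] | table["low_mappability"] | table["gc_excluded"])
    return BinSet(width=width, table=table)
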