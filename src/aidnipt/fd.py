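"""Fragment-distance (FD) computation.

Instead of counting fragments per bin, the caller summarises the
*spacing* of fragments.  Three steps:

1. **Positional shifting** harmonises strand-dependent coordinates of
   single-end reads: forward reads get ``+80`` bp added to the leftmost
   aligned position; reverse reads get ``80`` bp subtracted from their
   rightmost aligned position.
2. **FD** is the difference between adjacent shifted positions on a
   chromosome (successive differences of the sorted positions).
3. Per 1-Mb bin, the FD sample is summarised by mean, median and IQR,
   alongside the conventional fragment count (FC).

Distances are assigned to the bin containing the *left* member of the
pair, so each distance lands in exactly one bin.  Quartiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinSet
from .fragments import FragmentTable

__all__ = ["ShiftedPositions", "BinFDTable", "shift_positions", "compute_fd",
           "bin_fd_stats", "DEFAULT_SHIFT", "DEFAULT_MIN_FD_N"]

DEFAULT_SHIFT = 80
#: bins whose FD sample is smaller than this are flagged unusable
DEFAULT_MIN_FD_N = 10


@dataclass
class ShiftedPositions:
    """Sorted shifted fragment positions per chromosome (1-based bp)."""

    positions: dict[str, np.ndarray]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.positions[chrom]

    def chromosomes(self) -> list[str]:
        return list(self.positions)


@dataclass
class BinFDTable:
    """Per-bin FC and FD summaries for one sample.

    ``table`` is aligned with the BinSet rows and adds ``fc, fd_n,
    fd_mean, fd_median, fd_iqr, usable``.  ``chrom_median_fd`` is the
    median of all distances assigned to retained bins of each
    chromosome (the chromosome-level summary used for control-chromosome
    selection).  ``raw`` optionally keeps each bin's distance sample for
    audit.
    """

    table: pd.DataFrame
    chrom_median_fd: dict[str, float]
    min_fd_n: int = DEFAULT_MIN_FD_N
    raw: dict[int, np.ndarray] | None = field(default=None, repr=False)

    @property
    def usable(self) -> pd.DataFrame:
        return self.table[self.table["retained"] & self.table["usable"]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, med in self.chrom_median_fd.items():
                fh.write(f"#chrom_median_fd\t{chrom}\t{med!r}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinFDTable":
        medians: dict[str, float] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#chrom_median_fd"):
                    break
                _, chrom, value = line.rstrip("\n").split("\t")
                medians[chrom] = float(value)
                skip += 1
        table = pd.read_csv(path, sep="\t", skiprows=skip)
        for col in ("retained", "usable"):
            table[col] = table[col].astype(bool)
        return cls(table=table, chrom_median_fd=medians)


def shift_positions(fragments: FragmentTable, shift: int = DEFAULT_SHIFT) -> ShiftedPositions:
    """Apply the strand-dependent positional shift and sort per chromosome.

    Forward reads: ``pos + shift``.  Reverse reads:
    ``(pos + read_len - 1) - shift`` (rightmost aligned base minus the
    shift).  Shifted positions may fall slightly outside chromosome
    ends; they are kept here and dropped by binning.
    """
    frame = fragments.frame
    pos = frame["pos"].to_numpy(np.int64)
    fwd = (frame["strand"] == "+").to_numpy()
    shifted = np.where(fwd, pos + shift, pos + fragments.read_len - 1 - shift)
    out: dict[str, np.ndarray] = {}
    # integer codes keep the per-chromosome split cheap at millions of reads
    codes, names = pd.factorize(frame["chrom"], sort=False)
    for k, chrom in enumerate(names):
        vals = shifted[codes == k]
        vals.sort()
        out[str(chrom)] = vals
    return ShiftedPositions(out)


def compute_fd(shifted: ShiftedPositions) -> dict[str, np.ndarray]:
    """Successive differences of the sorted shifted positions, per chromosome.

    A chromosome with fewer than two positions yields an empty array.
    All distances are >= 0 (zero when two reads shift to the same
    coordinate; deduplication happened upstream and is not repeated).
    """
    return {chrom: np.diff(pos) for chrom, pos in shifted.positions.items()}


def _grouped_quantile(sorted_values: np.ndarray, starts: np.ndarray,
                      counts: np.ndarray, q: float) -> np.ndarray:
    """Quantile ``q`` for each group of a group-sorted value array.

    ``sorted_values`` must be ordered within each group; groups are
    ``[starts[i], starts[i] + counts[i])``.  Linear interpolation
    between order statistics, matching ``numpy.quantile`` defaults.
    Groups with zero count yield NaN.
    """
    out = np.full(len(starts), np.nan)
    nz = counts > 0
    h = (counts[nz] - 1) * q
    lo = np.floor(h).astype(np.int64)
    hi = np.ceil(h).astype(np.int64)
    frac = h - lo
    base = starts[nz]
    out[nz] = (sorted_values[base + lo] * (1 - frac)
               + sorted_values[base + hi] * frac)
    return out


def bin_fd_stats(shifted: ShiftedPositions, distances: dict[str, np.ndarray],
                 bins: BinSet, min_fd_n: int = DEFAULT_MIN_FD_N,
                 keep_raw: bool = False) -> BinFDTable:
    """Summarise the FD sample of every bin: FC, mean, median, IQR.

    Each distance goes to the bin containing the left position of its
    pair; FC counts shifted positions per bin.  Bins with fewer than
    ``min_fd_n`` distances are flagged unusable (their statistics are
    NaN when empty).  Also computes the per-chromosome median FD over
    distances in retained bins.
    """
    bt = bins.table
    width = bins.width
    n_total = len(bt)
    fc = np.zeros(n_total, dtype=np.int64)
    fd_n = np.zeros(n_total, dtype=np.int64)
    fd_mean = np.full(n_total, np.nan)
    fd_median = np.full(n_total, np.nan)
    fd_iqr = np.full(n_total, np.nan)
    raw: dict[int, np.ndarray] = {}
    chrom_median: dict[str, float] = {}

    # row offset of each chromosome's first bin within the global table
    chrom_offsets: dict[str, int] = {}
    chrom_nbins: dict[str, int] = {}
    for chrom, sub in bt.groupby("chrom", sort=False):
        chrom_offsets[str(chrom)] = int(sub.index[0])
        chrom_nbins[str(chrom)] = len(sub)

    retained = bt["retained"].to_numpy()

    for chrom, pos in shifted.positions.items():
        if chrom not in chrom_offsets:
            continue
        off = chrom_offsets[chrom]
        nb = chrom_nbins[chrom]

        # FC: counts of shifted positions per bin (1-based pos -> 0-based bin)
        pbin = (pos - 1) // width
        ok = (pbin >= 0) & (pbin < nb)
        fc[off:off + nb] = np.bincount(pbin[ok], minlength=nb)

        d = distances.get(chrom)
        if d is None or len(d) == 0:
            chrom_median[chrom] = float("nan")
            continue
        left = pos[:-1]
        dbin = (left - 1) // width
        ok = (dbin >= 0) & (dbin < nb)
        d, dbin = d[ok], dbin[ok]
        if len(d) == 0:
            chrom_median[chrom] = float("nan")
            continue
        # positions are sorted, so dbin is non-decreasing; sort distances
        # within each bin for order-statistic quantiles
        order = np.lexsort((d, dbin))
        d_sorted = d[order].astype(float)
        dbin_sorted = dbin[order]
        counts = np.bincount(dbin_sorted, minlength=nb)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))

        nz = counts > 0
        sl = slice(off, off + nb)
        fd_n[sl] = counts
        means = np.full(nb, np.nan)
        means[nz] = np.add.reduceat(d_sorted, starts[nz]) / counts[nz]
        fd_mean[sl] = means
        fd_median[sl] = _grouped_quantile(d_sorted, starts, counts, 0.5)
        q3 = _grouped_quantile(d_sorted, starts, counts, 0.75)
        q1 = _grouped_quantile(d_sorted, starts, counts, 0.25)
        fd_iqr[sl] = q3 - q1

        keep = retained[off:off + nb][dbin_sorted]
        chrom_median[chrom] = float(np.median(d_sorted[keep])) if keep.any() else float("nan")

        if keep_raw:
            for b in np.nonzero(nz)[0]:
                raw[off + b] = d_sorted[starts[b]:starts[b] + counts[b]]

    table = bt.copy()
    table["fc"] = fc
    table["fd_n"] = fd_n
    table["fd_mean"] = fd_mean
    table["fd_median"] = fd_median
    table["fd_iqr"] = fd_iqr
    table["usable"] = fd_n >= min_fd_n
    return BinFDTable(table=table, chrom_median_fd=chrom_median,
                      min_fd_n=min_fd_n, raw=raw if keep_raw else None)
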