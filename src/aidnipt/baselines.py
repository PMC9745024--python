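"""Count-based aneuploidy callers: Z-score and NCV.

Both standardise a per-sample chromosome summary against the mean/SD of
a euploid reference cohort and call a trisomy when the score reaches 3.

* **Z-score** uses the chromosome's share of the genome-wide (GC- and
  mappability-adjusted) fragment count.
* **NCV** (normalised chromosomal value) divides the target chromosome
  count by a designated denominator set: chr9 for chr21, chr8 for
  chr18, and the sum of chr2..chr6 for chr13.

GC correction is a local (LOWESS) regression of bin count on bin GC,
normalised to mean 1 and divided out, followed by division by
mappability/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinSet

__all__ = ["ReferenceStats", "adjust_counts", "chrom_fraction", "ncv_ratio",
           "build_reference", "z_score", "ncv_score", "NCV_DENOMINATORS",
           "SCORE_CUTOFF", "TARGETS"]

TARGETS = ("chr21", "chr18", "chr13")
SCORE_CUTOFF = 3.0
NCV_DENOMINATORS: dict[str, tuple[str, ...]] = {
    "chr21": ("chr9",),
    "chr18": ("chr8",),
    "chr13": ("chr2", "chr3", "chr4", "chr5", "chr6"),
}


class DegenerateReferenceError(ValueError):
    """Raised when the reference cohort cannot yield a usable SD."""


@dataclass
class ReferenceStats:
    """Euploid-cohort mean/SD of the normalised value per target chromosome."""

    method: str                      # "z" or "ncv"
    mean: dict[str, float]
    sd: dict[str, float]
    cohort_size: int

    def __post_init__(self) -> None:
        if self.method not in ("z", "ncv"):
            raise ValueError("method must be 'z' or 'ncv'")
        for target, sd in self.sd.items():
            if not sd > 0:
                raise DegenerateReferenceError(
                    f"reference SD for {target} is {sd}; cohort is degenerate")

    def to_dict(self) -> dict:
        return {"method": self.method, "mean": self.mean, "sd": self.sd,
                "cohort_size": self.cohort_size}

    @classmethod
    def from_dict(cls, doc: dict) -> "ReferenceStats":
        return cls(method=doc["method"], mean=dict(doc["mean"]),
                   sd=dict(doc["sd"]), cohort_size=int(doc["cohort_size"]))


def adjust_counts(bin_counts: np.ndarray, gc_track: np.ndarray,
                  map_track: np.ndarray, lowess_frac: float = 0.3) -> np.ndarray:
    """Remove GC bias and mappability from per-bin counts.

    A LOWESS fit of count on GC percent (span ``lowess_frac``) is
    normalised to mean 1 and divided out; counts are then divided by
    mappability/100.  Input arrays are aligned (retained bins only).
    """
    counts = np.asarray(bin_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("all-zero counts; nothing to adjust")
    gc = np.asarray(gc_track, dtype=float)
    mp = np.asarray(map_track, dtype=float)
    fitted = lowess(counts, gc, frac=lowess_frac, return_sorted=False)
    fitted = np.clip(fitted, 1e-12, None)
    bias = fitted / fitted.mean()
    return counts / bias / (mp / 100.0)


def retained_bin_counts(counts_all_bins: np.ndarray, bins: BinSet) -> pd.DataFrame:
    """Restrict a full-grid count vector to retained bins, with metadata."""
    bt = bins.table
    keep = bt["retained"].to_numpy()
    return pd.DataFrame({
        "chrom": bt["chrom"].to_numpy()[keep],
        "gc": bt["gc"].to_numpy()[keep],
        "mappability": bt["mappability"].to_numpy()[keep],
        "count": np.asarray(counts_all_bins)[keep],
    })


def adjusted_chrom_counts(counts_all_bins: np.ndarray, bins: BinSet,
                          lowess_frac: float = 0.3) -> pd.Series:
    """GC/mappability-adjust retained-bin counts and sum per chromosome."""
    df = retained_bin_counts(counts_all_bins, bins)
    adj = adjust_counts(df["count"].to_numpy(), df["gc"].to_numpy(),
                        df["mappability"].to_numpy(), lowess_frac)
    return pd.Series(adj).groupby(df["chrom"].to_numpy()).sum()


def chrom_fraction(adjusted: pd.Series) -> pd.Series:
    """Per-chromosome share of the genome-wide adjusted count (sums to 1)."""
    total = adjusted.sum()
    if total <= 0:
        raise ValueError("zero total count")
    return adjusted / total


def ncv_ratio(adjusted: pd.Series, target: str) -> float:
    """Target count over its designated denominator-set count."""
    denom_chroms = NCV_DENOMINATORS[target]
    denom = sum(adjusted.get(c, 0.0) for c in denom_chroms)
    if denom <= 0:
        raise ValueError(f"zero denominator count for {target} ({denom_chroms})")
    return float(adjusted.get(target, 0.0)) / denom


def _normalized_value(adjusted: pd.Series, target: str, method: str) -> float:
    if method == "z":
        return float(chrom_fraction(adjusted)[target])
    return ncv_ratio(adjusted, target)


def build_reference(cohort_adjusted: list[pd.Series], method: str,
                    targets: tuple[str, ...] = TARGETS) -> ReferenceStats:
    """Mean/SD of the normalised values over a euploid reference cohort.

    ``cohort_adjusted`` holds each reference sample's adjusted
    per-chromosome counts.  SD is the unbiased (n-1) sample SD.
    """
    if len(cohort_adjusted) < 2:
        raise DegenerateReferenceError("reference cohort needs at least two samples")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for target in targets:
        vals = np.array([_normalized_value(a, target, method) for a in cohort_adjusted])
        mean[target] = float(vals.mean())
        sd[target] = float(vals.std(ddof=1))
    return ReferenceStats(method=method, mean=mean, sd=sd,
                          cohort_size=len(cohort_adjusted))


def z_score(adjusted: pd.Series, ref: ReferenceStats, target: str
            ) -> tuple[float, bool]:
    """Standardised chromosome fraction; positive call iff score >= 3."""
    if ref.method != "z":
        raise ValueError("reference stats were built for a different method")
    value = _normalized_value(adjusted, target, "z")
    score = (value - ref.mean[target]) / ref.sd[target]
    return score, score >= SCORE_CUTOFF


def ncv_score(adjusted: pd.Series, ref: ReferenceStats, target: str
              ) -> tuple[float, bool]:
    """Standardised NCV ratio; positive call iff score >= 3."""
    if ref.method != "ncv":
        raise ValueError("reference stats were built for a different method")
    value = _normalized_value(adjusted, target, "ncv")
    score = (value - ref.mean[target]) / ref.sd[target]
    return score, score >= SCORE_CUTOFF
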