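"""Target-repeat-stacking (TRS) images.

A TRS image encodes one sample's fragment-distance profile for one
target chromosome (TC) as a 200x400 grayscale line plot in which the
TC is stacked repeatedly across three internal control chromosomes
(ICCs): segment order ICC1, TC, ICC2, TC, ICC3, TC — the TC occupies
the 2nd, 4th and 6th positions.

* **ICC selection** — on a euploid reference cohort, ordinary least
  squares of the target's reciprocal median FD on each candidate
  autosome's; candidates ranked by -log10(MSE), top three win.  The
  trisomy targets (chr13/18/21) and sex chromosomes are never eligible.
* **Median normalisation** — every per-bin representative value (mean,
  median, IQR) is divided by the sample's global median (the
  genome-wide median of per-bin FD medians), making images
  depth-independent.
* **Trimming** — per chromosome and per representative, the lowest 10%
  and highest 10% of bins by normalised value are dropped (genomic
  order of survivors preserved); this is what blunts focal maternal
  CNVs.
* **Rasterisation** — a 1-px polyline on a black background, drawn
  directly into the matrix (Bresenham) with a fixed affine y-map from
  [0.5, 1.5] (clipped) to rows, so intensities are bit-reproducible
  and comparable across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fd import BinFDTable
from .genome import TARGET_CHROMOSOMES, SEX_CHROMOSOMES

__all__ = ["ICCSelection", "TRSImage", "select_icc", "normalize_and_trim",
           "render_trs", "build_trs_images", "REPRESENTATIVES",
           "TRS_HEIGHT", "TRS_WIDTH", "DEFAULT_Y_RANGE"]

REPRESENTATIVES = ("mean", "median", "iqr")
TRS_HEIGHT = 200
TRS_WIDTH = 400
DEFAULT_Y_RANGE = (0.5, 1.5)
DEFAULT_TRIM = 0.10

_REP_COLUMN = {"mean": "fd_mean", "median": "fd_median", "iqr": "fd_iqr"}


class DegenerateSampleError(ValueError):
    """Raised when a sample's FD table cannot support normalisation."""


@dataclass(frozen=True)
class ICCSelection:
    """Three control chromosomes for one target, with -log10(MSE) scores."""

    target: str
    controls: tuple[tuple[str, float], ...]  # ((chrom, score), ...) best first

    def __post_init__(self) -> None:
        if len(self.controls) != 3:
            raise ValueError("exactly three control chromosomes are required")
        for chrom, _ in self.controls:
            if chrom == self.target or chrom in TARGET_CHROMOSOMES or chrom in SEX_CHROMOSOMES:
                raise ValueError(f"{chrom} is not an eligible control chromosome")

    @property
    def chromosomes(self) -> list[str]:
        return [c for c, _ in self.controls]

    def to_dict(self) -> dict:
        return {"target": self.target,
                "controls": [[c, s] for c, s in self.controls]}

    @classmethod
    def from_dict(cls, doc: dict) -> "ICCSelection":
        return cls(target=doc["target"],
                   controls=tuple((c, float(s)) for c, s in doc["controls"]))


@dataclass
class TRSImage:
    """A 200x400 grayscale matrix plus its segment layout metadata."""

    pixels: np.ndarray                       # (TRS_HEIGHT, TRS_WIDTH) float32 in [0,1]
    layout: list[tuple[str, int, int]]       # (segment name, first col, last col)
    representative: str
    y_range: tuple[float, float] = DEFAULT_Y_RANGE

    def __post_init__(self) -> None:
        if self.pixels.shape != (TRS_HEIGHT, TRS_WIDTH):
            raise ValueError(f"TRS image must be {TRS_HEIGHT}x{TRS_WIDTH}, "
                             f"got {self.pixels.shape}")

    def to_png(self, path) -> None:
        from PIL import Image
        arr = np.clip(self.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path, dpi=(200, 200))

    def to_npz(self, path) -> None:
        np.savez_compressed(path, pixels=self.pixels,
                            layout=np.array(self.layout, dtype=object),
                            representative=self.representative)


def _chrom_order_key(chrom: str) -> tuple[int, str]:
    body = chrom.removeprefix("chr")
    return (int(body), "") if body.isdigit() else (10**6, body)


def select_icc(reference_tables: list[BinFDTable], target: str,
               candidates: list[str] | None = None) -> ICCSelection:
    """Pick the three autosomes whose reciprocal median FD best predicts
    the target's across a euploid reference cohort.

    For each eligible candidate, fit ``1/medFD(target) ~ 1/medFD(candidate)``
    by OLS over the cohort and score it by ``-log10(MSE)`` of the
    residuals; a perfect fit (MSE 0) scores ``+inf``.  Ties break by
    chromosome order.  Requires >= 2 reference samples and >= 3
    eligible candidates.
    """
    if len(reference_tables) < 2:
        raise ValueError("ICC regression needs at least two reference samples")
    y = np.array([1.0 / t.chrom_median_fd[target] for t in reference_tables])
    if candidates is None:
        chroms = reference_tables[0].chrom_median_fd.keys()
        candidates = [c for c in chroms
                      if c != target and c not in TARGET_CHROMOSOMES
                      and c not in SEX_CHROMOSOMES]
    if len(candidates) < 3:
        raise ValueError(f"only {len(candidates)} eligible control candidates")

    scored: list[tuple[float, tuple[int, str], str]] = []
    for cand in candidates:
        x = np.array([1.0 / t.chrom_median_fd[cand] for t in reference_tables])
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mse = float(np.mean((y - X @ beta) ** 2))
        # numerically perfect fits count as MSE 0 (score +inf)
        if mse <= 1e-24 * float(np.mean(y * y)):
            score = math.inf
        else:
            score = -math.log10(mse)
        scored.append((score, _chrom_order_key(cand), cand))
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = tuple((chrom, score) for score, _, chrom in scored[:3])
    return ICCSelection(target=target, controls=top)


def _trim_sequence(values: np.ndarray, trim: float) -> np.ndarray:
    """Drop the floor(trim*n) lowest and highest values, preserving order."""
    n = len(values)
    k = int(math.floor(trim * n))
    if k == 0:
        return values
    order = np.argsort(values, kind="stable")
    drop = np.zeros(n, dtype=bool)
    drop[order[:k]] = True
    drop[order[n - k:]] = True
    return values[~drop]


def normalize_and_trim(table: BinFDTable, target: str, icc: ICCSelection,
                       trim: float = DEFAULT_TRIM) -> dict[str, dict[str, np.ndarray]]:
    """Median-normalise the per-bin representatives and trim the tails.

    Returns ``{representative: {chrom: ordered value array}}`` for the
    target and the three control chromosomes.  The normaliser is the
    sample's genome-wide median of per-bin FD medians over retained,
    usable bins; per chromosome and representative the lowest and
    highest ``floor(trim * n)`` bins are removed with genomic order of
    the survivors preserved.
    """
    usable = table.usable
    global_median = float(np.median(usable["fd_median"].to_numpy()))
    if not np.isfinite(global_median) or global_median == 0.0:
        raise DegenerateSampleError("global median FD is zero or undefined")

    chroms = [target] + icc.chromosomes
    out: dict[str, dict[str, np.ndarray]] = {rep: {} for rep in REPRESENTATIVES}
    for chrom in chroms:
        sub = usable[usable["chrom"] == chrom]
        if sub.empty:
            raise DegenerateSampleError(f"no usable bins on {chrom}")
        for rep in REPRESENTATIVES:
            values = sub[_REP_COLUMN[rep]].to_numpy(dtype=float) / global_median
            out[rep][chrom] = _trim_sequence(values, trim)
    return out


def _draw_polyline(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> None:
    """1-px Bresenham polyline with intensity 1, no anti-aliasing."""
    for i in range(len(xs) - 1):
        x0, y0, x1, y1 = int(xs[i]), int(ys[i]), int(xs[i + 1]), int(ys[i + 1])
        dx, dy = abs(x1 - x0), -abs(y1 - y0)
        sx = 1 if x0 < x1 else -1
        sy = 1 if y0 < y1 else -1
        err = dx + dy
        while True:
            img[y0, x0] = 1.0
            if x0 == x1 and y0 == y1:
                break
            e2 = 2 * err
            if e2 >= dy:
                err += dy
                x0 += sx
            if e2 <= dx:
                err += dx
                y0 += sy


def render_trs(target_values: np.ndarray, icc_values: list[np.ndarray],
               representative: str,
               y_range: tuple[float, float] = DEFAULT_Y_RANGE,
               icc_names: list[str] | None = None,
               target_name: str = "TC") -> TRSImage:
    """Rasterise the six-segment sequence ICC1,TC,ICC2,TC,ICC3,TC.

    x is the index within the concatenated sequence rescaled to the
    400 columns; y maps affinely from ``y_range`` (values clipped) to
    rows 199 (bottom, y_min) through 0 (top, y_max).  Pure function:
    identical inputs give byte-identical images.
    """
    if len(icc_values) != 3:
        raise ValueError("three ICC value sequences are required")
    segments = [icc_values[0], target_values, icc_values[1],
                target_values, icc_values[2], target_values]
    if icc_names is None:
        icc_names = ["ICC1", "ICC2", "ICC3"]
    names = [icc_names[0], target_name, icc_names[1],
             target_name, icc_names[2], target_name]
    for name, seg in zip(names, segments):
        if len(seg) == 0:
            raise ValueError(f"empty segment {name!r}")

    values = np.concatenate(segments)
    n = len(values)
    y_min, y_max = y_range
    clipped = np.clip(values, y_min, y_max)
    rows = np.rint((y_max - clipped) / (y_max - y_min) * (TRS_HEIGHT - 1)).astype(int)
    if n == 1:
        cols = np.array([0])
    else:
        cols = np.rint(np.arange(n) * (TRS_WIDTH - 1) / (n - 1)).astype(int)

    img = np.zeros((TRS_HEIGHT, TRS_WIDTH), dtype=np.float32)
    _draw_polyline(img, cols, rows)

    layout = []
    start = 0
    for name, seg in zip(names, segments):
        stop = start + len(seg)
        layout.append((name, int(cols[start]), int(cols[stop - 1])))
        start = stop
    return TRSImage(pixels=img, layout=layout, representative=representative,
                    y_range=y_range)


def build_trs_images(table: BinFDTable, target: str, icc: ICCSelection,
                     trim: float = DEFAULT_TRIM,
                     y_range: tuple[float, float] = DEFAULT_Y_RANGE
                     ) -> dict[str, TRSImage]:
    """Normalise, trim and render all three representatives for one sample."""
    trimmed = normalize_and_trim(table, target, icc, trim)
    images = {}
    for rep in REPRESENTATIVES:
        seqs = trimmed[rep]
        images[rep] = render_trs(seqs[target], [seqs[c] for c in icc.chromosomes],
                                 rep, y_range=y_range, icc_names=icc.chromosomes,
                                 target_name=target)
    return images
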