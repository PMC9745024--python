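"""cfDNA fragment simulator with known ground truth.

Emulates low-coverage single-end cfDNA sequencing of maternal plasma:
per 1-Mb bin the expected fragment intensity is

    bin_width x dosage(bin) x gc_bias(GC(bin)) x mappability(bin)/100

with dosage ``1 + f/2`` on the trisomic chromosome at fetal fraction
``f`` (the fetus contributes 3 copies instead of 2 to a fraction ``f``
of the cfDNA pool), times ``copy_ratio`` on bins covered by a maternal
CNV, and 1 elsewhere.  Masked bins get zero intensity.  The per-bin
fragment count vector is a single multinomial draw of ``n_fragments``
(fixed per-sample sequencing yield), positions are uniform within the
bin, strands Bernoulli.

For strand symmetry the simulator draws the harmonised cut coordinate
``c`` and derives the recorded leftmost position by strand, so that the
downstream +/-80 bp positional shift recovers ``c`` exactly.

Everything is reproducible from an integer seed; cohort samples derive
per-sample seeds from ``(master_seed, sample_index)`` so parallel or
partial regeneration yields identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeBuild, BinSet, make_bins, DEFAULT_BIN_WIDTH
from .fragments import FragmentTable, DEFAULT_READ_LEN
from .fd import DEFAULT_SHIFT

__all__ = ["SimConfig", "SimTruth", "simulate_sample", "simulate_bin_counts",
           "simulate_cohort", "toy_genome", "HG19_LENGTHS",
           "ASSAY_SCALE_N_FRAGMENTS", "TOY_N_FRAGMENTS"]

#: sequencing yield of the emulated assay (reads per sample)
ASSAY_SCALE_N_FRAGMENTS = 12_000_000
#: default desk-scale yield
TOY_N_FRAGMENTS = 200_000

TRISOMIES = ("none", "chr21", "chr18", "chr13")

# GRCh37 chromosome lengths (bp)
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560,
}


@dataclass
class SimConfig:
    """Parameters of one simulated sample."""

    genome: GenomeBuild
    n_fragments: int = TOY_N_FRAGMENTS
    fetal_fraction: float = 0.0
    trisomy: str = "none"
    #: quadratic GC-bias coefficients (a0, a1, a2) in u = (GC - 40)/10;
    #: the curve is renormalised to mean 1 over retained bins
    gc_bias: tuple[float, float, float] = (1.0, 0.06, -0.04)
    #: maternal CNV events as (chrom, start, end, copy_ratio)
    cnv_specs: list[tuple[str, int, int, float]] = field(default_factory=list)
    strand_prob: float = 0.5
    read_len: int = DEFAULT_READ_LEN
    shift: int = DEFAULT_SHIFT
    bin_width: int = DEFAULT_BIN_WIDTH
    seed: int | tuple = 0
    #: optional injection of filter-fodder records (fractions of n_fragments)
    dup_rate: float = 0.0
    low_mapq_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fetal_fraction <= 1.0:
            raise ValueError("fetal_fraction must be in [0, 1]")
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if self.trisomy not in TRISOMIES:
            raise ValueError(f"trisomy must be one of {TRISOMIES}")
        if self.trisomy != "none" and self.trisomy not in self.genome.chrom_lengths:
            raise ValueError(f"trisomy chromosome {self.trisomy!r} absent from genome")
        for chrom, start, end, ratio in self.cnv_specs:
            if ratio <= 0:
                raise ValueError("CNV copy_ratio must be positive")
            if chrom not in self.genome.chrom_lengths:
                raise ValueError(f"CNV chromosome {chrom!r} absent from genome")
            if not start < end:
                raise ValueError("CNV interval must have start < end")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth label attached to a simulated sample."""

    trisomy: str
    fetal_fraction: float
    cnv_specs: tuple
    seed: int | tuple


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def gc_bias_curve(gc: np.ndarray, coef: tuple[float, float, float],
                  retained: np.ndarray) -> np.ndarray:
    """Evaluate the quadratic GC bias, normalised to mean 1 over retained bins."""
    u = (np.asarray(gc, dtype=float) - 40.0) / 10.0
    raw = np.clip(coef[0] + coef[1] * u + coef[2] * u * u, 0.0, None)
    denom = raw[retained].mean() if retained.any() else raw.mean()
    if denom <= 0:
        raise ValueError("GC bias curve vanishes on retained bins")
    return raw / denom


def bin_intensities(config: SimConfig, bins: BinSet) -> np.ndarray:
    """Expected (unnormalised) fragment intensity per bin of the grid."""
    bt = bins.table
    retained = bt["retained"].to_numpy()
    intensity = np.where(bt["masked"].to_numpy(), 0.0, float(bins.width))
    intensity = intensity * gc_bias_curve(bt["gc"].to_numpy(), config.gc_bias, retained)
    intensity = intensity * (bt["mappability"].to_numpy(dtype=float) / 100.0)
    chroms = bt["chrom"].to_numpy()
    if config.trisomy != "none":
        dosage = 1.0 + config.fetal_fraction / 2.0
        intensity = np.where(chroms == config.trisomy, intensity * dosage, intensity)
    starts = bt["start"].to_numpy()
    ends = bt["end"].to_numpy()
    for chrom, cstart, cend, ratio in config.cnv_specs:
        on = chroms == chrom
        ovl = np.clip(np.minimum(ends, cend) - np.maximum(starts, cstart), 0, None)
        frac = np.where(on, ovl / (ends - starts), 0.0)
        intensity = intensity * (1.0 + frac * (ratio - 1.0))
    return intensity


def simulate_bin_counts(config: SimConfig, bins: BinSet | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw only the per-bin fragment counts (fast path for count-based
    methods that never look at individual positions)."""
    if bins is None:
        bins = make_bins(config.genome, config.bin_width)
    if rng is None:
        rng = _rng(config.seed)
    intensity = bin_intensities(config, bins)
    total = intensity.sum()
    if total <= 0:
        raise ValueError("all-zero intensity; nothing to simulate")
    return rng.multinomial(config.n_fragments, intensity / total)


def simulate_sample(config: SimConfig, bins: BinSet | None = None
                    ) -> tuple[FragmentTable, SimTruth]:
    """Simulate one sample's aligned fragment table plus its truth label."""
    if bins is None:
        bins = make_bins(config.genome, config.bin_width)
    rng = _rng(config.seed)
    counts = simulate_bin_counts(config, bins, rng)
    bt = bins.table
    n = int(counts.sum())

    bin_idx = np.repeat(np.arange(len(bt)), counts)
    # harmonised cut coordinate (1-based); margins keep the whole read inside
    # its bin, so no fragment ever touches a masked interval or chromosome end
    margin = max(config.shift, config.read_len - 1 - config.shift, 1)
    hi = max(bins.width - margin, margin + 1)
    offsets = rng.integers(margin, hi, size=n)
    c = bt["start"].to_numpy()[bin_idx] + 1 + offsets
    fwd = rng.random(n) < config.strand_prob
    pos = np.where(fwd, c - config.shift, c - config.read_len + 1 + config.shift)
    bin_chrom_codes, chrom_cats = pd.factorize(bt["chrom"], sort=False)
    chrom = pd.Categorical.from_codes(np.repeat(bin_chrom_codes, counts), chrom_cats)
    strand = np.where(fwd, "+", "-")
    mapq = np.full(n, 60, dtype=np.int64)
    dup = np.zeros(n, dtype=np.int64)
    if config.low_mapq_rate > 0:
        mapq[rng.random(n) < config.low_mapq_rate] = 30
    if config.dup_rate > 0:
        dup[rng.random(n) < config.dup_rate] = 1

    table = FragmentTable.from_arrays(chrom, pos, strand, mapq, dup,
                                      read_len=config.read_len)
    truth = SimTruth(trisomy=config.trisomy, fetal_fraction=config.fetal_fraction,
                     cnv_specs=tuple(config.cnv_specs), seed=config.seed)
    return table, truth


def simulate_cohort(n: int, prevalence: dict[str, float], base_config: SimConfig,
                    fetal_fraction_range: tuple[float, float] = (0.04, 0.20),
                    bins: BinSet | None = None, counts_only: bool = False):
    """Yield ``n`` simulated samples with labels drawn per ``prevalence``.

    ``prevalence`` maps trisomy name to proportion (summing to <= 1;
    the remainder is euploid).  Per-sample fetal fraction is uniform on
    ``fetal_fraction_range``.  Sample ``i`` uses seed
    ``(base_config.seed, i)``; the label/fraction stream uses
    ``(base_config.seed, n)`` — the whole cohort is reproducible from
    the master seed.  With ``counts_only`` yields ``(counts, truth)``
    instead of ``(FragmentTable, truth)``.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    total_prev = sum(prevalence.values())
    if total_prev > 1.0 + 1e-9:
        raise ValueError("prevalence proportions sum above 1")
    labels = ["none"] + [k for k in prevalence]
    probs = np.array([1.0 - total_prev] + [prevalence[k] for k in prevalence])
    if bins is None:
        bins = make_bins(base_config.genome, base_config.bin_width)

    master = base_config.seed if isinstance(base_config.seed, int) else tuple(base_config.seed)
    meta_rng = _rng((master, n))
    drawn = meta_rng.choice(len(labels), size=n, p=probs)
    fracs = meta_rng.uniform(*fetal_fraction_range, size=n)
    for i in range(n):
        label = labels[drawn[i]]
        cfg = replace(base_config, trisomy=label,
                      fetal_fraction=float(fracs[i]) if label != "none" else float(fracs[i]),
                      seed=(master, i))
        if counts_only:
            counts = simulate_bin_counts(cfg, bins)
            truth = SimTruth(cfg.trisomy, cfg.fetal_fraction, tuple(cfg.cnv_specs), cfg.seed)
            yield counts, truth
        else:
            yield simulate_sample(cfg, bins)


def truth_table(truths) -> pd.DataFrame:
    """Tabulate SimTruth records (one row per sample) for the truth TSV."""
    rows = [(i, t.trisomy, t.fetal_fraction, repr(list(t.cnv_specs)), repr(t.seed))
            for i, t in enumerate(truths)]
    return pd.DataFrame(rows, columns=["sample", "trisomy", "fetal_fraction",
                                       "cnv_specs", "seed"])


def toy_genome(scale: float = 0.5, track_seed: int = 20220929) -> GenomeBuild:
    """A scaled human-like genome for desk-scale studies.

    Chromosome lengths are the GRCh37 ones multiplied by ``scale``.
    GC and mappability tracks are drawn once from ``track_seed`` (a
    fixed property of the genome, not of any sample): GC oscillates
    around 41% with noise so a realistic minority of bins violates the
    (30, 50] retention window, and ~7% of bins get low mappability.
    The centromeric middle 6% of each chromosome plus the first and
    last bin (telomeres) are masked.
    """
    rng = _rng(track_seed)
    lengths = {c: int(l * scale) for c, l in HG19_LENGTHS.items()}
    names = list(lengths)
    gc_track: dict[str, np.ndarray] = {}
    map_track: dict[str, np.ndarray] = {}
    masks: dict[str, list[tuple[int, int]]] = {}
    for chrom in names:
        L = lengths[chrom]
        n = L // DEFAULT_BIN_WIDTH
        i = np.arange(n)
        gc = 41.0 + 8.0 * np.sin(2 * np.pi * i / 17.0 + rng.uniform(0, 2 * np.pi)) \
            + rng.normal(0, 2.0, size=n)
        gc_track[chrom] = np.clip(gc, 20.0, 65.0)
        mp = np.where(rng.random(n) < 0.07,
                      rng.uniform(50.0, 80.0, size=n),
                      rng.uniform(85.0, 100.0, size=n))
        map_track[chrom] = mp
        centro_mid = L // 2
        half = max(int(0.03 * L), 1)
        masks[chrom] = [
            (0, min(DEFAULT_BIN_WIDTH, L)),               # p telomere
            (centro_mid - half, centro_mid + half),       # centromere
            (max(L - DEFAULT_BIN_WIDTH, 0), L),           # q telomere
        ]
    return GenomeBuild(chrom_names=names, chrom_lengths=lengths,
                       mask_intervals=masks, gc_track=gc_track, map_track=map_track)
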