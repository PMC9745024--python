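"""Desk-scale end-to-end studies on the built-in simulator.

These workflows wire the whole pipeline together — simulate cfDNA
fragments, compute fragment-distance features, select control
chromosomes, render TRS images, train the per-trisomy CNNs, and score
the count-based baselines — at sizes a single CPU handles in minutes.

Problem sizes (the package's study conditions):

* genome: GRCh37 chromosome proportions at half scale (~1.4 Gb, ~1500
  one-Mb bins);
* depth: 800,000 fragments per sample — per-bin FD medians are stable
  (~5% relative noise against a 4-7% trisomy signal) and the
  maternal-CNV scenario below shifts the chr18 fraction by ~5 reference
  SDs, as the real event did on the full assay; 750,000 for the
  Z-score power study,
  chosen by a power calculation (the chr21 share rises by p*f/2 under
  trisomy while its SD shrinks as 1/sqrt(depth); 750k gives a mean
  z of ~4.7 at f = 0.10, i.e. >90% detection at cutoff 3);
* cohorts: 150 euploid + 150 trisomy-21 samples for the chr21 model
  (the euploid half doubles as the reference cohort), 150 + 50 for the
  chr18 model used in the maternal-CNV scenario;
* fetal fractions: uniform 0.08-0.15 for affected training samples;
* maternal-CNV scenario: a euploid pregnancy carrying a 2-Mb one-copy
  duplication (copy ratio 1.5) spanning two retained chr18 bins — the
  half-scale analogue of a multi-Mb maternal event.  It inflates the
  chr18 Z-score by ~5 reference SDs, while the affected bins fall
  strictly inside the 10% lower-tail trim capacity of the TRS pipeline
  (2 of a 3-bin budget on chr18's 30 retained bins), so the image-based
  caller stays negative.  The footprint is kept below the trim budget
  deliberately: when an event consumes the entire budget, the
  chromosome's own low tail survives untrimmed and mimics a weak
  trisomy shift.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .genome import BinSet, make_bins
from .fragments import FragmentTable
from .fd import BinFDTable, shift_positions, compute_fd, bin_fd_stats
from .trs import ICCSelection, select_icc, build_trs_images, REPRESENTATIVES
from .baselines import (adjusted_chrom_counts, build_reference, z_score,
                        ncv_score, ReferenceStats)
from .classifier import TrainConfig, TrisomyModel, train_models, predict_proba
from .simulate import SimConfig, simulate_sample, simulate_bin_counts, toy_genome

__all__ = ["extract_features", "simulate_feature_cohort", "fit_target_model",
           "run_study", "study_train_config", "STUDY_N_FRAGMENTS",
           "POWER_N_FRAGMENTS", "CNV_CHR18"]

STUDY_N_FRAGMENTS = 800_000
POWER_N_FRAGMENTS = 750_000
#: half-scale chr18 maternal duplication (chrom, start, end, copy_ratio)
CNV_CHR18 = ("chr18", 31_000_000, 33_000_000, 1.5)


def extract_features(fragments: FragmentTable, bins: BinSet) -> BinFDTable:
    """Shift, difference and summarise one sample's fragments per bin."""
    shifted = shift_positions(fragments, shift=80)
    distances = compute_fd(shifted)
    return bin_fd_stats(shifted, distances, bins)


def simulate_feature_cohort(genome, bins: BinSet, specs: list[tuple[str, float]],
                            n_fragments: int, seed_stream: tuple
                            ) -> list[BinFDTable]:
    """Simulate one sample per (trisomy, fetal_fraction) spec and return
    its per-bin FD table.  Sample ``i`` uses seed ``(*seed_stream, i)``."""
    tables = []
    for i, (label, f) in enumerate(specs):
        cfg = SimConfig(genome=genome, n_fragments=n_fragments, trisomy=label,
                        fetal_fraction=f, seed=(*seed_stream, i))
        frags, _ = simulate_sample(cfg, bins)
        tables.append(extract_features(frags, bins))
    return tables


def _image_stack(tables: list[BinFDTable], target: str, icc: ICCSelection
                 ) -> dict[str, np.ndarray]:
    stacks: dict[str, list] = {rep: [] for rep in REPRESENTATIVES}
    for table in tables:
        images = build_trs_images(table, target, icc)
        for rep in REPRESENTATIVES:
            stacks[rep].append(images[rep].pixels)
    return {rep: np.stack(v) for rep, v in stacks.items()}


def study_train_config(seed: int) -> TrainConfig:
    """Training settings for the desk-scale studies (small net, early stop)."""
    return TrainConfig(seed=seed, max_epochs=40, patience=6)


def fit_target_model(tables: list[BinFDTable], labels: np.ndarray, target: str,
                     icc: ICCSelection, config: TrainConfig
                     ) -> tuple[TrisomyModel, dict[str, float]]:
    """Render TRS images for ``target`` and train its CNN grid.

    Returns the model plus held-out AUCs (one per representative and
    for the ensemble) from the cross-validation test splits.
    """
    images = _image_stack(tables, target, icc)
    model = train_models(images, labels, config, target=target)
    aucs = {rep: float(roc_auc_score(labels, model.cv_probs[rep]))
            for rep in REPRESENTATIVES}
    aucs["ensemble"] = float(roc_auc_score(labels, model.heldout_ensemble()))
    return model, aucs


def _fractions(rng: np.random.Generator, n: int, lo: float = 0.08,
               hi: float = 0.15) -> np.ndarray:
    return rng.uniform(lo, hi, size=n)


def dosage_recovery(genome, bins: BinSet, seed: int, n_reps: int = 50,
                    fetal_fraction: float = 0.10,
                    n_fragments: int = 200_000) -> float:
    """Mean chr21 fragment-share ratio, trisomic vs euploid (expect 1 + f/2).

    Counts-only replicates; the ratio is taken pairwise at matched seeds
    so depth noise largely cancels.
    """
    keep = bins.table["retained"].to_numpy()
    on21 = (bins.table["chrom"].to_numpy() == "chr21") & keep
    ratios = []
    for i in range(n_reps):
        base = SimConfig(genome=genome, n_fragments=n_fragments, seed=(seed, 4, i))
        tri = replace(base, trisomy="chr21", fetal_fraction=fetal_fraction)
        c_eu = simulate_bin_counts(base, bins)
        c_tr = simulate_bin_counts(tri, bins)
        share_eu = c_eu[on21].sum() / c_eu[keep].sum()
        share_tr = c_tr[on21].sum() / c_tr[keep].sum()
        ratios.append(share_tr / share_eu)
    return float(np.mean(ratios))


def _counts_reference(genome, bins: BinSet, seed_stream: tuple, n_ref: int,
                      n_fragments: int, method: str) -> ReferenceStats:
    cohort = []
    for i in range(n_ref):
        cfg = SimConfig(genome=genome, n_fragments=n_fragments, seed=(*seed_stream, i))
        counts = simulate_bin_counts(cfg, bins)
        cohort.append(adjusted_chrom_counts(counts, bins))
    return build_reference(cohort, method)


def z_power(genome, bins: BinSet, seed: int, n_reps: int = 100,
            fetal_fraction: float = 0.10, n_fragments: int = POWER_N_FRAGMENTS,
            n_ref: int = 60) -> float:
    """Fraction of simulated trisomy-21 replicates with chr21 Z-score >= 3."""
    ref = _counts_reference(genome, bins, (seed, 3), n_ref, n_fragments, "z")
    hits = 0
    for i in range(n_reps):
        cfg = SimConfig(genome=genome, n_fragments=n_fragments, trisomy="chr21",
                        fetal_fraction=fetal_fraction, seed=(seed, 2, i))
        counts = simulate_bin_counts(cfg, bins)
        adjusted = adjusted_chrom_counts(counts, bins)
        score, positive = z_score(adjusted, ref, "chr21")
        hits += int(positive)
    return hits / n_reps


def run_study(seed: int, n_per_class: int = 150, n_t18: int = 50,
              n_fragments: int = STUDY_N_FRAGMENTS, n_cnv: int = 30,
              n_power: int = 100, n_dosage: int = 50,
              with_power: bool = True, with_dosage: bool = True) -> dict:
    """Full desk-scale study; returns a flat dict of computed quantities."""
    genome = toy_genome()
    bins = make_bins(genome)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 10)))

    specs_eu = [("none", 0.0)] * n_per_class
    specs_21 = [("chr21", float(f)) for f in _fractions(rng, n_per_class)]
    specs_18 = [("chr18", float(f)) for f in _fractions(rng, n_t18)]

    tables_eu = simulate_feature_cohort(genome, bins, specs_eu, n_fragments, (seed, 0, 0))
    tables_21 = simulate_feature_cohort(genome, bins, specs_21, n_fragments, (seed, 0, 1))
    tables_18 = simulate_feature_cohort(genome, bins, specs_18, n_fragments, (seed, 0, 2))

    icc21 = select_icc(tables_eu, "chr21")
    icc18 = select_icc(tables_eu, "chr18")

    labels21 = np.array([0] * n_per_class + [1] * n_per_class)
    model21, auc21 = fit_target_model(tables_eu + tables_21, labels21, "chr21",
                                      icc21, study_train_config(seed))
    labels18 = np.array([0] * n_per_class + [1] * n_t18)
    model18, auc18 = fit_target_model(tables_eu + tables_18, labels18, "chr18",
                                      icc18, study_train_config(seed + 1))

    # count-based reference from the euploid training half
    cohort_adjusted = [adjusted_chrom_counts(t.table["fc"].to_numpy(), bins)
                       for t in tables_eu]
    ref_z = build_reference(cohort_adjusted, "z")
    ref_ncv = build_reference(cohort_adjusted, "ncv")

    # maternal-CNV scenario: euploid + chr18 duplication
    cnv_tables = []
    z_hits = 0
    for i in range(n_cnv):
        cfg = SimConfig(genome=genome, n_fragments=n_fragments,
                        cnv_specs=[CNV_CHR18], seed=(seed, 1, i))
        frags, _ = simulate_sample(cfg, bins)
        table = extract_features(frags, bins)
        cnv_tables.append(table)
        adjusted = adjusted_chrom_counts(table.table["fc"].to_numpy(), bins)
        _, positive = z_score(adjusted, ref_z, "chr18")
        z_hits += int(positive)
    cnv_images = _image_stack(cnv_tables, "chr18", icc18)
    cnv_probs = predict_proba(model18, cnv_images)
    cnv_neg = int(np.sum(cnv_probs["ensemble"] < model18.config.cutoff))

    results = {
        "auc_chr21_ensemble": auc21["ensemble"],
        "auc_chr21_mean": auc21["mean"],
        "auc_chr21_median": auc21["median"],
        "auc_chr21_iqr": auc21["iqr"],
        "auc_chr18_ensemble": auc18["ensemble"],
        "cnv_z_positive_rate": z_hits / n_cnv,
        "cnv_ensemble_negative_rate": cnv_neg / n_cnv,
        "cnv_ensemble_probs": [float(p) for p in cnv_probs["ensemble"]],
        "chr18_euploid_heldout_fpr": float(
            (model18.heldout_ensemble()[labels18 == 0] >= model18.config.cutoff).mean()),
        "n_train_chr21": len(labels21),
        "n_train_chr18": len(labels18),
        "n_cnv": n_cnv,
        "icc_chr21": icc21.chromosomes,
        "icc_chr18": icc18.chromosomes,
        "ref_z": ref_z, "ref_ncv": ref_ncv,
        "model21": model21, "model18": model18,
    }
    if with_power:
        results["z_power_rate"] = z_power(genome, bins, seed, n_reps=n_power)
        results["n_power"] = n_power
    if with_dosage:
        results["dosage_ratio_f10"] = dosage_recovery(genome, bins, seed,
                                                      n_reps=n_dosage)
        results["n_dosage"] = n_dosage
    return results
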