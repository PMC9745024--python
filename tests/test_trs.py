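import numpy as np
import pandas as pd
import pytest

from aidnipt.fd import BinFDTable
from aidnipt.trs import (DegenerateSampleError, ICCSelection, TRS_HEIGHT,
                         TRS_WIDTH, normalize_and_trim, render_trs, select_icc)


def _fake_table(chrom_medians: dict[str, float], bin_table: pd.DataFrame | None = None):
    if bin_table is None:
        bin_table = pd.DataFrame(columns=["chrom", "start", "end", "retained",
                                          "fd_mean", "fd_median", "fd_iqr", "usable"])
    return BinFDTable(table=bin_table, chrom_median_fd=chrom_medians)


def _cohort(n, noise_by_chrom, seed=0):
    """Cohort where 1/median(candidate) = 1/median(target) + noise."""
    rng = np.random.default_rng(seed)
    tables = []
    base = rng.uniform(2.0e-4, 4.0e-4, size=n)  # target reciprocal medians
    for s in range(n):
        medians = {"chr21": 1.0 / base[s]}
        for chrom, sd in noise_by_chrom.items():
            medians[chrom] = 1.0 / (base[s] + rng.normal(0, sd * 1e-4))
        tables.append(_fake_table(medians))
    return tables


class TestICCSelection:
    def test_perfect_fit_wins(self):
        tables = _cohort(20, {"chr1": 0.5, "chr2": 0.8, "chr3": 0.2})
        for t in tables:  # chr4 mirrors the target exactly -> MSE 0
            t.chrom_median_fd["chr4"] = t.chrom_median_fd["chr21"]
        icc = select_icc(tables, "chr21")
        assert icc.chromosomes[0] == "chr4"
        assert icc.controls[0][1] == np.inf

    def test_noise_order_matches_independent_ols_oracle(self):
        noise = {"chr1": 0.001, "chr2": 0.01, "chr3": 0.1}
        tables = _cohort(20, noise, seed=3)
        icc = select_icc(tables, "chr21")
        assert icc.chromosomes == ["chr1", "chr2", "chr3"]
        # oracle: refit each regression with numpy.polyfit and recompute MSE
        y = np.array([1 / t.chrom_median_fd["chr21"] for t in tables])
        for chrom, score in icc.controls:
            x = np.array([1 / t.chrom_median_fd[chrom] for t in tables])
            slope, intercept = np.polyfit(x, y, 1)
            mse = np.mean((y - (slope * x + intercept)) ** 2)
            assert score == pytest.approx(-np.log10(mse), rel=1e-9)

    def test_single_sample_cohort_rejected(self):
        tables = _cohort(1, {"chr1": 0.1, "chr2": 0.1, "chr3": 0.1})
        with pytest.raises(ValueError, match="two reference samples"):
            select_icc(tables, "chr21")

    def test_targets_and_sex_chromosomes_never_eligible(self):
        tables = _cohort(10, {"chr1": 0.1, "chr2": 0.1, "chr3": 0.1})
        for t in tables:  # perfectly-correlated but ineligible chromosomes
            for c in ("chr13", "chr18", "chrX"):
                t.chrom_median_fd[c] = t.chrom_median_fd["chr21"]
        icc = select_icc(tables, "chr21")
        assert set(icc.chromosomes) == {"chr1", "chr2", "chr3"}

    def test_too_few_candidates_rejected(self):
        tables = _cohort(10, {"chr1": 0.1, "chr2": 0.1})
        with pytest.raises(ValueError, match="eligible"):
            select_icc(tables, "chr21")

    def test_selection_type_invariants(self):
        with pytest.raises(ValueError):
            ICCSelection(target="chr21", controls=(("chr1", 1.0), ("chr2", 1.0)))
        with pytest.raises(ValueError):
            ICCSelection(target="chr21",
                         controls=(("chr21", 1.0), ("chr2", 1.0), ("chr3", 1.0)))


def _bin_table(values_by_chrom):
    rows = []
    for chrom, vals in values_by_chrom.items():
        for i, v in enumerate(vals):
            rows.append((chrom, i * 10, (i + 1) * 10, True, v, v, v / 10, True))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "retained",
                                       "fd_mean", "fd_median", "fd_iqr", "usable"])


def _icc123():
    return ICCSelection(target="chr21", controls=(("chr1", 3.0), ("chr2", 2.0),
                                                  ("chr3", 1.0)))


class TestNormalizeAndTrim:
    def test_constant_sample_normalises_to_one(self):
        table = _fake_table({}, _bin_table({c: [500.0] * 20
                                            for c in ("chr21", "chr1", "chr2", "chr3")}))
        out = normalize_and_trim(table, "chr21", _icc123())
        for chrom in ("chr21", "chr1"):
            np.testing.assert_allclose(out["median"][chrom], 1.0)

    def test_trim_counts_and_order(self):
        """30 usable bins: floor(0.1*30)=3 dropped each side, 24 survive
        in genomic order."""
        rng = np.random.default_rng(0)
        vals = {c: 500 + rng.normal(0, 40, 30) for c in ("chr21", "chr1", "chr2", "chr3")}
        table = _fake_table({}, _bin_table(vals))
        out = normalize_and_trim(table, "chr21", _icc123())
        global_median = np.median(np.concatenate(list(vals.values())))
        for chrom in vals:
            trimmed = out["median"][chrom]
            assert len(trimmed) == 24
            norm = vals[chrom] / global_median
            order = np.argsort(norm, kind="stable")
            survivors = np.ones(30, dtype=bool)
            survivors[order[:3]] = survivors[order[-3:]] = False
            np.testing.assert_allclose(trimmed, norm[survivors])

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = {c: 500 + rng.normal(0, 40, 15) for c in ("chr21", "chr1", "chr2", "chr3")}
        t1 = _fake_table({}, _bin_table(vals))
        t2 = _fake_table({}, _bin_table({c: 2 * v for c, v in vals.items()}))
        o1 = normalize_and_trim(t1, "chr21", _icc123())
        o2 = normalize_and_trim(t2, "chr21", _icc123())
        for rep in o1:
            for chrom in o1[rep]:
                np.testing.assert_allclose(o1[rep][chrom], o2[rep][chrom])

    def test_never_removes_more_than_20_percent(self):
        for n in (5, 9, 10, 11, 29, 30, 31, 100):
            vals = {c: 500 + np.arange(n, dtype=float)
                    for c in ("chr21", "chr1", "chr2", "chr3")}
            table = _fake_table({}, _bin_table(vals))
            out = normalize_and_trim(table, "chr21", _icc123())
            assert len(out["median"]["chr21"]) >= np.ceil(0.8 * n)

    def test_zero_global_median_rejected(self):
        table = _fake_table({}, _bin_table({c: [0.0] * 5
                                            for c in ("chr21", "chr1", "chr2", "chr3")}))
        with pytest.raises(DegenerateSampleError):
            normalize_and_trim(table, "chr21", _icc123())

    def test_missing_chromosome_rejected(self):
        table = _fake_table({}, _bin_table({"chr21": [500.0] * 5}))
        with pytest.raises(DegenerateSampleError, match="chr1"):
            normalize_and_trim(table, "chr21", _icc123())


class TestRender:
    def test_constant_one_draws_horizontal_midline(self):
        seqs = [np.ones(20)] * 3
        img = render_trs(np.ones(20), seqs, "median")
        row = int(np.rint((1.5 - 1.0) / 1.0 * (TRS_HEIGHT - 1)))
        assert (img.pixels[row, :] == 1.0).all()
        assert img.pixels.sum() == TRS_WIDTH  # nothing but the line

    def test_dimensions_fixed(self):
        img = render_trs(np.full(3, 0.9), [np.full(7, 1.1)] * 3, "mean")
        assert img.pixels.shape == (200, 400)

    def test_pure_function_byte_identical(self):
        rng = np.random.default_rng(2)
        tc = 1 + 0.1 * rng.standard_normal(25)
        iccs = [1 + 0.1 * rng.standard_normal(30) for _ in range(3)]
        a = render_trs(tc, iccs, "iqr")
        b = render_trs(tc, iccs, "iqr")
        assert np.array_equal(a.pixels, b.pixels)

    def test_layout_tc_at_positions_2_4_6(self):
        img = render_trs(np.ones(10), [np.ones(10)] * 3, "median",
                         icc_names=["chr3", "chr7", "chr10"], target_name="chr21")
        names = [name for name, _, _ in img.layout]
        assert names == ["chr3", "chr21", "chr7", "chr21", "chr10", "chr21"]
        cols = [c for _, c0, c1 in img.layout for c in (c0, c1)]
        assert cols[0] == 0 and cols[-1] == TRS_WIDTH - 1

    def test_values_outside_range_clipped(self):
        img = render_trs(np.array([5.0, -5.0]), [np.ones(2)] * 3, "median")
        assert img.pixels[0, :].any() and img.pixels[TRS_HEIGHT - 1, :].any()

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty segment"):
            render_trs(np.empty(0), [np.ones(5)] * 3, "median")

    def test_trisomy_shifts_target_band(self):
        """A uniform TC shift lands the TC polyline in a different row
        band at segments 2, 4, 6; smaller FD (trisomy) means lower y."""
        icc = [np.full(20, 1.0)] * 3
        img_eu = render_trs(np.full(20, 1.0), icc, "median")
        img_tr = render_trs(np.full(20, 1.0 / 1.05), icc, "median")

        def tc_rows(img):
            rows = []
            for i, (_, c0, c1) in enumerate(img.layout):
                if i % 2 == 1:
                    r, _ = np.nonzero(img.pixels[:, c0 + 2:c1 - 1])
                    rows.append(r.mean())
            return np.mean(rows)

        assert tc_rows(img_tr) > tc_rows(img_eu)  # larger row index = smaller FD

    def test_png_roundtrip(self, tmp_path):
        from PIL import Image
        img = render_trs(np.ones(10), [np.ones(10)] * 3, "median")
        path = tmp_path / "trs.png"
        img.to_png(path)
        arr = np.asarray(Image.open(path))
        assert arr.shape == (200, 400)
        np.testing.assert_array_equal(arr > 0, img.pixels > 0)
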