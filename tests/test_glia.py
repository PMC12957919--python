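"""Glial coverage, intensity and nuclear-gated cell counting in annuli."""

import numpy as np
import pandas as pd
import pytest

from periplaque.geometry import get_scheme, make_distance_bins, reference_plaque
from periplaque.glia import (
    cohort_threshold,
    count_cells,
    coverage_and_intensity,
    glia_metric_table,
)

SCHEME = get_scheme("microglia_10um")


@pytest.fixture(scope="module")
def disc_bins():
    """Bin map around a 10 µm reference disc, 0.5 µm pixels, 130 µm field."""
    mask = reference_plaque((260, 260), 10.0, 0.5)
    return mask, make_distance_bins(mask, SCHEME, 0.5)


class TestCoverage:
    def test_everything_positive_reads_100_everywhere(self, disc_bins):
        _, bm = disc_bins
        img = np.ones(bm.shape)
        out = coverage_and_intensity(img, bm, SCHEME, 0.5, 0.5)
        assert np.allclose(out.coverage_pct, 100.0)

    def test_nothing_positive_reads_0_with_undefined_intensity(self, disc_bins):
        _, bm = disc_bins
        img = np.zeros(bm.shape)
        out = coverage_and_intensity(img, bm, SCHEME, 0.5, 0.5)
        assert np.allclose(out.coverage_pct, 0.0)
        assert out.mean_intensity.isna().all()

    def test_exact_fraction_recovery_on_binary_bins(self):
        from periplaque.studies import coverage_recovery_check

        res = coverage_recovery_check()
        for frac, values in res.items():
            assert np.allclose(values, 100.0 * frac)

    def test_coverage_monotone_non_increasing_in_threshold(self, disc_bins, rng):
        _, bm = disc_bins
        img = rng.uniform(0, 1, bm.shape)
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.8):
            cov = coverage_and_intensity(img, bm, SCHEME, thr, 0.5).coverage_pct
            if prev is not None:
                assert (cov <= prev + 1e-12).all()
            prev = cov

    def test_doubling_intensities_doubles_mean_intensity_exactly(self, disc_bins, rng):
        _, bm = disc_bins
        img = rng.uniform(0, 10, bm.shape)
        thr = 4.0
        a = coverage_and_intensity(img, bm, SCHEME, thr, 0.5)
        b = coverage_and_intensity(2 * img, bm, SCHEME, 2 * thr, 0.5)
        np.testing.assert_allclose(b.mean_intensity, 2 * a.mean_intensity)
        np.testing.assert_allclose(b.coverage_pct, a.coverage_pct)


def _nucleus_blob(shape, cy, cx, r=5):
    img = np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 10.0
    return img


class TestCountCells:
    def test_no_somata_counts_zero_in_every_bin(self, disc_bins):
        _, bm = disc_bins
        out = count_cells(
            np.ones(bm.shape), np.zeros(bm.shape), bm, SCHEME,
            marker_threshold=0.5, pixel_size_um=0.5, nuclear_threshold=1.0,
        )
        assert (out.cell_count == 0).all()

    def test_straddling_soma_counted_once_in_the_inner_bin(self, disc_bins):
        _, bm = disc_bins
        # soma centred exactly on the 10 µm edge: 20 µm from the disc border
        # = pixel radius (10+10)/0.5 = 40 px from centre (129.5, 129.5)
        nuc = _nucleus_blob(bm.shape, 130, 130 + 40, r=5)
        out = count_cells(
            np.ones(bm.shape), nuc, bm, SCHEME,
            marker_threshold=0.5, pixel_size_um=0.5, nuclear_threshold=1.0,
        )
        assert out.cell_count.sum() == 1  # conservation: exactly once
        by = out.set_index("bin_label").cell_count
        assert by["0-10"] == 1 and by["10-20"] == 0

    def test_marker_negative_nucleus_is_not_a_glial_cell(self, disc_bins):
        _, bm = disc_bins
        nuc = _nucleus_blob(bm.shape, 130, 170)
        out = count_cells(
            np.zeros(bm.shape), nuc, bm, SCHEME,
            marker_threshold=0.5, pixel_size_um=0.5, nuclear_threshold=1.0,
        )
        assert out.cell_count.sum() == 0

    def test_missing_nuclear_channel_is_an_error(self, disc_bins):
        _, bm = disc_bins
        with pytest.raises(ValueError, match="nuclear"):
            count_cells(np.ones(bm.shape), None, bm, SCHEME, 0.5, 0.5)

    def test_counts_conserved_across_scattered_somata(self, disc_bins):
        _, bm = disc_bins
        rng = np.random.default_rng(3)
        nuc = np.zeros(bm.shape)
        n_put = 12
        for _ in range(n_put):
            cy, cx = rng.integers(15, 245, 2)
            nuc += _nucleus_blob(bm.shape, cy, cx)
        out = count_cells(
            np.ones(bm.shape), nuc, bm, SCHEME,
            marker_threshold=0.5, pixel_size_um=0.5, nuclear_threshold=1.0,
        )
        # every soma inside the quantified regions lands in exactly one bin
        from scipy import ndimage

        labels, n_blobs = ndimage.label(nuc > 1.0)
        in_region = 0
        for b in range(1, n_blobs + 1):
            touched = set(np.unique(bm[labels == b]))
            if touched & ({-1} | set(range(SCHEME.n_bins))):
                in_region += 1
        assert out.cell_count.sum() == in_region

    def test_astrocyte_scheme_uses_25um_shells(self):
        scheme = get_scheme("astrocyte_25um")
        mask = reference_plaque((260, 260), 10.0, 0.5)
        bm = make_distance_bins(mask, scheme, 0.5)
        nuc = _nucleus_blob(mask.shape, 130, 130 + 30)  # 15 µm out -> (0,25]
        out = count_cells(
            np.ones(bm.shape), nuc, bm, scheme,
            marker_threshold=0.5, pixel_size_um=0.5, nuclear_threshold=1.0,
        )
        assert list(out.bin_label) == ["plaque", "0-25", "25-50"]
        assert out.set_index("bin_label").cell_count["0-25"] == 1


class TestMetricTable:
    def test_wt_only_cohort_normalizes_to_mean_100_per_metric(self):
        rng = np.random.default_rng(1)
        rows = []
        for a in range(1, 5):
            for s in (1, 2):
                for b in SCHEME.labels:
                    rows.append(
                        {
                            "animal": f"WT{a}", "genotype": "WT", "slice": s,
                            "image": 1, "bin_label": b, "metric": "coverage",
                            "raw": rng.uniform(10, 20),
                        }
                    )
        table = glia_metric_table(pd.DataFrame(rows))
        assert table.normalized_pct.mean() == pytest.approx(100.0)

    def test_fourfold_in_plaque_density_reads_400(self):
        rows = []
        for genotype, gain in (("WT", 1.0), ("NLGF", 1.0)):
            for a in range(1, 4):
                for b in SCHEME.labels:
                    raw = 2.0 * (4.0 if (genotype == "NLGF" and b == "plaque") else 1.0)
                    rows.append(
                        {
                            "animal": f"{genotype}{a}", "genotype": genotype,
                            "slice": 1, "image": 1, "bin_label": b,
                            "metric": "cell_density", "raw": raw,
                        }
                    )
        table = glia_metric_table(pd.DataFrame(rows))
        got = table[(table.genotype == "NLGF") & (table.bin_label == "plaque")]
        assert np.allclose(got.normalized_pct, 400.0)

    def test_cohort_threshold_pools_histograms(self, rng):
        imgs = [rng.normal(5, 1, (50, 50)), rng.normal(20, 1, (50, 50))]
        thr = cohort_threshold(imgs)
        assert 5 < thr < 20
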