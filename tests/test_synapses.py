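"""Crop placement, puncta detection, and co-localization synapse counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from periplaque.plaques import detect_plaques
from periplaque.studies import _focal_plaque
from periplaque.synapses import (
    PUNCTA_COLUMNS,
    PunctaSet,
    count_synapses,
    crop_volume_um3,
    detect_puncta,
    place_crops,
    quantify_image_synapses,
    synapse_density_table,
)


def _puncta(coords):
    coords = np.atleast_2d(np.asarray(coords, float))
    if coords.size == 0:
        return PunctaSet("x", pd.DataFrame(columns=PUNCTA_COLUMNS))
    df = pd.DataFrame(coords, columns=["x_um", "y_um", "z_um"])
    df["volume_vox"] = 5
    df["peak"] = 1.0
    df["flux"] = 1.0
    df["multiplicity"] = 1
    return PunctaSet("x", df)


class TestCropGeometry:
    def test_crop_volume_identity(self):
        # 10 × 10 µm footprint over 9 planes 0.25 µm apart spans 2 µm: 200 µm³
        assert crop_volume_um3(10.0, 9, 0.25) == pytest.approx(200.0)

    def test_series_anchors_at_border_and_reaches_50um(self, tg_synapse_stack):
        stack, _ = tg_synapse_stack
        plaque = detect_plaques(stack)[0]
        series = place_crops(plaque, stack, direction_seed=5)
        assert series.labels == ["core", "0-10", "10-20", "20-30", "30-40", "40-50"]
        r = np.hypot(
            series.origin_um[0] - plaque.centroid_um[0],
            series.origin_um[1] - plaque.centroid_um[1],
        )
        # ray origin sits on the plaque border (8 µm disc, fuzzy edge)
        assert r == pytest.approx(8.0, abs=1.5)
        assert series.crop_volume_um3 == pytest.approx(200.0)

    def test_same_seed_same_ray(self, tg_synapse_stack):
        stack, _ = tg_synapse_stack
        plaque = detect_plaques(stack)[0]
        s1 = place_crops(plaque, stack, direction_seed=9)
        s2 = place_crops(plaque, stack, direction_seed=9)
        assert s1.direction == s2.direction
        np.testing.assert_array_equal(s1.crops["pre"][1], s2.crops["pre"][1])

    def test_crops_are_consecutive_and_disjoint(self, tg_synapse_stack):
        stack, _ = tg_synapse_stack
        plaque = detect_plaques(stack)[0]
        series = place_crops(plaque, stack, direction_seed=5)
        u = np.array(series.direction)
        origin = np.array(series.origin_um)
        centers = [origin + u * (-5.0)] + [origin + u * (10 * k + 5.0) for k in range(5)]
        for a, b in zip(centers[:-1], centers[1:]):
            assert np.linalg.norm(b - a) == pytest.approx(10.0)


class TestDetectPuncta:
    def test_blank_crop_yields_empty_set(self, rng):
        crop = rng.normal(5, 1, (9, 40, 40)).astype(np.float32)
        assert len(detect_puncta(crop, "pre", 0.25, 0.25)) == 0

    def test_single_spot_centroid_within_one_voxel(self):
        crop = np.full((9, 40, 40), 5.0, np.float32)
        rng = np.random.default_rng(1)
        crop += rng.normal(0, 0.5, crop.shape).astype(np.float32)
        zc, yc, xc = 4, 20, 13
        zz, yy, xx = np.meshgrid(np.arange(9), np.arange(40), np.arange(40), indexing="ij")
        crop += 40 * np.exp(
            -0.5 * (((zz - zc) / 2.0) ** 2 + ((yy - yc) / 0.8) ** 2 + ((xx - xc) / 0.8) ** 2)
        ).astype(np.float32)
        ps = detect_puncta(crop, "pre", 0.25, 0.25)
        assert len(ps) == 1
        got = ps.coords[0]
        want = np.array([xc * 0.25, yc * 0.25, zc * 0.25])
        assert np.abs(got - want).max() < 0.25

    def test_two_spots_beyond_2sigma_resolve(self):
        crop = np.full((9, 40, 40), 5.0, np.float32)
        rng = np.random.default_rng(2)
        crop += rng.normal(0, 0.5, crop.shape).astype(np.float32)
        zz, yy, xx = np.meshgrid(np.arange(9), np.arange(40), np.arange(40), indexing="ij")
        for xc in (12, 18):  # 6 px apart ≫ 2σ (σ≈0.8 px)
            crop += 40 * np.exp(
                -0.5 * (((zz - 4) / 2.0) ** 2 + ((yy - 20) / 0.8) ** 2 + ((xx - xc) / 0.8) ** 2)
            ).astype(np.float32)
        ps = detect_puncta(crop, "pre", 0.25, 0.25)
        # brute-force oracle: two local maxima above threshold
        assert ps.n_components == 2


def _brute_force_greedy(a, b, radius):
    """Independent O(n³) matcher: repeatedly take the globally closest pair."""
    a, b = list(map(np.asarray, (a, b)))
    used_a, used_b, n = set(), set(), 0
    while True:
        best = None
        for i in range(len(a)):
            if i in used_a:
                continue
            for j in range(len(b)):
                if j in used_b:
                    continue
                d = float(np.linalg.norm(a[i] - b[j]))
                if d <= radius and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is None:
            return n
        used_a.add(best[1])
        used_b.add(best[2])
        n += 1


class TestCountSynapses:
    def test_empty_post_gives_zero(self):
        assert count_synapses(_puncta([[1, 1, 1]]), _puncta([])) == 0

    def test_identical_sets_pair_completely(self):
        pts = [[0, 0, 0], [1, 1, 1], [2, 0, 1]]
        assert count_synapses(_puncta(pts), _puncta(pts)) == 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 10), st.integers(0, 10))
    def test_matches_exhaustive_oracle_on_small_sets(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 3, (na, 3))
        b = rng.uniform(0, 3, (nb, 3))
        got = count_synapses(_puncta(a), _puncta(b), 0.5)
        assert got == _brute_force_greedy(a, b, 0.5)
        # symmetry and the cardinality bound
        assert got == count_synapses(_puncta(b), _puncta(a), 0.5)
        assert got <= min(na, nb)

    def test_density_invariant_to_crop_position_in_homogeneous_field(
        self, small_synapse_stack
    ):
        stack, truth = small_synapse_stack
        counts = []
        for x0 in (0, 20, 40):
            crops = {
                ch: stack.channel(ch)[:, 10:50, x0 : x0 + 40] for ch in ("pre", "post")
            }
            pre = detect_puncta(crops["pre"], "pre", 0.25, 0.25)
            post = detect_puncta(crops["post"], "post", 0.25, 0.25)
            counts.append(count_synapses(pre, post))
        lam = np.mean(counts)
        se = np.sqrt(lam)
        assert max(abs(c - lam) for c in counts) < 3 * se


class TestDensityTables:
    @staticmethod
    def _per_image(counts_by_genotype_bin):
        rows = []
        for genotype, per_bin in counts_by_genotype_bin.items():
            for a in range(1, 4):
                for bin_label, c in per_bin.items():
                    rows.append(
                        {
                            "animal": f"{genotype}{a}",
                            "genotype": genotype,
                            "slice": 1,
                            "image": 1,
                            "bin_label": bin_label,
                            "raw_count_per_200um3": c,
                        }
                    )
        return pd.DataFrame(rows)

    def test_uniform_wt_normalizes_to_100_everywhere(self):
        bins = {"0-10": 7, "10-20": 7, "20-30": 7, "30-40": 7, "40-50": 7}
        table = synapse_density_table(self._per_image({"WT": bins}))
        assert np.allclose(table.normalized_pct, 100.0)

    def test_half_deficit_reads_50_in_its_bin(self):
        wt = {b: 8.0 for b in ("0-10", "10-20", "20-30", "30-40", "40-50")}
        tg = dict(wt)
        tg["0-10"] = 4.0
        table = synapse_density_table(self._per_image({"WT": wt, "NLGF": tg}))
        tg_rows = table[table.genotype == "NLGF"]
        assert np.allclose(
            tg_rows[tg_rows.bin_label == "0-10"].normalized_pct, 50.0
        )
        assert np.allclose(
            tg_rows[tg_rows.bin_label != "0-10"].normalized_pct, 100.0
        )

    def test_no_wt_leaves_raw_table_without_normalization(self):
        tg = {b: 5.0 for b in ("0-10", "10-20")}
        table = synapse_density_table(self._per_image({"NLGF": tg}))
        assert table.normalized_pct.isna().all()
        assert (table.raw_count_per_200um3 == 5.0).all()

    def test_inhibitory_preset_drops_the_first_crop_from_the_schema(
        self, tg_synapse_stack
    ):
        stack, _ = tg_synapse_stack
        plaque = _focal_plaque(stack, 8.0)
        df = quantify_image_synapses(stack, plaque, 3, scheme="synapse_inhibitory")
        assert set(df.bin_label) == {"10-20", "20-30", "30-40", "40-50"}
        df_exc = quantify_image_synapses(stack, plaque, 3, scheme="synapse_excitatory")
        assert "0-10" in set(df_exc.bin_label) and "core" not in set(df_exc.bin_label)
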