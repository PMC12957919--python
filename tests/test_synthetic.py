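"""Ground-truthed scene generator: determinism, Poisson statistics, invariants."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from periplaque.synthetic import (
    PlaqueSpec,
    SceneSpec,
    SynapseProfile,
    generate_cohort,
    generate_stack,
    iter_cohort,
    region_labels,
)


class TestDeterminism:
    def test_same_spec_same_seed_is_bit_identical(self, small_synapse_spec):
        s1, _ = generate_stack(small_synapse_spec)
        s2, _ = generate_stack(small_synapse_spec)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_different_seed_differs(self, small_synapse_spec):
        s1, _ = generate_stack(small_synapse_spec)
        s2, _ = generate_stack(replace(small_synapse_spec, rng_seed=99))
        assert not np.array_equal(s1.voxels, s2.voxels)


class TestSynapseScenes:
    def test_zero_density_gives_pure_background(self, small_synapse_spec):
        spec = replace(
            small_synapse_spec,
            synapse_profile=SynapseProfile(baseline_pair_density_per_um3=0.0,
                                           unpaired_fraction=0.0),
        )
        stack, truth = generate_stack(spec)
        assert len(truth.puncta) == 0
        pre = stack.channel("pre")
        # background + Gaussian noise only
        assert abs(float(pre.mean()) - spec.noise.background) < 0.5
        assert float(pre.std()) < 1.5 * spec.noise.gaussian_sigma

    def test_pair_counts_follow_poisson_law(self, small_synapse_spec):
        # 20 seeds over a 10×10×2 µm = 200 µm³ region at 0.3 pairs/µm³:
        # mean true paired count should sit within 3 s.e. of 60
        counts = []
        for seed in range(20):
            _, truth = generate_stack(replace(small_synapse_spec, rng_seed=seed))
            p = truth.puncta
            pairs = p[(p.channel == "pre") & p.paired]
            sel = (pairs.x_um > 5) & (pairs.x_um <= 15) & (pairs.y_um > 5) & (pairs.y_um <= 15)
            counts.append(int(sel.sum()))
        expected = 0.3 * 200.0
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_every_paired_pre_has_one_partner_within_pairing_radius(self, small_synapse_spec):
        _, truth = generate_stack(small_synapse_spec)
        p = truth.puncta
        pre = p[(p.channel == "pre") & p.paired].set_index("pair_id")
        post = p[(p.channel == "post") & p.paired].set_index("pair_id")
        assert pre.index.is_unique and post.index.is_unique
        assert set(pre.index) == set(post.index)
        d = np.linalg.norm(
            pre[["x_um", "y_um", "z_um"]].to_numpy()
            - post.loc[pre.index, ["x_um", "y_um", "z_um"]].to_numpy(),
            axis=1,
        )
        assert (d <= small_synapse_spec.synapse_profile.pairing_radius_um + 1e-9).all()

    def test_bin_truth_matches_brute_force_recount(self):
        # independent oracle: signed distance to the disc border, point by point
        spec = SceneSpec(
            field_size_um=(130.0, 130.0),
            acquisition_mode="synapse",
            plaque_specs=(PlaqueSpec(center_um=(65.0, 65.0), radius_um=8.0),),
            synapse_profile=SynapseProfile(deficit={"0-10": 0.5}),
            rng_seed=3,
        )
        _, truth = generate_stack(spec)
        pairs = truth.puncta[(truth.puncta.channel == "pre") & truth.puncta.paired]
        edges = [0, 10, 20, 30, 40, 50]
        labels = ["0-10", "10-20", "20-30", "30-40", "40-50"]
        d = np.hypot(pairs.x_um - 65.0, pairs.y_um - 65.0) - 8.0
        for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
            brute = int(((d > lo) & (d <= hi)).sum())
            stored = int(truth.bin_truth.set_index("bin_label").loc[lab, "pair_count"])
            assert brute == stored

    def test_rendered_puncta_match_records_at_low_density(self):
        from periplaque.synapses import detect_puncta

        spec = SceneSpec(
            field_size_um=(20.0, 20.0),
            acquisition_mode="synapse",
            plaque_specs=(),
            synapse_profile=SynapseProfile(
                baseline_pair_density_per_um3=0.01, unpaired_fraction=0.0
            ),
            rng_seed=5,
        )
        stack, truth = generate_stack(spec)
        for ch in ("pre", "post"):
            # deblending off: this checks the rendering, punctum for punctum
            found = detect_puncta(stack.channel(ch), ch, 0.25, 0.25, deblend=False)
            records = truth.puncta[truth.puncta.channel == ch]
            # puncta can straddle the imaged volume's edge (pairing offsets
            # reach past the slab); every interior record must be detected,
            # each exactly once, with no spurious detections elsewhere
            interior = records[
                records.x_um.between(1, 19) & records.y_um.between(1, 19)
                & records.z_um.between(0.4, 1.6)
            ]
            got = found.coords
            for _, r in interior.iterrows():
                d = np.linalg.norm(got - r[["x_um", "y_um", "z_um"]].to_numpy(float), axis=1)
                assert (d < 0.5).sum() == 1
            assert len(found) <= len(records)


class TestValidation:
    def test_field_too_small_for_outermost_bin_is_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            SceneSpec(
                field_size_um=(60.0, 60.0),
                acquisition_mode="synapse",
                plaque_specs=(PlaqueSpec(center_um=(30.0, 30.0), radius_um=8.0),),
            )

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(synapse_profile=SynapseProfile(baseline_pair_density_per_um3=-1))

    def test_region_labels_around_disc(self):
        plaques = (PlaqueSpec(center_um=(0.0, 0.0), radius_um=5.0),)
        from periplaque.geometry import get_scheme

        pts = np.array([[0, 0], [0, 9], [0, 16], [0, 70]], dtype=float)
        labs = region_labels(pts, plaques, get_scheme("microglia_10um"))
        assert list(labs) == ["plaque", "0-10", "10-20", "far"]


class TestCohorts:
    def test_manifest_nesting_matches_design(self, tmp_path, small_synapse_spec):
        man = generate_cohort(
            small_synapse_spec, small_synapse_spec, n_per_group=6, seed=1,
            out_dir=tmp_path, n_slices=1, n_images_per_slice=1,
        )
        assert man.animal.nunique() == 12
        assert (man.genotype.value_counts() == 6).all()
        # round-trips through the pipeline's reader unchanged
        back = pd.read_csv(tmp_path / "manifest.csv")
        pd.testing.assert_frame_equal(back, man)

    def test_same_specs_differ_only_by_seed_stream(self, small_synapse_spec):
        stacks = [
            s for _m, s, _t in iter_cohort(
                small_synapse_spec, small_synapse_spec, 1, seed=4,
                n_slices=1, n_images_per_slice=1,
            )
        ]
        assert len(stacks) == 2
        assert not np.array_equal(stacks[0].voxels, stacks[1].voxels)

    def test_cohort_is_reproducible(self, small_synapse_spec):
        def first_stack():
            return next(iter(iter_cohort(
                small_synapse_spec, small_synapse_spec, 1, seed=8,
                n_slices=1, n_images_per_slice=1,
            )))[1]

        np.testing.assert_array_equal(first_stack().voxels, first_stack().voxels)
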