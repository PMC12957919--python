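"""Parameter-recovery studies over synthetic cohorts.

Each study generates cohorts with the default study conditions (two
genotypes, n = 6 animals per group, 2 slices × 3 images per animal), runs
the full quantification pipeline on them, and measures how well the known
generator-imposed effect is recovered.  The routines here are the single
source the tests, the acceptance script and the analysis drivers all call,
so every reported number is computed by the same code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import glia as gl
from . import qpcr as qp
from . import stats as st
from . import synapses as sy
from .geometry import IN_PLAQUE, OUTSIDE, get_scheme, make_distance_bins, reference_plaque
from .plaques import PlaqueObject, classify_plaque, detect_plaques
from .synthetic import (
    GliaProfile,
    PlaqueSpec,
    SceneSpec,
    SynapseProfile,
    generate_stack,
    iter_cohort,
)

# ---------------------------------------------------------------------------
# study conditions (scene factories)

SYNAPSE_FIELD = (130.0, 130.0)
SYNAPSE_PLAQUE_RADIUS = 8.0
GLIA_FIELD = (140.0, 140.0)
GLIA_PLAQUE_RADIUS = 13.0
GLIA_PIXEL = 0.4

#: glial per-bin gains mirroring the 5-month pattern: strong elevation within
#: the plaque, decaying with distance
GLIA_DENSITY_GAIN = {"plaque": 4.0, "0-10": 2.0, "10-20": 1.5}
GLIA_COVERAGE_GAIN = {"plaque": 3.0, "0-10": 2.0, "10-20": 1.5}
GLIA_INTENSITY_GAIN = {"plaque": 2.3, "0-10": 1.5}


def synapse_scene(genotype: str, deficit: dict[str, float] | None = None) -> SceneSpec:
    """Synapse-mode scene: transgenic fields carry one central plaque."""
    plaques = ()
    if genotype != "WT":
        plaques = (
            PlaqueSpec(
                center_um=(SYNAPSE_FIELD[0] / 2, SYNAPSE_FIELD[1] / 2),
                radius_um=SYNAPSE_PLAQUE_RADIUS,
            ),
        )
    return SceneSpec(
        field_size_um=SYNAPSE_FIELD,
        acquisition_mode="synapse",
        pixel_size_um=0.25,
        plaque_specs=plaques,
        synapse_profile=SynapseProfile(deficit=deficit or {}),
    )


def glia_scene(
    genotype: str,
    density_gain: dict[str, float] | None = None,
    coverage_gain: dict[str, float] | None = None,
    intensity_gain: dict[str, float] | None = None,
    plaque_class: str = "diffuse",
) -> SceneSpec:
    """Glia-mode scene: transgenic fields carry one central plaque with gains."""
    plaques = ()
    profile = GliaProfile()
    if genotype != "WT":
        plaques = (
            PlaqueSpec(
                center_um=(GLIA_FIELD[0] / 2, GLIA_FIELD[1] / 2),
                radius_um=GLIA_PLAQUE_RADIUS,
                plaque_class=plaque_class,
            ),
        )
        profile = GliaProfile(
            density_gain=GLIA_DENSITY_GAIN if density_gain is None else density_gain,
            coverage_gain=GLIA_COVERAGE_GAIN if coverage_gain is None else coverage_gain,
            intensity_gain=GLIA_INTENSITY_GAIN if intensity_gain is None else intensity_gain,
        )
    return SceneSpec(
        field_size_um=GLIA_FIELD,
        acquisition_mode="glia",
        pixel_size_um=GLIA_PIXEL,
        plaque_specs=plaques,
        glia_profile=profile,
    )


def _sub_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _focal_plaque(stack, reference_radius_um: float) -> PlaqueObject:
    """Detected focal plaque, or the centered reference disc when none is found."""
    plaques = detect_plaques(stack)
    if plaques:
        return plaques[0]
    mask = reference_plaque(stack.shape_yx, reference_radius_um, stack.pixel_size_um)
    px = stack.pixel_size_um
    h, w = mask.shape
    return PlaqueObject(
        label=0,
        mask=mask,
        centroid_um=((w - 1) / 2 * px, (h - 1) / 2 * px),
        area_um2=float(mask.sum()) * px**2,
        pixel_size_um=px,
        plaque_class="reference",
        source_channel="reference",
    )


# ---------------------------------------------------------------------------
# synapse deficit recovery


def quantify_synapse_cohort(
    cohort, seed: int, scheme: str = "synapse_excitatory"
) -> pd.DataFrame:
    """Run plaque detection → crop placement → puncta/synapse counting per image."""
    rows = []
    for idx, (meta, stack, _truth) in enumerate(cohort):
        plaque = _focal_plaque(stack, SYNAPSE_PLAQUE_RADIUS)
        df = sy.quantify_image_synapses(
            stack, plaque, direction_seed=_sub_seed(seed, 7, idx), scheme=scheme
        )
        for _, r in df.iterrows():
            rows.append({**meta, **r.to_dict()})
    return pd.DataFrame(rows)


def synapse_deficit_cohort_result(
    cohort_seed: int,
    deficit: dict[str, float] | None = None,
    n_per_group: int = 6,
    n_slices: int = 2,
    n_images_per_slice: int = 3,
    scheme: str = "synapse_excitatory",
) -> dict:
    """One cohort: density table plus the factorial genotype × distance test."""
    if deficit is None:
        deficit = {"0-10": 0.5}
    cohort = iter_cohort(
        synapse_scene("WT"),
        synapse_scene("NLGF", deficit=deficit),
        n_per_group=n_per_group,
        seed=cohort_seed,
        n_slices=n_slices,
        n_images_per_slice=n_images_per_slice,
    )
    per_image = quantify_synapse_cohort(cohort, cohort_seed, scheme=scheme)
    table = sy.synapse_density_table(per_image, scheme=scheme)
    bin_order = get_scheme(scheme).bin_labels
    result = st.factorial_distance_test(table, bin_order)
    tg = table[table.genotype == "NLGF"]
    by_bin = tg.groupby("bin_label")["normalized_pct"].mean()
    deficit_bins = [b for b, f in deficit.items() if f != 1.0]
    other = [b for b in bin_order if b not in deficit_bins]
    post = result.posthoc
    sig = {r.bin_label: r.p_adj < 0.05 for r in post.itertuples()}
    confined = all(sig.get(b, False) for b in deficit_bins) and not any(
        sig.get(b, False) for b in other
    )
    return {
        "table": table,
        "result": result,
        "tg_norm_by_bin": by_bin,
        "deficit_bin_norm": float(by_bin[deficit_bins].mean()) if deficit_bins else np.nan,
        "other_bins_norm": float(by_bin[other].mean()),
        "interaction_p": result.p_value,
        "confined": bool(confined and result.p_value < 0.05),
    }


def synapse_deficit_study(seed: int, n_seeds: int = 20) -> dict:
    """Recovery of a 50% synapse deficit confined to the (0–10] µm bin.

    Runs ``n_seeds`` independent cohorts (n = 6 per genotype, 2 slices ×
    3 images each) and summarizes the recovered normalized density in the
    deficit bin, in the unaffected bins, and how often the interaction is
    significant with the post-hoc difference confined to (0–10].
    """
    per_seed = []
    for s in range(n_seeds):
        res = synapse_deficit_cohort_result(_sub_seed(seed, 11, s))
        per_seed.append(
            {
                "seed_index": s,
                "deficit_bin_norm": res["deficit_bin_norm"],
                "other_bins_norm": res["other_bins_norm"],
                "interaction_p": res["interaction_p"],
                "confined": res["confined"],
            }
        )
    df = pd.DataFrame(per_seed)
    return {
        "per_seed": df,
        "deficit_bin_norm_mean": float(df.deficit_bin_norm.mean()),
        "other_bins_norm_mean": float(df.other_bins_norm.mean()),
        "n_confined": int(df.confined.sum()),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# glia fold recovery


def quantify_glia_cohort(cohort, scheme: str = "microglia_10um") -> pd.DataFrame:
    """Coverage/intensity/cell-density per bin per image, cohort-thresholded.

    The marker threshold is frozen from the pooled wild-type projections
    before any measurement, then applied to every image.
    """
    cached = []
    for meta, stack, _truth in cohort:
        marker = stack.channel("glia").max(axis=0)
        nuclear = stack.channel("nuclear").max(axis=0)
        plaque = _focal_plaque(stack, GLIA_PLAQUE_RADIUS)
        cached.append((meta, marker, nuclear, plaque, stack.pixel_size_um))
    thr = gl.cohort_threshold([m for meta, m, *_ in cached if meta["genotype"] == "WT"])
    sch = get_scheme(scheme)
    rows = []
    for meta, marker, nuclear, plaque, px in cached:
        bin_map = make_distance_bins(plaque.mask, sch, px)
        cov = gl.coverage_and_intensity(marker, bin_map, sch, thr, px)
        cells = gl.count_cells(marker, nuclear, bin_map, sch, thr, px)
        for _, r in cov.iterrows():
            rows.append({**meta, "bin_label": r.bin_label, "metric": "coverage", "raw": r.coverage_pct})
            rows.append({**meta, "bin_label": r.bin_label, "metric": "intensity", "raw": r.mean_intensity})
        for _, r in cells.iterrows():
            rows.append(
                {**meta, "bin_label": r.bin_label, "metric": "cell_density", "raw": r.cell_density_per_um2}
            )
    out = pd.DataFrame(rows)
    out.attrs["marker_threshold"] = thr
    return out


def glia_fold_study(seed: int, n_per_group: int = 6) -> dict:
    """Recovery of the 4× in-plaque microglial density elevation as ≈ 400%."""
    cohort = iter_cohort(
        glia_scene("WT"),
        glia_scene("NLGF"),
        n_per_group=n_per_group,
        seed=_sub_seed(seed, 21),
    )
    per_image = quantify_glia_cohort(cohort)
    table = gl.glia_metric_table(per_image)
    dens = table[(table.metric == "cell_density") & (table.genotype == "NLGF")]
    cov = table[(table.metric == "coverage") & (table.genotype == "NLGF")]
    return {
        "table": table,
        "in_plaque_density_norm": float(
            dens[dens.bin_label == "plaque"].normalized_pct.mean()
        ),
        "in_plaque_coverage_norm": float(
            cov[cov.bin_label == "plaque"].normalized_pct.mean()
        ),
    }


# ---------------------------------------------------------------------------
# plaque classification recovery


def plaque_class_study(seed: int, n_images: int = 50, p_diffuse: float = 0.6) -> dict:
    """Diffuse-fraction recovery from Thio-S classification of synthetic plaques."""
    rng = np.random.default_rng(_sub_seed(seed, 31))
    truths, calls = [], []
    for i in range(n_images):
        is_diffuse = bool(rng.uniform() < p_diffuse)
        spec = glia_scene(
            "NLGF", plaque_class="diffuse" if is_diffuse else "non_diffuse"
        )
        spec = replace(spec, rng_seed=_sub_seed(seed, 32, i))
        stack, _truth = generate_stack(spec)
        plaques = detect_plaques(stack)
        if not plaques:
            continue
        cls = classify_plaque(plaques[0], stack.channel("thioS").max(axis=0))
        truths.append(is_diffuse)
        calls.append(cls == "diffuse")
    truths_arr = np.asarray(truths)
    calls_arr = np.asarray(calls)
    n = len(calls_arr)
    return {
        "n_images": n,
        "true_diffuse_frac": float(truths_arr.mean()) if n else np.nan,
        "recovered_diffuse_frac": float(calls_arr.mean()) if n else np.nan,
        "accuracy": float((truths_arr == calls_arr).mean()) if n else np.nan,
        "binomial_se": float(np.sqrt(p_diffuse * (1 - p_diffuse) / n)) if n else np.nan,
    }


# ---------------------------------------------------------------------------
# statistics calibration and qPCR recovery


def type1_error_study(seed: int, n_reps: int = 1000, n_per_group: int = 8) -> dict:
    """Rejection rate of the gated two-group test under the exchangeable null."""
    rng = np.random.default_rng(_sub_seed(seed, 41))
    rejected = 0
    for _ in range(n_reps):
        x = rng.normal(0, 1, n_per_group)
        y = rng.normal(0, 1, n_per_group)
        if st.two_group_test(x, y).p_value < 0.05:
            rejected += 1
    return {"rate": rejected / n_reps, "n_reps": n_reps}


def qpcr_recovery_study(seed: int, injected: dict[str, float] | None = None) -> dict:
    """ΔΔCt identities and recovery of injected fold changes (e.g. Trem2 1.8×)."""
    injected = injected or {"Trem2": 1.8}
    ct = qp.simulate_ct_table(injected, seed=_sub_seed(seed, 51))
    folds = qp.fold_change(ct, control_group="WT")
    summ = qp.group_summary(folds)
    out: dict = {"summary": summ}
    for gene, f in injected.items():
        row = summ[(summ.gene == gene) & (summ.group == "NLGF")].iloc[0]
        out[gene] = {
            "injected": f,
            "recovered": float(row["mean_fold"]),
            "sem": float(row["sem"]),
        }
    return out


# ---------------------------------------------------------------------------
# deterministic geometry checks


def annulus_geometry_check(
    plaque_radius_um: float = 15.0, pixel_size_um: float = 0.2
) -> dict:
    """Pixel-count annulus areas around a disc vs the closed form, as max |rel err|."""
    from .geometry import annulus_area_um2, bin_region_table

    sch = get_scheme("microglia_10um")
    margin = sch.edges[-1] + 5
    n = int(round(2 * (plaque_radius_um + margin) / pixel_size_um))
    mask = reference_plaque((n, n), plaque_radius_um, pixel_size_um)
    bin_map = make_distance_bins(mask, sch, pixel_size_um)
    table = bin_region_table(bin_map, sch, pixel_size_um)
    errs = {}
    for k, lab in enumerate(sch.bin_labels):
        measured = float(table[table.bin_label == lab].area_um2.iloc[0])
        expected = annulus_area_um2(plaque_radius_um, sch.edges[k], sch.edges[k + 1])
        errs[lab] = abs(measured - expected) / expected
    return {"rel_errors": errs, "max_rel_error": max(errs.values())}


def coverage_recovery_check() -> dict:
    """Painted fractions {0, ¼, 1} on binary regions recovered as exact percentages."""
    sch = get_scheme("microglia_10um")
    h, w = 40, 40 * 6
    bin_map = np.full((h, w), OUTSIDE, dtype=np.int16)
    codes = [IN_PLAQUE, 0, 1, 2, 3, 4]
    for j, code in enumerate(codes):
        bin_map[:, j * 40 : (j + 1) * 40] = code
    out = {}
    for frac in (0.0, 0.25, 1.0):
        img = np.zeros((h, w), dtype=float)
        for j in range(len(codes)):
            n_paint = int(round(frac * h * 40))
            flat = np.zeros(h * 40)
            flat[:n_paint] = 1.0
            img[:, j * 40 : (j + 1) * 40] = flat.reshape(h, 40)
        cov = gl.coverage_and_intensity(img, bin_map, sch, 0.5, pixel_size_um=1.0)
        out[frac] = [float(v) for v in cov.coverage_pct]
    return out
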