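"""Glial cell number, marker coverage and intensity in plaque-centric annuli.

Glial metrics are measured on the 2D maximum projection of the 22-plane
stack, inside the plaque mask and in concentric distance shells around the
plaque border.  Coverage and intensity use one fixed threshold per cohort
(frozen from the pooled wild-type histogram by default) so values are
comparable across images; cell counting requires nuclear co-localization
(a DAPI blob overlapping marker-positive pixels), and a soma straddling a
bin edge is counted once, in the innermost region it touches — no double
counting, no loss.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .geometry import (
    IN_PLAQUE,
    PLAQUE_LABEL,
    DistanceBinScheme,
    bin_region_table,
    get_scheme,
)
from .synapses import aggregate_to_animals, normalize_to_wt


def cohort_threshold(projections: list[np.ndarray]) -> float:
    """One fixed marker threshold for a whole cohort: Otsu on the pooled histogram.

    Operationalizes "the same threshold across all images" without manual
    input; compute it on the wild-type projections and freeze it.
    """
    pooled = np.concatenate([np.asarray(p).ravel() for p in projections])
    return float(threshold_otsu(pooled))


def coverage_and_intensity(
    projection: np.ndarray,
    bin_map: np.ndarray,
    scheme: DistanceBinScheme | str,
    global_threshold: float,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Per-region marker coverage (%) and mean intensity over positive pixels.

    Regions with no marker-positive pixel report intensity as NaN; fully
    clipped regions (zero pixels) report both metrics as NaN with a flag.
    """
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    projection = np.asarray(projection)
    positive = projection > global_threshold
    regions = bin_region_table(bin_map, scheme, pixel_size_um)
    rows = []
    for _, reg in regions.iterrows():
        sel = bin_map == reg.code
        n = int(reg.n_pixels)
        if n == 0:
            rows.append(
                {
                    "bin_label": reg.bin_label,
                    "coverage_pct": np.nan,
                    "mean_intensity": np.nan,
                    "bin_area_um2": 0.0,
                    "clipped": True,
                }
            )
            continue
        pos = positive & sel
        n_pos = int(pos.sum())
        rows.append(
            {
                "bin_label": reg.bin_label,
                "coverage_pct": 100.0 * n_pos / n,
                "mean_intensity": float(projection[pos].mean()) if n_pos else np.nan,
                "bin_area_um2": float(reg.area_um2),
                "clipped": bool(reg.clipped),
            }
        )
    return pd.DataFrame(rows)


def count_cells(
    marker_projection: np.ndarray,
    nuclear_projection: np.ndarray,
    bin_map: np.ndarray,
    scheme: DistanceBinScheme | str,
    marker_threshold: float,
    pixel_size_um: float,
    nuclear_threshold: str | float = "otsu",
    overlap_frac: float = 0.3,
    min_nucleus_area_um2: float = 4.0,
) -> pd.DataFrame:
    """Per-region glial cell counts and densities (cells / µm²).

    Somata are nuclear blobs whose mask is at least ``overlap_frac``
    marker-positive.  Each soma is assigned to exactly one region — the
    innermost one its body touches (the plaque interior counts as innermost),
    which is the tie-break that avoids double counting cells straddling a
    bin edge.
    """
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    if nuclear_projection is None:
        raise ValueError("cell counting requires the nuclear channel")
    nuclear_projection = np.asarray(nuclear_projection)
    marker_positive = np.asarray(marker_projection) > marker_threshold
    if nuclear_threshold == "otsu":
        if np.ptp(nuclear_projection) <= 0:
            nthr = np.inf
        else:
            nthr = threshold_otsu(nuclear_projection)
    else:
        nthr = float(nuclear_threshold)
    nuclei, _ = ndimage.label(nuclear_projection > nthr)
    min_px = min_nucleus_area_um2 / pixel_size_um**2

    codes = ([IN_PLAQUE] if scheme.include_in_plaque else []) + list(range(scheme.n_bins))
    labels = scheme.labels
    counts = {lab: 0 for lab in labels}
    rank = {code: i for i, code in enumerate(codes)}  # innermost first
    for prop in regionprops(nuclei):
        if prop.area < min_px:
            continue
        sel = nuclei == prop.label
        if np.count_nonzero(marker_positive & sel) < overlap_frac * prop.area:
            continue
        touched = np.unique(bin_map[sel])
        touched = [c for c in touched if c in rank]
        if not touched:
            continue  # soma entirely outside the quantified regions
        inner = min(touched, key=lambda c: rank[c])
        counts[labels[rank[inner]]] += 1

    regions = bin_region_table(bin_map, scheme, pixel_size_um)
    out = regions[["bin_label", "area_um2", "clipped"]].rename(
        columns={"area_um2": "bin_area_um2"}
    )
    out = out.copy()
    out["cell_count"] = out.bin_label.map(counts).astype(int)
    out["cell_density_per_um2"] = np.where(
        out.bin_area_um2 > 0, out.cell_count / out.bin_area_um2, np.nan
    )
    return out


def glia_metric_table(per_image: pd.DataFrame) -> pd.DataFrame:
    """Animal-level MetricTable for glial metrics, raw and WT-normalized.

    ``per_image`` is long-format with one row per (animal, genotype, slice,
    image, bin_label, metric) carrying ``raw``.  Values are averaged image →
    slice → animal; each metric is then normalized to the wild-type mean
    pooled across all regions (plaque region included).
    """
    frames = []
    for metric, sub in per_image.groupby("metric", sort=False):
        table = aggregate_to_animals(sub, "raw")
        table = normalize_to_wt(table, "raw")
        table.insert(0, "metric", metric)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def region_order(scheme: DistanceBinScheme | str) -> dict[str, int]:
    """Inner→outer ordering of region labels (plaque first when included)."""
    scheme = get_scheme(scheme) if isinstance(scheme, str) else scheme
    return {lab: i for i, lab in enumerate(scheme.labels)}


__all__ = [
    "cohort_threshold",
    "coverage_and_intensity",
    "count_cells",
    "glia_metric_table",
    "region_order",
    "PLAQUE_LABEL",
]
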