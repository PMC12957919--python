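"""Synthetic multi-channel confocal stacks with machine-readable ground truth.

The generator emulates the two acquisition geometries used for tissue
imaging around amyloid plaques:

* ``synapse`` mode — 9 equidistant planes 0.25 µm apart (2.0 µm span),
  with pre- and post-synaptic puncta channels plus a plaque channel.
  Paired puncta model synapses: each pre punctum gets exactly one post
  partner at an offset drawn uniformly inside the pairing radius, so
  pairs are detectable as co-localized by construction.  Pair density can
  be modulated per distance bin around the plaque border (a multiplicative
  deficit), which is how genotype effects are injected.
* ``glia`` mode — 22 equidistant planes 1 µm apart, with a glial-marker
  channel (somata as blobs, processes as random-walk strokes), a nuclear
  channel (glial nuclei co-localized with somata plus unrelated background
  nuclei), a plaque channel, and a Thioflavin-S channel that labels the
  compact cores of non-diffuse plaques.  Per-bin gains modulate soma
  density, process count (coverage) and amplitude (intensity) separately.

Every random draw flows from ``SceneSpec.rng_seed``: identical spec and
seed yield bit-identical voxel arrays.  Point sources are deposited with
trilinear weights and blurred once per channel with an anisotropic
Gaussian point-spread function, which is equivalent to stamping a kernel
per point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import (
    PLAQUE_LABEL,
    DistanceBinScheme,
    ImageStack3D,
    get_scheme,
    write_stack,
)

FAR_LABEL = "far"

#: acquisition geometries: mode -> (n_planes, z_spacing_um, channel roles)
MODES: dict[str, tuple[int, float, tuple[str, ...]]] = {
    "synapse": (9, 0.25, ("pre", "post", "plaque")),
    "glia": (22, 1.0, ("glia", "nuclear", "plaque", "thioS")),
}


@dataclass(frozen=True)
class PlaqueSpec:
    """One plaque to render: a disc of ``radius_um`` at ``center_um`` (x, y).

    ``plaque_class`` is "diffuse" (soft, low-gradient edge) or "non_diffuse"
    (sharper halo plus a bright Thio-S-positive core of ``core_radius_um``).
    """

    center_um: tuple[float, float]
    radius_um: float
    plaque_class: str = "diffuse"
    core_radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("plaque radius must be positive")
        if self.plaque_class not in ("diffuse", "non_diffuse"):
            raise ValueError(f"unknown plaque class {self.plaque_class!r}")
        if self.plaque_class == "non_diffuse" and self.core_radius_um is None:
            object.__setattr__(self, "core_radius_um", 0.5 * self.radius_um)


@dataclass(frozen=True)
class SynapseProfile:
    """Paired-puncta statistics for synapse mode.

    ``baseline_pair_density_per_um3`` is the synapse (pair) density far from
    plaques; ``deficit`` maps a distance-bin label to a multiplicative factor
    (1 = no change, 0.5 = half the synapses).  ``unpaired_fraction`` is the
    fraction of puncta in each channel without a partner.
    """

    baseline_pair_density_per_um3: float = 0.3
    deficit: dict[str, float] = field(default_factory=dict)
    in_plaque_factor: float = 0.3
    unpaired_fraction: float = 0.25
    pairing_radius_um: float = 0.4
    peak_intensity: float = 40.0

    def factor(self, label: str) -> float:
        if label == PLAQUE_LABEL:
            return self.deficit.get(PLAQUE_LABEL, self.in_plaque_factor)
        return self.deficit.get(label, 1.0)


@dataclass(frozen=True)
class GliaProfile:
    """Glial scene statistics for glia mode (densities are 2D, per µm²)."""

    soma_density_per_um2: float = 1.2e-3
    density_gain: dict[str, float] = field(default_factory=dict)
    coverage_gain: dict[str, float] = field(default_factory=dict)
    intensity_gain: dict[str, float] = field(default_factory=dict)
    soma_sigma_um: float = 2.5
    nucleus_sigma_um: float = 1.8
    soma_peak: float = 40.0
    nucleus_peak: float = 35.0
    processes_per_cell: float = 4.0
    process_step_um: float = 0.5
    process_length_um: float = 16.0
    process_peak: float = 16.0
    background_nuclei_per_um2: float = 2e-3

    @staticmethod
    def _get(d: dict[str, float], label: str) -> float:
        return d.get(label, 1.0)

    def gains(self, label: str) -> tuple[float, float, float]:
        return (
            self._get(self.density_gain, label),
            self._get(self.coverage_gain, label),
            self._get(self.intensity_gain, label),
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive background plus Gaussian read noise; optional Poisson shot noise."""

    background: float = 5.0
    gaussian_sigma: float = 3.0
    poisson: bool = False


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic field; deterministic given ``rng_seed``."""

    field_size_um: tuple[float, float] = (130.0, 130.0)
    acquisition_mode: str = "synapse"
    pixel_size_um: float = 0.25
    plaque_specs: tuple[PlaqueSpec, ...] = ()
    synapse_profile: SynapseProfile = field(default_factory=SynapseProfile)
    glia_profile: GliaProfile = field(default_factory=GliaProfile)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    psf_sigma_xy_um: float = 0.15
    psf_sigma_z_um: float = 0.5
    bin_scheme: str | None = None  # defaults to the mode's convention
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.acquisition_mode not in MODES:
            raise ValueError(f"unknown acquisition mode {self.acquisition_mode!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        sp = self.synapse_profile
        if sp.baseline_pair_density_per_um3 < 0 or not 0 <= sp.unpaired_fraction < 1:
            raise ValueError("invalid synapse profile")
        for mult in list(sp.deficit.values()) + [sp.in_plaque_factor]:
            if not (np.isfinite(mult) and mult >= 0):
                raise ValueError("deficit multipliers must be finite and >= 0")
        gp = self.glia_profile
        if gp.soma_density_per_um2 < 0:
            raise ValueError("soma density must be >= 0")
        for d in (gp.density_gain, gp.coverage_gain, gp.intensity_gain):
            for mult in d.values():
                if not (np.isfinite(mult) and mult >= 0):
                    raise ValueError("glia gains must be finite and >= 0")
        fx, fy = self.field_size_um
        outer = self.scheme.edges[-1]
        for p in self.plaque_specs:
            cx, cy = p.center_um
            reach = p.radius_um + outer
            if cx - reach < 0 or cy - reach < 0 or cx + reach > fx or cy + reach > fy:
                raise ValueError(
                    f"field {fx}x{fy} µm too small to hold the outermost "
                    f"{outer:g} µm bin of plaque at {p.center_um} (r={p.radius_um})"
                )

    @property
    def scheme(self) -> DistanceBinScheme:
        if self.bin_scheme is not None:
            return get_scheme(self.bin_scheme)
        return get_scheme(
            "synapse_excitatory" if self.acquisition_mode == "synapse" else "microglia_10um"
        )

    @property
    def n_planes(self) -> int:
        return MODES[self.acquisition_mode][0]

    @property
    def z_spacing_um(self) -> float:
        return MODES[self.acquisition_mode][1]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return MODES[self.acquisition_mode][2]

    @property
    def axial_span_um(self) -> float:
        return (self.n_planes - 1) * self.z_spacing_um


@dataclass
class GroundTruth:
    """Machine-readable record of what was rendered.

    ``bin_truth`` stores per-region counts, sizes and densities computed by
    brute force from the point records and the analytic region geometry.
    """

    mode: str
    scheme_name: str
    plaques: pd.DataFrame
    puncta: pd.DataFrame
    glia: pd.DataFrame
    bin_truth: pd.DataFrame

    def write(self, directory, stem: str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / f"{stem}_truth.json").write_text(
            json.dumps({"mode": self.mode, "scheme": self.scheme_name}, indent=2)
        )
        self.plaques.to_csv(directory / f"{stem}_plaques.csv", index=False)
        self.puncta.to_csv(directory / f"{stem}_puncta.csv", index=False)
        self.glia.to_csv(directory / f"{stem}_glia.csv", index=False)
        self.bin_truth.to_csv(directory / f"{stem}_bins.csv", index=False)


# ---------------------------------------------------------------------------
# geometry helpers on analytic plaque discs


def border_distances(
    xy_um: np.ndarray, plaques: tuple[PlaqueSpec, ...]
) -> np.ndarray:
    """Signed distance (µm) from points to the nearest plaque border (<0 inside)."""
    if len(plaques) == 0:
        return np.full(len(xy_um), np.inf)
    d = np.full(len(xy_um), np.inf)
    for p in plaques:
        r = np.hypot(xy_um[:, 0] - p.center_um[0], xy_um[:, 1] - p.center_um[1])
        d = np.minimum(d, r - p.radius_um)
    return d


def _region_codes(
    xy_um: np.ndarray, plaques: tuple[PlaqueSpec, ...], scheme: DistanceBinScheme
) -> np.ndarray:
    """Integer region code per point: -1 plaque, 0..n_bins-1 bins, n_bins far."""
    d = border_distances(np.atleast_2d(xy_um), plaques)
    edges = np.asarray(scheme.edges, float)
    k = np.searchsorted(edges, d, side="left") - 1  # (edges[k], edges[k+1]]
    codes = np.where((k >= 0) & (k < scheme.n_bins) & (d > edges[0]), k, scheme.n_bins)
    codes[d <= 0] = -1
    return codes.astype(np.int64)


def region_labels(
    xy_um: np.ndarray, plaques: tuple[PlaqueSpec, ...], scheme: DistanceBinScheme
) -> np.ndarray:
    """Region label for each (x, y) point: plaque, a bin label, or far."""
    codes = _region_codes(xy_um, plaques, scheme)
    lut = np.array([PLAQUE_LABEL] + scheme.bin_labels + [FAR_LABEL], dtype=object)
    return lut[codes + 1]


def _pixel_region_areas(spec: SceneSpec) -> pd.DataFrame:
    """Pixel-count area (µm²) of every region label on the scene grid."""
    px = spec.pixel_size_um
    nx = int(round(spec.field_size_um[0] / px))
    ny = int(round(spec.field_size_um[1] / px))
    xs = (np.arange(nx) + 0.5) * px
    ys = (np.arange(ny) + 0.5) * px
    xg, yg = np.meshgrid(xs, ys)
    codes = _region_codes(
        np.column_stack([xg.ravel(), yg.ravel()]), spec.plaque_specs, spec.scheme
    )
    counts = np.bincount(codes + 1, minlength=spec.scheme.n_bins + 2)
    lut = [PLAQUE_LABEL] + spec.scheme.bin_labels + [FAR_LABEL]
    keep = counts > 0
    return pd.DataFrame(
        {
            "bin_label": [lab for lab, k in zip(lut, keep) if k],
            "area_um2": counts[keep] * px**2,
        }
    )


# ---------------------------------------------------------------------------
# rendering primitives


def _deposit_points(
    vol: np.ndarray, zyx_vox: np.ndarray, flux: np.ndarray
) -> None:
    """Accumulate point masses into ``vol`` with trilinear weights (in place)."""
    if len(zyx_vox) == 0:
        return
    nz, ny, nx = vol.shape
    base = np.floor(zyx_vox).astype(np.int64)
    frac = zyx_vox - base
    flat = vol.ravel()
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = base + off
        w = np.prod(np.where(off == 1, frac, 1.0 - frac), axis=1) * flux
        ok = (
            (idx[:, 0] >= 0) & (idx[:, 0] < nz)
            & (idx[:, 1] >= 0) & (idx[:, 1] < ny)
            & (idx[:, 2] >= 0) & (idx[:, 2] < nx)
        )
        lin = (idx[ok, 0] * ny + idx[ok, 1]) * nx + idx[ok, 2]
        np.add.at(flat, lin, w[ok].astype(vol.dtype))


def _render_points(
    shape: tuple[int, int, int],
    xyz_um: np.ndarray,
    peaks: np.ndarray,
    sigma_xy_um: float,
    sigma_z_um: float,
    spacing: tuple[float, float],  # (z_spacing, pixel_size)
) -> np.ndarray:
    """Render point sources as PSF-blurred spots with the requested peak heights."""
    dz, px = spacing
    vol = np.zeros(shape, dtype=np.float32)
    sz, sxy = sigma_z_um / dz, sigma_xy_um / px
    if len(xyz_um):
        zyx = np.column_stack(
            [xyz_um[:, 2] / dz, xyz_um[:, 1] / px, xyz_um[:, 0] / px]
        )
        flux = np.asarray(peaks) * (2 * np.pi) ** 1.5 * sz * sxy * sxy
        _deposit_points(vol, zyx, flux)
        # constant boundary: light from sources near the volume edge is lost,
        # not mirrored back (reflection would double their apparent flux)
        ndimage.gaussian_filter(
            vol, sigma=(sz, sxy, sxy), output=vol, truncate=3.5, mode="constant"
        )
    return vol


def _plaque_profiles(
    spec: SceneSpec, shape_yx: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """2D intensity profiles for the plaque channel and the Thio-S channel."""
    ny, nx = shape_yx
    px = spec.pixel_size_um
    plaque = np.zeros((ny, nx), dtype=np.float32)
    thios = np.zeros((ny, nx), dtype=np.float32)
    for p in spec.plaque_specs:
        # evaluate only inside a bounding box around the plaque
        pad = p.radius_um + 8.0
        x0 = max(int((p.center_um[0] - pad) / px), 0)
        x1 = min(int((p.center_um[0] + pad) / px) + 1, nx)
        y0 = max(int((p.center_um[1] - pad) / px), 0)
        y1 = min(int((p.center_um[1] + pad) / px) + 1, ny)
        xs = (np.arange(x0, x1) + 0.5) * px
        ys = (np.arange(y0, y1) + 0.5) * px
        xg, yg = np.meshgrid(xs, ys)
        r = np.hypot(xg - p.center_um[0], yg - p.center_um[1])
        if p.plaque_class == "diffuse":
            plaque[y0:y1, x0:x1] += 30.0 * 0.5 * (1.0 - np.tanh((r - p.radius_um) / 2.0))
        else:
            plaque[y0:y1, x0:x1] += 35.0 * 0.5 * (1.0 - np.tanh((r - p.radius_um) / 0.7))
            core = 70.0 * 0.5 * (1.0 - np.tanh((r - p.core_radius_um) / 0.5))
            plaque[y0:y1, x0:x1] += core
            thios[y0:y1, x0:x1] += core
    return plaque, thios


def _finish_channel(img: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    img = np.asarray(img, np.float32)
    img += np.float32(noise.background)
    if noise.poisson:
        img = rng.poisson(np.maximum(img, 0)).astype(np.float32)
    if noise.gaussian_sigma > 0:
        g = rng.standard_normal(img.shape, dtype=np.float32)
        g *= np.float32(noise.gaussian_sigma)
        img += g
    np.maximum(img, np.float32(0.0), out=img)
    return img


# ---------------------------------------------------------------------------
# point-process sampling


def _factor_lut(spec: SceneSpec, factor_of_label: Callable[[str], float]) -> np.ndarray:
    """Per-region multipliers indexed by region code + 1 (plaque, bins…, far)."""
    labels = [PLAQUE_LABEL] + spec.scheme.bin_labels + [FAR_LABEL]
    return np.array([factor_of_label(l) for l in labels], dtype=float)


def _sample_thinned_2d(
    rng: np.random.Generator,
    spec: SceneSpec,
    base_density: float,  # per µm²
    factor_of_label: Callable[[str], float],
) -> np.ndarray:
    """Inhomogeneous 2D Poisson points via thinning of a homogeneous process."""
    lut = _factor_lut(spec, factor_of_label)
    fmax = float(lut.max())
    if base_density <= 0 or fmax <= 0:
        return np.empty((0, 2))
    fx, fy = spec.field_size_um
    n = rng.poisson(base_density * fmax * fx * fy)
    pts = np.column_stack([rng.uniform(0, fx, n), rng.uniform(0, fy, n)])
    codes = _region_codes(pts, spec.plaque_specs, spec.scheme)
    f = lut[codes + 1] / fmax
    return pts[rng.uniform(size=n) < f]


def _sample_synapse_points(
    rng: np.random.Generator, spec: SceneSpec
) -> pd.DataFrame:
    """Paired and unpaired puncta records for both synaptic channels."""
    sp = spec.synapse_profile
    span = spec.axial_span_um
    pair_xy = _sample_thinned_2d(
        rng, spec, sp.baseline_pair_density_per_um3 * span, sp.factor
    )
    n_pairs = len(pair_xy)
    pre = np.column_stack([pair_xy, rng.uniform(0, span, n_pairs)])
    # partner offset: uniform in a ball of the pairing radius
    u = rng.normal(size=(n_pairs, 3))
    u /= np.maximum(np.linalg.norm(u, axis=1, keepdims=True), 1e-12)
    radii = sp.pairing_radius_um * rng.uniform(size=n_pairs) ** (1 / 3)
    post = pre + u * radii[:, None]
    frames = [
        pd.DataFrame(
            {
                "channel": ch,
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "z_um": pts[:, 2],
                "paired": True,
                "pair_id": np.arange(n_pairs),
            }
        )
        for ch, pts in (("pre", pre), ("post", post))
    ]
    # unpaired puncta, per channel
    if sp.unpaired_fraction > 0:
        u_density = (
            sp.baseline_pair_density_per_um3
            * span
            * sp.unpaired_fraction
            / (1 - sp.unpaired_fraction)
        )
        for ch in ("pre", "post"):
            xy = _sample_thinned_2d(rng, spec, u_density, sp.factor)
            frames.append(
                pd.DataFrame(
                    {
                        "channel": ch,
                        "x_um": xy[:, 0],
                        "y_um": xy[:, 1],
                        "z_um": rng.uniform(0, span, len(xy)),
                        "paired": False,
                        "pair_id": -1,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.astype({"x_um": float, "y_um": float, "z_um": float})


def _sample_glia(rng: np.random.Generator, spec: SceneSpec) -> pd.DataFrame:
    gp = spec.glia_profile
    span = spec.axial_span_um
    soma_xy = _sample_thinned_2d(
        rng, spec, gp.soma_density_per_um2, lambda l: gp.gains(l)[0]
    )
    n = len(soma_xy)
    z = rng.uniform(0.2 * span, 0.8 * span, n)
    jitter = rng.normal(0, 0.5, (n, 2))
    labs = region_labels(soma_xy, spec.plaque_specs, spec.scheme)
    return pd.DataFrame(
        {
            "x_um": soma_xy[:, 0],
            "y_um": soma_xy[:, 1],
            "z_um": z,
            "nucleus_x_um": soma_xy[:, 0] + jitter[:, 0],
            "nucleus_y_um": soma_xy[:, 1] + jitter[:, 1],
            "bin_label": labs,
        }
    )


# ---------------------------------------------------------------------------
# ground truth assembly


def _bin_truth_synapse(spec: SceneSpec, puncta: pd.DataFrame) -> pd.DataFrame:
    areas = _pixel_region_areas(spec)
    span = spec.axial_span_um
    pairs = puncta[(puncta.channel == "pre") & puncta.paired]
    if len(pairs):
        labs = region_labels(
            pairs[["x_um", "y_um"]].to_numpy(), spec.plaque_specs, spec.scheme
        )
        counts = pd.Series(labs).value_counts()
    else:
        counts = pd.Series(dtype=int)
    out = areas.copy()
    out["volume_um3"] = out.area_um2 * span
    out["pair_count"] = out.bin_label.map(counts).fillna(0).astype(int)
    out["density_per_um3"] = out.pair_count / out.volume_um3
    return out


def _bin_truth_glia(spec: SceneSpec, glia: pd.DataFrame) -> pd.DataFrame:
    areas = _pixel_region_areas(spec)
    counts = glia.bin_label.value_counts() if len(glia) else pd.Series(dtype=int)
    out = areas.copy()
    out["soma_count"] = out.bin_label.map(counts).fillna(0).astype(int)
    out["density_per_um2"] = out.soma_count / out.area_um2
    return out


# ---------------------------------------------------------------------------
# public API


def generate_stack(spec: SceneSpec) -> tuple[ImageStack3D, GroundTruth]:
    """Render one field described by ``spec``; returns the stack and its truth."""
    rng = np.random.default_rng(spec.rng_seed)
    px, dz = spec.pixel_size_um, spec.z_spacing_um
    nx = int(round(spec.field_size_um[0] / px))
    ny = int(round(spec.field_size_um[1] / px))
    nz = spec.n_planes
    shape = (nz, ny, nx)
    channels = spec.channel_names
    vox = np.zeros((len(channels),) + shape, dtype=np.float32)
    plaque2d, thios2d = _plaque_profiles(spec, (ny, nx))

    puncta = pd.DataFrame(columns=["channel", "x_um", "y_um", "z_um", "paired", "pair_id"])
    glia = pd.DataFrame(
        columns=["x_um", "y_um", "z_um", "nucleus_x_um", "nucleus_y_um", "bin_label"]
    )

    if spec.acquisition_mode == "synapse":
        puncta = _sample_synapse_points(rng, spec)
        sp = spec.synapse_profile
        for ci, ch in enumerate(("pre", "post")):
            sub = puncta[puncta.channel == ch]
            peaks = sp.peak_intensity * rng.lognormal(0.0, 0.2, len(sub))
            vox[ci] = _render_points(
                shape,
                sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                peaks,
                spec.psf_sigma_xy_um,
                spec.psf_sigma_z_um,
                (dz, px),
            )
        vox[2] = plaque2d[None, :, :]
        bin_truth = _bin_truth_synapse(spec, puncta)
    else:
        gp = spec.glia_profile
        glia = _sample_glia(rng, spec)
        gains = np.array([gp.gains(l) for l in glia.bin_label]) if len(glia) else np.zeros((0, 3))
        soma_xyz = glia[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        inten = gains[:, 2] if len(glia) else np.empty(0)
        # somata: wide blobs (PSF negligible at this scale)
        vox[0] = _render_points(
            shape, soma_xyz, gp.soma_peak * inten, gp.soma_sigma_um, gp.soma_sigma_um,
            (dz, px),
        )
        # processes: random-walk strokes of small stamps from each soma
        stroke_pts, stroke_peaks = [], []
        n_steps = max(int(round(gp.process_length_um / gp.process_step_um)), 1)
        for i in range(len(glia)):
            n_strokes = rng.poisson(gp.processes_per_cell * gains[i, 1])
            for _ in range(n_strokes):
                theta = rng.uniform(0, 2 * np.pi)
                pos = soma_xyz[i].copy()
                for _ in range(n_steps):
                    theta += rng.normal(0, 0.45)
                    pos = pos + np.array(
                        [
                            np.cos(theta) * gp.process_step_um,
                            np.sin(theta) * gp.process_step_um,
                            rng.normal(0, 0.25),
                        ]
                    )
                    stroke_pts.append(pos)
                    stroke_peaks.append(gp.process_peak * gains[i, 2])
        if stroke_pts:
            vox[0] += _render_points(
                shape, np.array(stroke_pts), np.array(stroke_peaks), 0.5, 0.8, (dz, px)
            )
        # nuclear channel: glial nuclei + unrelated background nuclei
        nuc_xyz = np.column_stack(
            [glia.nucleus_x_um, glia.nucleus_y_um, glia.z_um]
        ) if len(glia) else np.empty((0, 3))
        fx, fy = spec.field_size_um
        n_bg = rng.poisson(gp.background_nuclei_per_um2 * fx * fy)
        bg = np.column_stack(
            [
                rng.uniform(0, fx, n_bg),
                rng.uniform(0, fy, n_bg),
                rng.uniform(0.2 * spec.axial_span_um, 0.8 * spec.axial_span_um, n_bg),
            ]
        )
        all_nuc = np.vstack([nuc_xyz, bg])
        vox[1] = _render_points(
            shape,
            all_nuc,
            np.full(len(all_nuc), gp.nucleus_peak),
            gp.nucleus_sigma_um,
            gp.nucleus_sigma_um,
            (dz, px),
        )
        vox[2] = plaque2d[None, :, :]
        vox[3] = thios2d[None, :, :]
        bin_truth = _bin_truth_glia(spec, glia)

    for ci in range(len(channels)):
        vox[ci] = _finish_channel(vox[ci], spec.noise, rng)

    stack = ImageStack3D(
        voxels=vox,
        pixel_size_um=px,
        z_spacing_um=dz,
        channel_roles={ch: i for i, ch in enumerate(channels)},
    )
    plaques_df = pd.DataFrame(
        [
            {
                "x_um": p.center_um[0],
                "y_um": p.center_um[1],
                "radius_um": p.radius_um,
                "core_radius_um": p.core_radius_um,
                "plaque_class": p.plaque_class,
            }
            for p in spec.plaque_specs
        ]
    )
    truth = GroundTruth(
        mode=spec.acquisition_mode,
        scheme_name=spec.scheme.name,
        plaques=plaques_df,
        puncta=puncta,
        glia=glia,
        bin_truth=bin_truth,
    )
    return stack, truth


def stack_seed(seed: int, genotype_idx: int, animal: int, slice_idx: int, image_idx: int) -> int:
    """Deterministic per-stack seed derived from the cohort seed and nesting."""
    ss = np.random.SeedSequence([seed, genotype_idx, animal, slice_idx, image_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def iter_cohort(
    wt_spec: SceneSpec,
    tg_spec: SceneSpec,
    n_per_group: int,
    seed: int,
    n_slices: int = 2,
    n_images_per_slice: int = 3,
    age_label: str = "5mo",
    mutate: Callable[[SceneSpec, dict, np.random.Generator], SceneSpec] | None = None,
) -> Iterator[tuple[dict, ImageStack3D, GroundTruth]]:
    """Yield (meta, stack, truth) per image for a two-genotype cohort.

    Nesting mirrors the experimental design: per animal, ``n_slices`` brain
    slices with ``n_images_per_slice`` fields each.  ``mutate`` may adjust the
    base spec per image (e.g. to vary plaque size or class) using the image's
    own RNG stream.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for g_idx, (genotype, base) in enumerate([("WT", wt_spec), ("NLGF", tg_spec)]):
        for a in range(n_per_group):
            for s in range(n_slices):
                for i in range(n_images_per_slice):
                    sd = stack_seed(seed, g_idx, a, s, i)
                    spec = replace(base, rng_seed=sd)
                    meta = {
                        "animal": f"{genotype}{a + 1}",
                        "genotype": genotype,
                        "age": age_label,
                        "slice": s + 1,
                        "image": i + 1,
                    }
                    if mutate is not None:
                        spec = mutate(spec, meta, np.random.default_rng(sd + 1))
                    stack, truth = generate_stack(spec)
                    yield meta, stack, truth


def generate_cohort(
    wt_spec: SceneSpec,
    tg_spec: SceneSpec,
    n_per_group: int,
    seed: int,
    out_dir,
    **kwargs,
) -> pd.DataFrame:
    """Write a cohort to disk (TIFF stacks + truth tables) and return its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, stack, truth in iter_cohort(wt_spec, tg_spec, n_per_group, seed, **kwargs):
        stem = f"{meta['animal']}_s{meta['slice']}_i{meta['image']}"
        path = out_dir / f"{stem}.tif"
        write_stack(stack, path)
        truth.write(out_dir / "truth", stem)
        rows.append({**meta, "path": str(path)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
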