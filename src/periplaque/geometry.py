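"""Stack I/O, unit conversion, projections, and plaque-centric distance binning.

Physical conventions
--------------------
Coordinates are 0-based voxel indices; physical positions sit at voxel
centers.  The axial extent of a stack follows the span convention
``(n_planes - 1) * z_spacing``: 9 planes spaced 0.25 µm apart span 2.0 µm,
which is the depth that makes a 10 µm × 10 µm crop a 200 µm³ volume.

Distance binning
----------------
All proximity metrics are expressed in concentric shells ("annuli")
measured from the *border* of an amyloid plaque, not its centroid, so the
scheme generalizes to irregular plaque outlines via the Euclidean distance
transform.  Bins are half-open ``(lo, hi]``: a point exactly on an edge
belongs to the inner bin, consistent with the cell-counting tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

# label codes used in bin maps
EXCLUDED = -3   # inside another plaque's mask
OUTSIDE = -2    # beyond the outermost bin edge
IN_PLAQUE = -1  # inside the focal plaque mask
PLAQUE_LABEL = "plaque"


class StackReadError(RuntimeError):
    """Raised when a stack file cannot be read or lacks required metadata."""


@dataclass
class ImageStack3D:
    """Multi-channel 3D fluorescence stack with physical voxel spacing.

    ``voxels`` is (channel, z, y, x); ``channel_roles`` maps a biological
    role ("plaque", "pre", "post", "glia", "nuclear", "thioS", ...) to a
    channel index.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channel, z, y, x); got shape {self.voxels.shape}"
            )
        if not (self.pixel_size_um > 0 and self.z_spacing_um > 0):
            raise ValueError("voxel spacings must be positive")
        n_ch = self.voxels.shape[0]
        for role, idx in self.channel_roles.items():
            if not (0 <= idx < n_ch):
                raise ValueError(
                    f"role {role!r} maps to channel {idx}, but stack has {n_ch} channels"
                )

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    @property
    def axial_extent_um(self) -> float:
        """Depth spanned by the planes: (n_planes - 1) * z_spacing."""
        return (self.n_planes - 1) * self.z_spacing_um

    def channel(self, role: str) -> np.ndarray:
        """The (z, y, x) volume for a configured channel role."""
        if role not in self.channel_roles:
            raise KeyError(
                f"channel role {role!r} not configured; available: "
                f"{sorted(self.channel_roles)}"
            )
        return self.voxels[self.channel_roles[role]]


def write_stack(stack: ImageStack3D, path) -> None:
    """Write a multi-channel TIFF with spacing/role metadata in the description tag."""
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_spacing_um": stack.z_spacing_um,
        "channel_roles": stack.channel_roles,
    }
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(path, config: dict | None = None) -> ImageStack3D:
    """Read a stack written by :func:`write_stack` (or any plain TIFF plus config).

    ``config`` may supply/override ``pixel_size_um``, ``z_spacing_um`` and
    ``channel_roles`` when the file metadata lacks them.
    """
    config = config or {}
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackReadError(f"cannot read TIFF {path}: {exc}") from exc
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            pass
    if arr.ndim == 3:  # single channel
        arr = arr[None]
    if arr.ndim != 4:
        raise StackReadError(f"{path}: expected a (channel, z, y, x) stack, got {arr.shape}")
    merged = {**meta, **config}
    for key in ("pixel_size_um", "z_spacing_um"):
        if key not in merged:
            raise StackReadError(f"{path}: missing required metadata field {key!r}")
        if not merged[key] > 0:
            raise StackReadError(f"{path}: {key} must be positive, got {merged[key]}")
    roles = {str(k): int(v) for k, v in merged.get("channel_roles", {}).items()}
    return ImageStack3D(
        voxels=arr,
        pixel_size_um=float(merged["pixel_size_um"]),
        z_spacing_um=float(merged["z_spacing_um"]),
        channel_roles=roles,
    )


def max_project(stack: ImageStack3D, role: str) -> np.ndarray:
    """Maximum-intensity projection of a channel over z → 2D (y, x) image."""
    return stack.channel(role).max(axis=0)


@dataclass(frozen=True)
class DistanceBinScheme:
    """Ordered radial bins in µm from the plaque border, plus the in-plaque region.

    ``edges`` are strictly increasing distances; bin *k* collects points with
    ``edges[k] < d <= edges[k+1]``.  ``include_in_plaque`` states whether the
    plaque interior participates as its own (innermost) region, as it does for
    the glial metrics ("within plaques") but not for the synapse crops.
    """

    name: str
    edges: tuple[float, ...]
    include_in_plaque: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0) or e[0] < 0:
            raise ValueError(f"edges must be increasing and non-negative: {self.edges}")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def bin_labels(self) -> list[str]:
        fmt = lambda v: f"{v:g}"
        return [
            f"{fmt(self.edges[k])}-{fmt(self.edges[k + 1])}" for k in range(self.n_bins)
        ]

    @property
    def labels(self) -> list[str]:
        """All region labels in inner→outer order (plaque first when included)."""
        base = self.bin_labels
        return ([PLAQUE_LABEL] + base) if self.include_in_plaque else base

    def bin_of_distance(self, d: float) -> int | None:
        """Bin index for a border distance d (µm); None when outside every bin."""
        for k in range(self.n_bins):
            if self.edges[k] < d <= self.edges[k + 1]:
                return k
        return None


#: presets matching the published quantification conventions
SCHEMES: dict[str, DistanceBinScheme] = {
    # microglia: within the plaque then 10 µm shells to 50 µm
    "microglia_10um": DistanceBinScheme("microglia_10um", (0, 10, 20, 30, 40, 50), True),
    # astrocytes are larger cells: 25 µm shells for counting
    "astrocyte_25um": DistanceBinScheme("astrocyte_25um", (0, 25, 50), True),
    # excitatory synapse crops start at the plaque border
    "synapse_excitatory": DistanceBinScheme("synapse_excitatory", (0, 10, 20, 30, 40, 50), False),
    # inhibitory crops start at 10 µm (LAMP1/vGAT co-aggregation near the border)
    "synapse_inhibitory": DistanceBinScheme("synapse_inhibitory", (10, 20, 30, 40, 50), False),
}


def get_scheme(name: str) -> DistanceBinScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown bin scheme {name!r}; presets: {sorted(SCHEMES)}") from None


def border_distance_map(plaque_mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Euclidean distance (µm) of every outside pixel to the plaque border.

    Pixels inside the mask get distance 0.  Half a pixel is subtracted from
    the distance transform so that distances refer to the geometric mask edge
    rather than the centers of the outermost mask pixels; without this the
    pixel-count areas of thin annuli are biased outward by ~pixel_size/2.
    """
    plaque_mask = np.asarray(plaque_mask, bool)
    if not plaque_mask.any():
        raise ValueError("plaque mask is empty")
    d = ndimage.distance_transform_edt(~plaque_mask, sampling=pixel_size_um)
    np.subtract(d, 0.5 * pixel_size_um, out=d, where=~plaque_mask)
    np.maximum(d, 0.0, out=d)
    d[~plaque_mask & (d == 0.0)] = 1e-9  # adjacent pixels belong to the first bin
    return d


def make_distance_bins(
    plaque_mask: np.ndarray,
    scheme: DistanceBinScheme,
    pixel_size_um: float,
    exclude_masks: np.ndarray | None = None,
) -> np.ndarray:
    """Label every pixel with its distance bin around a plaque.

    Returns an int map: bin index ``0..n_bins-1``, or the codes
    :data:`IN_PLAQUE`, :data:`OUTSIDE`, :data:`EXCLUDED` (other plaques).
    Together these partition the image.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    plaque_mask = np.asarray(plaque_mask, bool)
    d = border_distance_map(plaque_mask, pixel_size_um)
    out = np.full(plaque_mask.shape, OUTSIDE, dtype=np.int16)
    for k in range(scheme.n_bins):
        out[(d > scheme.edges[k]) & (d <= scheme.edges[k + 1])] = k
    out[plaque_mask] = IN_PLAQUE
    if exclude_masks is not None:
        out[np.asarray(exclude_masks, bool) & ~plaque_mask] = EXCLUDED
    return out


def bin_region_table(
    bin_map: np.ndarray, scheme: DistanceBinScheme, pixel_size_um: float
) -> pd.DataFrame:
    """Per-region pixel counts and areas (µm²) for a bin map.

    ``clipped`` flags regions that touch the image border, i.e. annuli whose
    full extent did not fit in the field of view; their areas are the
    *available* areas and densities computed from them remain well defined.
    """
    px_area = pixel_size_um**2
    border = np.zeros(bin_map.shape, bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    rows = []
    codes = ([IN_PLAQUE] if scheme.include_in_plaque else []) + list(range(scheme.n_bins))
    labels = scheme.labels
    for label, code in zip(labels, codes):
        sel = bin_map == code
        n = int(sel.sum())
        rows.append(
            {
                "bin_label": label,
                "code": code,
                "n_pixels": n,
                "area_um2": n * px_area,
                "clipped": bool((sel & border).any()),
            }
        )
    return pd.DataFrame(rows)


def reference_plaque(
    image_shape: tuple[int, int], radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Centered disc mask used as a stand-in plaque for plaque-free images.

    Wild-type and pre-plaque-age images carry no plaque; a centrally placed
    reference disc lets the identical binning code run on every group.
    A radius of 0 degenerates to a single center pixel.
    """
    h, w = image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    r_px = radius_um / pixel_size_um
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= max(r_px, 1e-9) ** 2
    if not mask.any():
        mask[int(round(cy)), int(round(cx))] = True
    return mask


def annulus_area_um2(plaque_radius_um: float, lo: float, hi: float) -> float:
    """Closed-form area of the (lo, hi] shell around a disc plaque."""
    r = plaque_radius_um
    return float(np.pi * ((r + hi) ** 2 - (r + lo) ** 2))
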