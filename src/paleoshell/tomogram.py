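"""Metrics on labelled μCT voxel volumes.

Inputs are already-segmented volumes with labels {background, test, lumen,
debris, standard} on an isotropic grid (default 1.2 μm voxels), optionally
paired with the raw grey-value volume for CT-number standardisation.

Surface areas are measured on a marching-cubes iso-surface, not by counting
voxel faces: face counting overestimates the area of smooth objects by about
50%, which would bias any V/SA thickness estimate by the same factor. The
"potential specimen volume" (shell plus sealed interior, as if the chambers
were filled with protoplasm) is approximated by morphological closing of the
test mask followed by hole filling — a phantom-validated stand-in for the
ambient-occlusion construction used interactively in commercial software.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Label",
    "LabelVolume",
    "CTNumberResult",
    "PotentialVolumeResult",
    "component_volumes",
    "mesh_surface_area",
    "voxel_face_area",
    "potential_volume_closing",
    "normalize_ct_number",
    "debris_percent",
    "read_label_volume",
    "export_mesh_ply",
]

DEFAULT_VOXEL_SIZE_UM = 1.2
CT_STANDARD_REFERENCE = 1000.0  # mapped grey value of the calcite standard


class Label(IntEnum):
    BACKGROUND = 0
    TEST = 1  # calcite shell
    LUMEN = 2  # internal cavity / biovolume
    DEBRIS = 3  # sedimentary infill
    STANDARD = 4  # co-scanned calcite microcrystal


@dataclass
class LabelVolume:
    """A labelled voxel grid with isotropic spacing, optionally with raw grey values."""

    voxels: np.ndarray  # 3D integer label grid
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM  # μm
    raw_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        valid = {int(v) for v in Label}
        present = set(np.unique(self.voxels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown labels present: {sorted(present - valid)}")
        if self.raw_intensity is not None:
            self.raw_intensity = np.asarray(self.raw_intensity, dtype=float)
            if self.raw_intensity.shape != self.voxels.shape:
                raise ValueError("raw_intensity shape must match voxels")

    def mask(self, label: Label) -> np.ndarray:
        return self.voxels == int(label)


@dataclass
class CTNumberResult:
    """Standardised CT number of a specimen."""

    mean_ct: float
    standard_mean: float  # raw grey value of the calcite standard
    background_mean: float
    slope: float  # mapping: ct = slope * raw + offset
    offset: float


@dataclass
class PotentialVolumeResult:
    volume: float  # μm³
    sealed: bool  # hole filling captured an interior cavity


def component_volumes(volume: LabelVolume) -> dict[Label, float]:
    """Voxel-count volume (μm³) per label present in the grid."""
    if not volume.mask(Label.TEST).any():
        raise ValueError("empty test label: nothing segmented as shell")
    v3 = volume.voxel_size**3
    out: dict[Label, float] = {}
    for label in Label:
        n = int(np.count_nonzero(volume.voxels == int(label)))
        if n:
            out[label] = n * v3
    return out


def _padded_mask(volume: LabelVolume, label: Label) -> np.ndarray:
    mask = volume.mask(label)
    if not mask.any():
        raise ValueError(f"label {label.name} absent from volume")
    return np.pad(mask, 1)


def _label_mesh(volume: LabelVolume, label: Label, smooth_sigma: float):
    mask = _padded_mask(volume, label).astype(float)
    if smooth_sigma > 0:
        mask = ndimage.gaussian_filter(mask, smooth_sigma)
    s = volume.voxel_size
    return measure.marching_cubes(mask, level=0.5, spacing=(s, s, s))


def mesh_surface_area(
    volume: LabelVolume, label: Label = Label.TEST, smooth_sigma: float = 1.0
) -> float:
    """Iso-surface area (μm²) of a label's boundary, inner and outer faces.

    Marching cubes at the 0.5 level of the mask, Gaussian-smoothed by
    ``smooth_sigma`` voxels first to suppress the staircase bias of a raw
    binary surface (≈9% high on a digitised sphere; ≲0.5% after smoothing).
    Features thinner than about three voxels would be eroded by the
    smoothing — wall thicknesses here are required to span several voxels.
    For hollow objects the area includes both the outer boundary and the
    cavity wall.
    """
    verts, faces, _, _ = _label_mesh(volume, label, smooth_sigma)
    return float(measure.mesh_surface_area(verts, faces))


def voxel_face_area(volume: LabelVolume, label: Label = Label.TEST) -> float:
    """Exposed-voxel-face area (μm²). Biased high by ~1.5× on smooth objects.

    Kept only as a cross-check on the mesh estimator; never reported.
    """
    mask = _padded_mask(volume, label)
    faces = 0
    for axis in range(3):
        diff = np.diff(mask.astype(np.int8), axis=axis)
        faces += int(np.count_nonzero(diff))
    return faces * volume.voxel_size**2


def potential_volume_closing(
    volume: LabelVolume, closing_radius: float = 15.0
) -> PotentialVolumeResult:
    """Potential specimen volume (μm³): test + sealed interior.

    The test mask is morphologically closed with a ball of ``closing_radius``
    μm (sealing apertures narrower than twice the radius) and interior holes
    are filled. The closing is computed with Euclidean distance transforms
    (dilation = distance-to-mask ≤ r, then the matching erosion), which is
    exact for a ball structuring element and fast for large radii. ``sealed``
    is False when the closing captured no interior cavity — either the object
    is solid or the aperture is wider than the ball, in which case the
    returned volume underestimates the true enclosed volume.
    """
    if closing_radius < volume.voxel_size:
        raise ValueError("closing_radius must be at least one voxel")
    if not volume.mask(Label.TEST).any():
        raise ValueError("empty test label")
    mask = volume.mask(Label.TEST)
    r_vox = closing_radius / volume.voxel_size
    pad = int(np.ceil(r_vox)) + 2
    padded = np.pad(mask, pad)
    dilated = ndimage.distance_transform_edt(~padded) <= r_vox
    closed = padded | (ndimage.distance_transform_edt(dilated) > r_vox)
    filled = ndimage.binary_fill_holes(closed)
    # sealed ⇔ hole filling found a cavity disconnected from the outside,
    # i.e. the closing actually bridged every aperture
    sealed = bool(np.any(filled & ~closed))
    return PotentialVolumeResult(
        volume=float(np.count_nonzero(filled)) * volume.voxel_size**3,
        sealed=sealed,
    )


def normalize_ct_number(
    volume: LabelVolume, standard_reference: float = CT_STANDARD_REFERENCE
) -> CTNumberResult:
    """Standardised CT number over test voxels.

    The raw grey values are mapped by the linear transformation sending the
    background mean to 0 and the co-scanned calcite-standard mean to
    ``standard_reference``. Invariant under any affine rescaling of the raw
    intensities, so scans from different acquisitions become comparable.
    """
    if volume.raw_intensity is None:
        raise ValueError("raw_intensity required for CT-number standardisation")
    if not volume.mask(Label.STANDARD).any():
        raise ValueError("no calcite standard in scan")
    bg = float(volume.raw_intensity[volume.mask(Label.BACKGROUND)].mean())
    std = float(volume.raw_intensity[volume.mask(Label.STANDARD)].mean())
    if std <= bg:
        raise ValueError("standard mean grey value must exceed background")
    slope = standard_reference / (std - bg)
    offset = -slope * bg
    test_mean = float(volume.raw_intensity[volume.mask(Label.TEST)].mean())
    return CTNumberResult(
        mean_ct=slope * test_mean + offset,
        standard_mean=std,
        background_mean=bg,
        slope=slope,
        offset=offset,
    )


def debris_percent(volume: LabelVolume) -> float:
    """Sedimentary-infill volume as % of the calcite test volume."""
    test = int(np.count_nonzero(volume.mask(Label.TEST)))
    if test == 0:
        raise ValueError("empty test label")
    debris = int(np.count_nonzero(volume.mask(Label.DEBRIS)))
    return 100.0 * debris / test


def read_label_volume(
    path, voxel_size: float = DEFAULT_VOXEL_SIZE_UM, raw_path=None
) -> LabelVolume:
    """Read a labelled TIFF stack (and optional raw grey-value stack)."""
    import tifffile

    labels = tifffile.imread(path)
    raw = tifffile.imread(raw_path) if raw_path is not None else None
    return LabelVolume(voxels=labels, voxel_size=voxel_size, raw_intensity=raw)


def export_mesh_ply(volume: LabelVolume, label: Label, path, smooth_sigma: float = 1.0) -> None:
    """Export the label's iso-surface as a PLY mesh for inspection."""
    import trimesh

    verts, faces, _, _ = _label_mesh(volume, label, smooth_sigma)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(path)
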