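"""Two-dimensional rectangular universal coordinate system for an articular surface.

Each articular surface (distal lateral femur, proximal lateral tibia) gets its
own rectangular (u, v) frame:

* ``v`` runs medial (0) to lateral (1) across sagittal slices, anchored at the
  most medial and most lateral slices containing bone;
* ``u`` runs anterior (0) to posterior (1) along the bone-cartilage boundary of
  a single slice, normalized per slice by that slice's own anterior/posterior
  boundary extremes.

Volumes are stacks of sagittal slices indexed ``(slice, row, col)``; the slice
axis is oriented medial-to-lateral and the in-slice column axis
anterior-to-posterior, with row index increasing inferiorly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = 0
BONE = 1
CARTILAGE = 2

FEMUR = "femur"
TIBIA = "tibia"
SURFACES = (FEMUR, TIBIA)


class EmptyVolumeError(ValueError):
    """No bone voxels where bone is required."""


class DegenerateExtentError(ValueError):
    """Bone confined to a single slice: no medial-lateral axis."""


class DegenerateBoundaryError(ValueError):
    """Bone-cartilage boundary too short to define a frame."""


class OffSurfaceError(ValueError):
    """Requested point falls outside the surface's boundary extent."""


@dataclass(frozen=True)
class LabelVolume:
    """A 3D voxel grid of tissue labels with anisotropic spacing.

    Parameters
    ----------
    labels
        Integer array of shape ``(n_slices, n_rows, n_cols)`` with codes
        0 = background, 1 = bone, 2 = cartilage (denudation masks use 0/1).
    spacing
        ``(dx_mm, dy_mm, dz_mm)``: column (anterior-posterior), row
        (superior-inferior) and slice (medial-lateral) spacing in mm.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (slice, row, col) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.labels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[2]

    @property
    def dx(self) -> float:
        return self.spacing[0]

    @property
    def dy(self) -> float:
        return self.spacing[1]

    @property
    def dz(self) -> float:
        return self.spacing[2]

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI with voxel spacing in the header (axes slice,row,col)."""
        affine = np.diag([self.dz, self.dy, self.dx, 1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        img.header.set_zooms((self.dz, self.dy, self.dx))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "LabelVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        labels = np.asarray(img.dataobj).astype(np.int16)
        return cls(labels=labels, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])))


@dataclass(frozen=True)
class Boundary:
    """Ordered bone-cartilage boundary of one slice, anterior to posterior."""

    cols: np.ndarray  # strictly increasing column indices
    rows: np.ndarray  # bone-surface row per column

    def __post_init__(self) -> None:
        if len(self.cols) != len(self.rows):
            raise ValueError("cols and rows must have equal length")
        if len(self.cols) < 3:
            raise DegenerateBoundaryError("degenerate boundary")
        if not np.all(np.diff(self.cols) > 0):
            raise ValueError("boundary columns must be strictly increasing")

    @property
    def anterior_col(self) -> int:
        return int(self.cols[0])

    @property
    def posterior_col(self) -> int:
        return int(self.cols[-1])


@dataclass
class SurfaceFrame:
    """Universal coordinate frame of one articular surface.

    ``boundaries`` maps slice index -> :class:`Boundary` for every slice in
    ``[medial_slice, lateral_slice]`` that has a usable boundary.
    """

    surface: str
    medial_slice: int
    lateral_slice: int
    boundaries: dict[int, Boundary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lateral_slice <= self.medial_slice:
            raise DegenerateExtentError("degenerate medial-lateral extent")
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "surface": self.surface,
            "medial_slice": self.medial_slice,
            "lateral_slice": self.lateral_slice,
            "boundaries": {
                str(s): {"cols": b.cols.tolist(), "rows": b.rows.tolist()}
                for s, b in self.boundaries.items()
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurfaceFrame":
        payload = json.loads(Path(path).read_text())
        boundaries = {
            int(s): Boundary(np.asarray(d["cols"]), np.asarray(d["rows"]))
            for s, d in payload["boundaries"].items()
        }
        return cls(
            surface=payload["surface"],
            medial_slice=payload["medial_slice"],
            lateral_slice=payload["lateral_slice"],
            boundaries=boundaries,
        )


def find_bounding_slices(
    volume: LabelVolume, min_bone_voxels: int = 1
) -> tuple[int, int]:
    """Most medial and most lateral slices possessing bone.

    A slice "possesses bone" when it contains at least ``min_bone_voxels``
    bone-labelled voxels; the threshold guards against stray labels.
    """
    counts = (volume.labels == BONE).sum(axis=(1, 2))
    idx = np.flatnonzero(counts >= min_bone_voxels)
    if idx.size == 0:
        raise EmptyVolumeError("empty volume")
    medial, lateral = int(idx[0]), int(idx[-1])
    if medial == lateral:
        raise DegenerateExtentError("degenerate medial-lateral extent")
    return medial, lateral


def slice_for_v(v: float, frame: SurfaceFrame) -> int:
    """Slice index for a medial-lateral coordinate v in [0, 1].

    Rounds half-toward-lateral (ties go to the larger slice index).
    """
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"v={v} outside [0, 1]")
    span = frame.lateral_slice - frame.medial_slice
    return int(np.floor(frame.medial_slice + v * span + 0.5))


def v_for_slice(slice_index: int, frame: SurfaceFrame) -> float:
    """Inverse of :func:`slice_for_v` up to half a slice step."""
    span = frame.lateral_slice - frame.medial_slice
    return (slice_index - frame.medial_slice) / span


def extract_boundary(
    volume: LabelVolume, slice_index: int, surface: str
) -> Boundary:
    """Bone-cartilage boundary of one sagittal slice.

    For every column with bone, takes the bone voxel facing the articular
    side — superior (minimum row) for the tibia, inferior (maximum row) for
    the femur — and keeps the largest contiguous column run.
    """
    if surface not in SURFACES:
        raise ValueError(f"unknown surface {surface!r}")
    sl = volume.labels[slice_index]
    bone = sl == BONE
    has_bone = bone.any(axis=0)
    cols = np.flatnonzero(has_bone)
    if cols.size == 0:
        raise EmptyVolumeError(f"no bone in slice {slice_index}")
    # largest contiguous run of columns; first run wins ties (more anterior)
    breaks = np.flatnonzero(np.diff(cols) > 1)
    runs = np.split(cols, breaks + 1)
    cols = max(runs, key=len)
    if surface == TIBIA:
        rows = np.argmax(bone[:, cols], axis=0)  # first bone row from the top
    else:
        rows = volume.n_rows - 1 - np.argmax(bone[::-1, cols], axis=0)
    return Boundary(cols=np.asarray(cols, dtype=int), rows=np.asarray(rows, dtype=int))


def build_surface_frame(
    volume: LabelVolume, surface: str, min_bone_voxels: int = 1
) -> SurfaceFrame:
    """Construct the full frame: bounding slices plus per-slice boundaries."""
    medial, lateral = find_bounding_slices(volume, min_bone_voxels=min_bone_voxels)
    boundaries: dict[int, Boundary] = {}
    for s in range(medial, lateral + 1):
        try:
            boundaries[s] = extract_boundary(volume, s, surface)
        except (EmptyVolumeError, DegenerateBoundaryError):
            continue
    if not boundaries:
        raise EmptyVolumeError("no usable boundaries between bounding slices")
    return SurfaceFrame(
        surface=surface, medial_slice=medial, lateral_slice=lateral, boundaries=boundaries
    )


def u_for_point(col: float, boundary: Boundary) -> float:
    """Anterior-posterior coordinate of a column on one slice's boundary."""
    a, p = boundary.anterior_col, boundary.posterior_col
    if not a <= col <= p:
        raise OffSurfaceError(f"off-surface: column {col} outside [{a}, {p}]")
    return (col - a) / (p - a)


def col_for_u(u: float, boundary: Boundary) -> float:
    """Continuous column coordinate for u in [0, 1] on one slice's boundary."""
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u={u} outside [0, 1]")
    a, p = boundary.anterior_col, boundary.posterior_col
    return a + u * (p - a)
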