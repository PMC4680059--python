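"""Cartilage thickness at informative locations and the height-normalized CDI.

The CDI of one surface is the sum over its informative locations of
``thickness x AP length x medial-lateral factor``, divided by the subject's
height in meters (units mm^3 / m). Thickness is read off the label volume by
casting rays along the local surface normal; the anterior-posterior length is
the physical extent of cartilage-bearing boundary columns inside the
location's partition cell on its slice; the medial-lateral factor defaults to
the slice thickness (0.7 mm), making each contribution a small volume.

Sub-voxel strategy: a single normal ray cannot resolve thickness below the
row spacing (0.456 mm) because the label field is quantized, so a location's
thickness is the mean over a small window of parallel rays at neighboring
boundary columns, where the oblique bone-cartilage interface dephases the
per-column quantization. A location is reported denuded (0.0 mm) when the
majority of its rays step off bone directly into background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import LocationSet
from .coords import (
    BACKGROUND,
    BONE,
    CARTILAGE,
    FEMUR,
    TIBIA,
    Boundary,
    LabelVolume,
    OffSurfaceError,
    SurfaceFrame,
    build_surface_frame,
    col_for_u,
    slice_for_v,
)
from .synthetic import KneeRecord, ThicknessModel

DEFAULT_ML_FACTOR_MM = 0.7  # sagittal slice thickness
DEFAULT_RAY_STEP_MM = 0.05
MAX_THICKNESS_MM = 15.0  # cap against runaway rays through label noise


@dataclass(frozen=True)
class ThicknessMeasurement:
    surface: str
    location: tuple[float, float]
    slice_index: int
    thickness_mm: float
    ap_length_mm: float
    ml_factor_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm < 0 or self.ap_length_mm < 0:
            raise ValueError("thickness and AP length must be >= 0")

    @property
    def contribution_mm3(self) -> float:
        return self.thickness_mm * self.ap_length_mm * self.ml_factor_mm


@dataclass
class CdiResult:
    femur_cdi: float
    tibia_cdi: float
    height_m: float
    measurements: list[ThicknessMeasurement] = field(default_factory=list)

    @property
    def total_cdi(self) -> float:
        return self.femur_cdi + self.tibia_cdi


def _label_at(volume: LabelVolume, slice_index: int, x_mm: float, y_mm: float) -> int:
    col = int(round(x_mm / volume.dx))
    row = int(round(y_mm / volume.dy))
    if 0 <= row < volume.n_rows and 0 <= col < volume.n_cols:
        return int(volume.labels[slice_index, row, col])
    return BACKGROUND


def _normal_at(boundary: Boundary, idx: int, surface: str, dx: float, dy: float,
               halfwidth: int = 3) -> np.ndarray:
    """Unit outward (articular-side) normal from the local boundary tangent."""
    j0 = max(idx - halfwidth, 0)
    j1 = min(idx + halfwidth, len(boundary.cols) - 1)
    tx = (boundary.cols[j1] - boundary.cols[j0]) * dx
    ty = (boundary.rows[j1] - boundary.rows[j0]) * dy
    n = np.array([-ty, tx], dtype=float)
    norm = np.hypot(*n)
    if norm == 0:
        n = np.array([0.0, 1.0])
        norm = 1.0
    n /= norm
    # articular side: superior (y decreasing) for tibia, inferior for femur
    if surface == TIBIA and n[1] > 0:
        n = -n
    if surface == FEMUR and n[1] < 0:
        n = -n
    return n


def _single_ray(
    volume: LabelVolume,
    slice_index: int,
    origin_xy: tuple[float, float],
    normal: np.ndarray,
    ray_step: float,
) -> float | None:
    """Cartilage run length along one normal ray; None means denuded."""
    x0, y0 = origin_xy
    max_steps = int(MAX_THICKNESS_MM / ray_step)
    bone_skip = int(3.0 / ray_step)
    k = 0
    # leave the bone first
    while k <= bone_skip:
        lab = _label_at(volume, slice_index, x0 + k * ray_step * normal[0],
                        y0 + k * ray_step * normal[1])
        if lab != BONE:
            break
        k += 1
    else:
        return None
    if lab == BACKGROUND:
        return None
    k_entry = k
    while k - k_entry < max_steps:
        lab = _label_at(volume, slice_index, x0 + k * ray_step * normal[0],
                        y0 + k * ray_step * normal[1])
        if lab != CARTILAGE:
            break
        k += 1
    return (k - k_entry) * ray_step


def measure_thickness(
    volume: LabelVolume,
    frame: SurfaceFrame,
    location: tuple[float, float],
    *,
    cell_u: tuple[float, float] | None = None,
    ray_step: float = DEFAULT_RAY_STEP_MM,
    ray_halfwidth: int = 4,
    ml_factor_mm: float = DEFAULT_ML_FACTOR_MM,
) -> ThicknessMeasurement:
    """Measure cartilage thickness and AP length at one informative location.

    ``cell_u`` is the location's half-open u-cell from the LocationSet
    partition; when omitted, a symmetric 1/3-width cell around u is used.
    """
    u, v = location
    s = slice_for_v(v, frame)
    if s not in frame.boundaries:
        raise OffSurfaceError(f"no boundary on slice {s}")
    boundary = frame.boundaries[s]
    col_t = col_for_u(u, boundary)
    idx = int(np.argmin(np.abs(boundary.cols - col_t)))
    dx, dy = volume.dx, volume.dy

    thicknesses: list[float] = []
    n_denuded = 0
    n_rays = 0
    for j in range(idx - ray_halfwidth, idx + ray_halfwidth + 1):
        if not 0 <= j < len(boundary.cols):
            continue
        n_rays += 1
        normal = _normal_at(boundary, j, frame.surface, dx, dy)
        origin = (boundary.cols[j] * dx, boundary.rows[j] * dy)
        t = _single_ray(volume, s, origin, normal, ray_step)
        if t is None or t == 0.0:
            n_denuded += 1
        else:
            thicknesses.append(min(t, MAX_THICKNESS_MM))
    if n_rays == 0:
        raise OffSurfaceError("location off surface")
    thickness = 0.0 if (n_denuded * 2 >= n_rays or not thicknesses) else float(
        np.mean(thicknesses)
    )

    if cell_u is None:
        cell_u = (max(u - 1 / 6, 0.0), min(u + 1 / 6, 1.0))
    ap_length = _ap_length(volume, frame.surface, s, boundary, cell_u, dx)
    return ThicknessMeasurement(
        surface=frame.surface,
        location=location,
        slice_index=s,
        thickness_mm=thickness,
        ap_length_mm=ap_length,
        ml_factor_mm=ml_factor_mm,
    )


def _ap_length(
    volume: LabelVolume,
    surface: str,
    slice_index: int,
    boundary: Boundary,
    cell_u: tuple[float, float],
    dx: float,
) -> float:
    """Physical AP extent of cartilage-bearing boundary columns in the u-cell."""
    a, p = boundary.anterior_col, boundary.posterior_col
    u_cols = (boundary.cols - a) / (p - a)
    in_cell = (u_cols >= cell_u[0]) & (u_cols < cell_u[1])
    if cell_u[1] >= 1.0:
        in_cell |= u_cols == 1.0
    step = -1 if surface == TIBIA else 1
    rows = boundary.rows + step
    rows = np.clip(rows, 0, volume.n_rows - 1)
    bearing = volume.labels[slice_index, rows, boundary.cols] == CARTILAGE
    return float(np.count_nonzero(in_cell & bearing)) * dx


def measure_at_locations(
    volume: LabelVolume,
    frame: SurfaceFrame,
    locations: LocationSet,
    *,
    ray_step: float = DEFAULT_RAY_STEP_MM,
    ml_factor_mm: float = DEFAULT_ML_FACTOR_MM,
) -> list[ThicknessMeasurement]:
    out = []
    for loc, cell in zip(locations.locations, locations.cells):
        u0, _v0, du, _dv = cell
        out.append(
            measure_thickness(
                volume, frame, loc, cell_u=(u0, u0 + du), ray_step=ray_step,
                ml_factor_mm=ml_factor_mm,
            )
        )
    return out


def compute_cdi(
    measurements: list[ThicknessMeasurement], height_m: float
) -> CdiResult:
    """Height-normalized CDI from per-location measurements.

    Per surface: sum of thickness x AP length x ML factor over its
    locations, divided by height (m). Total = femur + tibia.
    """
    if height_m <= 0:
        raise ValueError("height must be > 0")
    per_surface = {FEMUR: [], TIBIA: []}
    for m in measurements:
        per_surface[m.surface].append(m)
    for surface, ms in per_surface.items():
        if not ms:
            raise ValueError(f"no measurements for surface {surface!r}")
    femur = sum(m.contribution_mm3 for m in per_surface[FEMUR]) / height_m
    tibia = sum(m.contribution_mm3 for m in per_surface[TIBIA]) / height_m
    return CdiResult(
        femur_cdi=femur, tibia_cdi=tibia, height_m=height_m,
        measurements=list(measurements),
    )


def cdi_for_volumes(
    volumes: dict[str, LabelVolume],
    location_sets: dict[str, LocationSet],
    height_m: float,
    *,
    min_bone_voxels: int = 1,
    ray_step: float = DEFAULT_RAY_STEP_MM,
    ml_factor_mm: float = DEFAULT_ML_FACTOR_MM,
) -> CdiResult:
    """CDI of one knee from per-surface label volumes, deriving frames fresh."""
    measurements: list[ThicknessMeasurement] = []
    for surface, volume in volumes.items():
        frame = build_surface_frame(volume, surface, min_bone_voxels=min_bone_voxels)
        measurements.extend(
            measure_at_locations(
                volume, frame, location_sets[surface], ray_step=ray_step,
                ml_factor_mm=ml_factor_mm,
            )
        )
    return compute_cdi(measurements, height_m)


def cdi_for_pair(
    baseline_volumes: dict[str, LabelVolume],
    followup_volumes: dict[str, LabelVolume],
    location_sets: dict[str, LocationSet],
    height_m: float,
    **kwargs,
) -> tuple[CdiResult, CdiResult, dict[str, float]]:
    """Baseline and follow-up CDI with independently derived frames."""
    base = cdi_for_volumes(baseline_volumes, location_sets, height_m, **kwargs)
    follow = cdi_for_volumes(followup_volumes, location_sets, height_m, **kwargs)
    change = {
        "femur": follow.femur_cdi - base.femur_cdi,
        "tibia": follow.tibia_cdi - base.tibia_cdi,
        "total": follow.total_cdi - base.total_cdi,
    }
    return base, follow, change


# ---------------------------------------------------------------------------
# fast mode: measure a cohort record from its (u, v) thickness grids
# ---------------------------------------------------------------------------


def _fast_surface_measurements(
    model: ThicknessModel,
    locations: LocationSet,
    rng: np.random.Generator | None,
    noise_sd: float,
    ml_factor_mm: float,
) -> list[ThicknessMeasurement]:
    out = []
    for loc, cell in zip(locations.locations, locations.cells):
        u, v = loc
        t_true = model.thickness_at(u, v)
        if t_true > 0 and rng is not None and noise_sd > 0:
            t_meas = max(t_true + float(rng.normal(0.0, noise_sd)), 0.0)
        else:
            t_meas = t_true
        u0, _v0, du, _dv = cell
        j = min(int(v * model.n_v), model.n_v - 1)
        i0 = min(int(u0 * model.n_u), model.n_u - 1)
        i1 = min(int((u0 + du) * model.n_u), model.n_u)
        i1 = max(i1, i0 + 1)
        row = model.grid[j, i0:i1]
        bearing_fraction = float(np.mean(row > 0)) if row.size else 0.0
        ap = du * model.ap_extent_mm * bearing_fraction
        out.append(
            ThicknessMeasurement(
                surface=model.surface,
                location=loc,
                slice_index=j,
                thickness_mm=t_meas,
                ap_length_mm=ap,
                ml_factor_mm=ml_factor_mm,
            )
        )
    return out


def measure_record(
    record: KneeRecord,
    location_sets: dict[str, LocationSet],
    *,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    ml_factor_mm: float = DEFAULT_ML_FACTOR_MM,
) -> CdiResult:
    """Fast-mode CDI of one cohort record, with optional remeasurement noise.

    Noise emulates intra-reader variation: an independent Gaussian
    perturbation of each location's thickness, floored at zero; denuded
    locations stay at zero (bare bone is unambiguous to a reader).
    """
    measurements: list[ThicknessMeasurement] = []
    for surface, model in record.models.items():
        measurements.extend(
            _fast_surface_measurements(
                model, location_sets[surface], rng, noise_sd, ml_factor_mm
            )
        )
    return compute_cdi(measurements, record.height_m)
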