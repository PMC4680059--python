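"""Synthetic knee phantoms and longitudinal cohorts with known ground truth.

Two fidelity levels:

* **Full rasterization** (:func:`rasterize_phantom`): a 3D label volume of
  sagittal slices emulating the OAI DESS geometry (160 slices of 0.7 mm, in
  plane 0.365 x 0.456 mm), holding one articular surface — a convex
  cylindrical-cap condyle for the femur or a shallow posteriorly tilted dish
  for the tibia — carrying a cartilage layer of prescribed normal thickness,
  with optional focal lesions (depth fraction 1 = denudation).
* **Fast mode** (:class:`ThicknessModel`): cohort-level experiments carry the
  (u, v) thickness grid directly, skipping voxelization, so statistical
  experiments over hundreds of knees run in seconds.

Both carry analytic ground truth (thickness grid, cartilage volume) so every
downstream module can be checked against a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coords import BONE, CARTILAGE, FEMUR, SURFACES, TIBIA, LabelVolume

# physical anterior-posterior / medial-lateral extents (mm) of the lateral
# articular surfaces used by fast mode; condyle AP span exceeds the plateau's
SURFACE_EXTENT_MM = {FEMUR: (50.0, 38.0), TIBIA: (42.0, 36.0)}

DEFAULT_SPACING = (0.365, 0.456, 0.7)  # DESS in-plane x, y and slice spacing
DEFAULT_IN_PLANE = (307, 384)  # rows x cols
DEFAULT_N_SLICES = 160


@dataclass(frozen=True)
class LesionSpec:
    """A focal cartilage lesion as a half-open rectangle in (u, v).

    ``depth_fraction`` = 1 removes the full thickness (denudation exposing
    subchondral bone); intermediate values thin the cartilage proportionally.
    """

    center_uv: tuple[float, float]
    extent_uv: tuple[float, float]
    depth_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must lie in [0, 1]")
        du, dv = self.extent_uv
        if du <= 0 or dv <= 0:
            raise ValueError("lesion extents must be positive")
        u0, v0 = self.rect[:2]
        if u0 >= 1.0 or v0 >= 1.0 or u0 + du <= 0.0 or v0 + dv <= 0.0:
            raise ValueError("lesion rectangle does not intersect [0,1]^2")

    @property
    def rect(self) -> tuple[float, float, float, float]:
        """(u0, v0, du, dv) with the half-open convention [u0, u0+du)."""
        cu, cv = self.center_uv
        du, dv = self.extent_uv
        return (cu - du / 2.0, cv - dv / 2.0, du, dv)

    def covers(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u0, v0, du, dv = self.rect
        return (u >= u0) & (u < u0 + du) & (v >= v0) & (v < v0 + dv)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and content of one single-surface phantom volume."""

    surface: str = FEMUR
    n_slices: int = DEFAULT_N_SLICES
    in_plane_shape: tuple[int, int] = DEFAULT_IN_PLANE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    base_thickness_mm: float = 2.0
    thickness_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface not in SURFACES:
            raise ValueError(f"unknown surface {self.surface!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if self.base_thickness_mm < 0:
            raise ValueError("base_thickness_mm must be >= 0")


@dataclass
class PhantomTruth:
    """Analytic ground truth attached to a rasterized phantom."""

    surface: str
    thickness_mm: np.ndarray  # (n_domain_slices, n_domain_cols) effective thickness
    u: np.ndarray  # per-domain-column u
    v: np.ndarray  # per-domain-slice v
    domain_slices: tuple[int, int]  # inclusive slice range with bone
    domain_cols: tuple[int, int]  # inclusive column range with bone
    analytic_volume_mm3: float
    lesions: tuple[LesionSpec, ...]


@dataclass
class PhantomResult:
    volume: LabelVolume
    truth: PhantomTruth
    denudation_mask: LabelVolume  # 0/1 volume marking denuded surface voxels


class PhantomOverflowError(ValueError):
    """Cartilage or bone would extend outside the volume."""


def _surface_height(
    surface: str,
    x: np.ndarray,
    z: np.ndarray,
    x_range: tuple[float, float],
    z_range: tuple[float, float],
    n_rows: int,
    dy: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bone-surface height h(x, z) in mm (row direction, inferior positive).

    Femur: parabolic cylindrical cap, convex toward the tibia, apex placed
    anteriorly so the posterior (weight-bearing in flexion) region presents
    an oblique interface to the voxel grid. Tibia: shallow dish with a
    posterior tilt. Returns (h, dh/dx, dh/dz).
    """
    x0, x1 = x_range
    z0, z1 = z_range
    width = x1 - x0
    depth_z = z1 - z0
    height = n_rows * dy
    xc = x0 + 0.35 * width  # anterior apex
    zc = 0.5 * (z0 + z1)
    ax = 0.65 * width
    az = 0.55 * depth_z
    if surface == FEMUR:
        dxx = 0.125 * width
        dzz = 0.05 * depth_z
        h = 0.42 * height + dxx * (1.0 - ((x - xc) / ax) ** 2) - dzz * ((z - zc) / az) ** 2
        hx = -2.0 * dxx * (x - xc) / ax**2
        hz = -2.0 * dzz * (z - zc) / az**2
    else:
        ddish = 0.05 * width
        tilt = 0.08
        h = (
            0.58 * height
            + ddish * (1.0 - ((x - xc) / ax) ** 2 - ((z - zc) / az) ** 2)
            + tilt * (x - x0)
        )
        hx = -2.0 * ddish * (x - xc) / ax**2 + tilt
        hz = -2.0 * ddish * (z - zc) / az**2
    return h, hx, hz


def effective_thickness(
    spec: PhantomSpec, u: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Thickness field after lesion attenuation, on a (v, u) meshgrid."""
    V, U = np.meshgrid(v, u, indexing="ij")
    if spec.thickness_field is not None:
        t = np.asarray(spec.thickness_field(U, V), dtype=float)
        t = np.broadcast_to(t, U.shape).copy()
    else:
        t = np.full(U.shape, float(spec.base_thickness_mm))
    if np.any(t < 0):
        raise ValueError("thickness_field must be non-negative everywhere")
    factor = np.ones_like(t)
    for lesion in spec.lesions:
        inside = lesion.covers(U, V)
        factor[inside] = np.minimum(factor[inside], 1.0 - lesion.depth_fraction)
    return t * factor


def rasterize_phantom(spec: PhantomSpec) -> PhantomResult:
    """Voxelize a phantom: bone slab + cartilage layer of normal thickness.

    The cartilage layer has local thickness ``thickness_field(u, v)`` along
    the surface normal; rasterization converts that to a vertical extent
    ``t * sqrt(1 + |grad h|^2)`` per surface column, so a normal ray through
    the labels recovers the prescribed thickness. Deterministic.
    """
    n_rows, n_cols = spec.in_plane_shape
    dx, dy, dz = spec.spacing
    # rectangular bone footprint: 10-90% of slices, 15-85% of columns
    s0, s1 = int(round(0.10 * spec.n_slices)), int(round(0.90 * spec.n_slices)) - 1
    c0, c1 = int(round(0.15 * n_cols)), int(round(0.85 * n_cols)) - 1
    if s1 - s0 < 2 or c1 - c0 < 2:
        raise ValueError("volume too small for a phantom surface")
    slices = np.arange(s0, s1 + 1)
    cols = np.arange(c0, c1 + 1)
    u = (cols - c0) / (c1 - c0)
    v = (slices - s0) / (s1 - s0)
    x = cols * dx
    z = slices * dz
    Z, X = np.meshgrid(z, x, indexing="ij")
    h, hx, hz = _surface_height(
        spec.surface, X, Z, (x[0], x[-1]), (z[0], z[-1]), n_rows, dy
    )
    sec = np.sqrt(1.0 + hx**2 + hz**2)
    t_eff = effective_thickness(spec, u, v)
    vext = t_eff * sec

    y = np.arange(n_rows) * dy
    Y = y[None, :, None]
    H = h[:, None, :]
    V = vext[:, None, :]
    bone_depth = 0.22 * n_rows * dy
    if spec.surface == TIBIA:
        cart_lo, cart_hi = H - V, H  # cartilage above the bone (superior)
        bone_lo, bone_hi = H, H + bone_depth
        if np.any(h - vext < dy):
            raise PhantomOverflowError("phantom overflow: cartilage exits the volume")
    else:
        cart_lo, cart_hi = H, H + V  # cartilage below the condyle (inferior)
        bone_lo, bone_hi = H - bone_depth, H
        if np.any(h + vext > (n_rows - 2) * dy):
            raise PhantomOverflowError("phantom overflow: cartilage exits the volume")
    bone_hi = np.clip(bone_hi, 0, (n_rows - 1) * dy)
    bone_lo = np.clip(bone_lo, 0, (n_rows - 1) * dy)

    labels = np.zeros((spec.n_slices, n_rows, n_cols), dtype=np.int16)
    block = labels[s0 : s1 + 1, :, c0 : c1 + 1]
    has_cart = (t_eff > 0)[:, None, :]
    if spec.surface == TIBIA:
        cart_mask = (Y >= cart_lo) & (Y < cart_hi) & has_cart
        bone_mask = (Y >= bone_lo) & (Y <= bone_hi)
    else:
        cart_mask = (Y > cart_lo) & (Y <= cart_hi) & has_cart
        bone_mask = (Y >= bone_lo) & (Y <= bone_hi)
    block[bone_mask] = BONE
    block[cart_mask & ~bone_mask] = CARTILAGE

    # denudation mask: articular-adjacent voxel wherever a full-depth lesion
    # removed all cartilage
    denuded_cols = np.zeros_like(t_eff, dtype=bool)
    V_, U_ = np.meshgrid(v, u, indexing="ij")
    for lesion in spec.lesions:
        if lesion.depth_fraction >= 1.0:
            denuded_cols |= lesion.covers(U_, V_)
    den = np.zeros_like(labels)
    if denuded_cols.any():
        si, ci = np.nonzero(denuded_cols)
        if spec.surface == TIBIA:
            r = np.ceil(h[si, ci] / dy - 1e-9).astype(int) - 1
        else:
            r = np.floor(h[si, ci] / dy + 1e-9).astype(int) + 1
        r = np.clip(r, 0, n_rows - 1)
        den[slices[si], r, cols[ci]] = 1

    cell_area = (x[1] - x[0]) * (z[1] - z[0])
    analytic_volume = float(np.sum(t_eff * sec) * cell_area)
    truth = PhantomTruth(
        surface=spec.surface,
        thickness_mm=t_eff,
        u=u,
        v=v,
        domain_slices=(s0, s1),
        domain_cols=(c0, c1),
        analytic_volume_mm3=analytic_volume,
        lesions=tuple(spec.lesions),
    )
    return PhantomResult(
        volume=LabelVolume(labels=labels, spacing=spec.spacing),
        truth=truth,
        denudation_mask=LabelVolume(labels=den, spacing=spec.spacing),
    )


# ---------------------------------------------------------------------------
# fast mode: (u, v) thickness grids without voxelization
# ---------------------------------------------------------------------------


@dataclass
class ThicknessModel:
    """Fast-mode articular surface: a thickness grid over (u, v).

    ``grid[j, i]`` is the thickness (mm) at v = v_centers[j], u = u_centers[i];
    cells partition [0,1]^2 evenly. Physical extents convert (u, v) areas to mm^2.
    """

    surface: str
    grid: np.ndarray  # (n_v, n_u) thickness in mm
    ap_extent_mm: float
    ml_extent_mm: float

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("thickness grid must be non-negative")

    @property
    def n_u(self) -> int:
        return self.grid.shape[1]

    @property
    def n_v(self) -> int:
        return self.grid.shape[0]

    def thickness_at(self, u: float, v: float) -> float:
        i = min(int(u * self.n_u), self.n_u - 1)
        j = min(int(v * self.n_v), self.n_v - 1)
        return float(self.grid[j, i])

    def volume_mm3(self) -> float:
        return float(self.grid.mean() * self.ap_extent_mm * self.ml_extent_mm)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cross-sectional + longitudinal cohort.

    Defaults mirror the validation design: 25 knees per lateral JSN grade
    (0-3), grade-dependent mean thickness loss, denudation lesions
    concentrated in a posterior hotspot whose prevalence rises with grade,
    a 24-month progression distribution, and linear covariate links from true
    cartilage volume to radiographic JSW and HKA analogs.
    """

    n_per_grade: int = 25
    grade_levels: tuple[int, ...] = (0, 1, 2, 3)
    grade_effect_mm: tuple[float, ...] = (0.0, 0.3, 0.7, 1.1)
    lesion_prob_by_grade: tuple[float, ...] = (0.05, 0.3, 0.6, 0.9)
    hotspot_uv: tuple[float, float, float, float] = (0.55, 0.35, 0.30, 0.30)
    progression_mean_mm: float = 0.12
    progression_sd_mm: float = 0.10
    remeasure_noise_sd: float = 0.06
    height_dist: tuple[float, float] = (1.68, 0.09)
    # jsw = a + b * total_volume_mm3 / 1000 + N(0, sd); likewise hka
    jsw_link: tuple[float, float, float] = (0.8, 0.6, 0.5)
    hka_link: tuple[float, float, float] = (7.0, -1.0, 2.0)
    base_thickness_mm: dict[str, float] = field(
        default_factory=lambda: {FEMUR: 2.2, TIBIA: 1.8}
    )
    between_subject_sd: float = 0.18
    grid_shape: tuple[int, int] = (60, 60)  # (n_v, n_u)
    n_reliability_per_grade: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grade_levels:
            raise ValueError("grade list must be non-empty")
        if self.n_per_grade < 1:
            raise ValueError("n_per_grade must be >= 1")
        if len(self.grade_effect_mm) != len(self.grade_levels):
            raise ValueError("grade_effect_mm must match grade_levels")
        if len(self.lesion_prob_by_grade) != len(self.grade_levels):
            raise ValueError("lesion_prob_by_grade must match grade_levels")
        if any(not 0.0 <= p <= 1.0 for p in self.lesion_prob_by_grade):
            raise ValueError("lesion probabilities must lie in [0, 1]")
        if self.progression_sd_mm <= 0:
            raise ValueError("progression_sd_mm must be > 0")


BASELINE = "baseline"
MONTH24 = "month24"


@dataclass
class KneeRecord:
    """One knee at one visit, fast mode: per-surface thickness models."""

    knee_id: str
    visit: str
    models: dict[str, ThicknessModel]
    height_m: float
    jsn_grade: int
    kl_grade: int
    jsw_mm: float
    hka_deg: float
    true_cartilage_volume_mm3: float
    lesions: dict[str, tuple[LesionSpec, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError("height must be > 0")
        if not 0 <= self.jsn_grade <= 3:
            raise ValueError("jsn_grade must lie in 0..3")
        if not 0 <= self.kl_grade <= 4:
            raise ValueError("kl_grade must lie in 0..4")


@dataclass
class Cohort:
    spec: CohortSpec
    records: list[KneeRecord]
    reliability_ids: list[str]
    remeasure_seeds: tuple[int, int]

    def baseline(self) -> list[KneeRecord]:
        return [r for r in self.records if r.visit == BASELINE]

    def month24(self) -> list[KneeRecord]:
        return [r for r in self.records if r.visit == MONTH24]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "knee_id": r.knee_id,
                "visit": r.visit,
                "height_m": r.height_m,
                "jsn": r.jsn_grade,
                "kl": r.kl_grade,
                "jsw_mm": r.jsw_mm,
                "hka_deg": r.hka_deg,
                "true_volume_mm3": r.true_cartilage_volume_mm3,
                "in_reliability": r.knee_id in set(self.reliability_ids),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows).sort_values(["knee_id", "visit"]).reset_index(drop=True)


def sample_lesions(
    rng: np.random.Generator,
    hotspot_uv: tuple[float, float, float, float],
    n_range: tuple[int, int] = (1, 2),
    extent_range: tuple[float, float] = (0.2, 0.5),
    depth_fraction: float = 1.0,
) -> tuple[LesionSpec, ...]:
    """Draw denudation lesions inside the hotspot rectangle.

    ``extent_range`` is the lesion width as a fraction of the hotspot extent
    per axis; centers are placed so the whole rectangle stays inside.
    """
    u0, v0, du, dv = hotspot_uv
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    lesions = []
    for _ in range(n):
        eu = float(rng.uniform(*extent_range)) * du
        ev = float(rng.uniform(*extent_range)) * dv
        cu = float(rng.uniform(u0 + eu / 2, u0 + du - eu / 2))
        cv = float(rng.uniform(v0 + ev / 2, v0 + dv - ev / 2))
        lesions.append(
            LesionSpec(center_uv=(cu, cv), extent_uv=(eu, ev), depth_fraction=depth_fraction)
        )
    return tuple(lesions)


def _grid_from_lesions(
    base: float,
    lesions: Sequence[LesionSpec],
    grid_shape: tuple[int, int],
) -> np.ndarray:
    n_v, n_u = grid_shape
    uc = (np.arange(n_u) + 0.5) / n_u
    vc = (np.arange(n_v) + 0.5) / n_v
    Vc, Uc = np.meshgrid(vc, uc, indexing="ij")
    t = np.full((n_v, n_u), max(base, 0.0))
    for lesion in lesions:
        inside = lesion.covers(Uc, Vc)
        t[inside] = np.minimum(t[inside], max(base, 0.0) * (1.0 - lesion.depth_fraction))
    return t


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a fast-mode cohort: baseline + 24-month visit per knee.

    Construction guarantees: per-grade mean true thickness decreases with
    grade (strictly increasing decrements); the 24-month grid is the baseline
    grid minus one progression draw per surface, floored at zero; covariates
    derive from baseline true volume through the configured linear links.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[KneeRecord] = []
    reliability_ids: list[str] = []
    h_mean, h_sd = spec.height_dist
    for gi, grade in enumerate(spec.grade_levels):
        for k in range(spec.n_per_grade):
            knee_id = f"K{grade}{k:03d}"
            height = float(np.clip(rng.normal(h_mean, h_sd), 1.4, 2.1))
            offset = {s: float(rng.normal(0.0, spec.between_subject_sd)) for s in SURFACES}
            has_lesion = bool(rng.random() < spec.lesion_prob_by_grade[gi])
            lesions: dict[str, tuple[LesionSpec, ...]] = {}
            for s in SURFACES:
                lesions[s] = (
                    sample_lesions(rng, spec.hotspot_uv) if has_lesion else ()
                )
            base_t = {
                s: max(
                    spec.base_thickness_mm[s] - spec.grade_effect_mm[gi] + offset[s], 0.05
                )
                for s in SURFACES
            }
            models_b = {
                s: ThicknessModel(
                    surface=s,
                    grid=_grid_from_lesions(base_t[s], lesions[s], spec.grid_shape),
                    ap_extent_mm=SURFACE_EXTENT_MM[s][0],
                    ml_extent_mm=SURFACE_EXTENT_MM[s][1],
                )
                for s in SURFACES
            }
            loss = {
                s: float(rng.normal(spec.progression_mean_mm, spec.progression_sd_mm))
                for s in SURFACES
            }
            models_f = {
                s: ThicknessModel(
                    surface=s,
                    grid=np.clip(models_b[s].grid - loss[s], 0.0, None),
                    ap_extent_mm=SURFACE_EXTENT_MM[s][0],
                    ml_extent_mm=SURFACE_EXTENT_MM[s][1],
                )
                for s in SURFACES
            }
            vol_b = sum(m.volume_mm3() for m in models_b.values())
            vol_f = sum(m.volume_mm3() for m in models_f.values())
            a, b, sd = spec.jsw_link
            jsw = float(max(a + b * vol_b / 1000.0 + rng.normal(0.0, sd), 0.0))
            a, b, sd = spec.hka_link
            hka = float(a + b * vol_b / 1000.0 + rng.normal(0.0, sd))
            kl = int(np.clip(grade + rng.binomial(1, 0.6), 0, 4))
            common = dict(
                height_m=height, jsn_grade=grade, kl_grade=kl, jsw_mm=jsw,
                hka_deg=hka, lesions=lesions,
            )
            records.append(
                KneeRecord(
                    knee_id=knee_id, visit=BASELINE, models=models_b,
                    true_cartilage_volume_mm3=vol_b, **common,
                )
            )
            records.append(
                KneeRecord(
                    knee_id=knee_id, visit=MONTH24, models=models_f,
                    true_cartilage_volume_mm3=vol_f, **common,
                )
            )
            if k < spec.n_reliability_per_grade:
                reliability_ids.append(knee_id)
    seeds = tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    return Cohort(
        spec=spec, records=records, reliability_ids=reliability_ids,
        remeasure_seeds=seeds,
    )
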