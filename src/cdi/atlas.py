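"""Denudation frequency atlas and informative-location selection.

Denudation annotations from a development sample are projected into the
surface's (u, v) frame, accumulated into a per-cell frequency map, and the
9 informative locations per surface are placed as an even 3x3 grid over the
margin-dilated bounding box of the most frequently denuded region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from . import coords
from .coords import LabelVolume, SurfaceFrame
from .synthetic import LesionSpec


class NoDenudationError(ValueError):
    """Frequency map has no positive cells: nothing to anchor locations on."""


@dataclass
class FrequencyMap:
    """Per-cell count of knees exhibiting denudation, over [0,1]^2."""

    counts: np.ndarray  # (n_u, n_v) integer grid
    n_knees: int
    surface: str

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_knees and int(self.counts.max(initial=0)) > self.n_knees:
            raise ValueError("a cell count cannot exceed the number of knees")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.counts, fmt="%d", delimiter=",")

    def to_png(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            self.counts.T, origin="lower", extent=(0, 1, 0, 1), aspect="auto",
            cmap="hot",
        )
        ax.set_xlabel("u (anterior → posterior)")
        ax.set_ylabel("v (medial → lateral)")
        ax.set_title(f"denudation frequency, {self.surface} (n={self.n_knees})")
        fig.colorbar(im, ax=ax, label="knees")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class LocationSet:
    """Informative locations of one surface plus their partition cells.

    ``locations`` are (u, v) points at the centers of ``cells``, which are
    half-open rectangles (u0, v0, du, dv) evenly tiling the selection box.
    """

    surface: str
    locations: list[tuple[float, float]]
    cells: list[tuple[float, float, float, float]]
    grid_shape: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        if len(self.locations) != len(self.cells):
            raise ValueError("locations and cells must pair up")
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("locations must be pairwise distinct")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "surface": self.surface,
            "grid": list(self.grid_shape),
            "locations": [list(p) for p in self.locations],
            "cells": [list(c) for c in self.cells],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LocationSet":
        d = json.loads(Path(path).read_text())
        return cls(
            surface=d["surface"],
            locations=[tuple(p) for p in d["locations"]],
            cells=[tuple(c) for c in d["cells"]],
            grid_shape=tuple(d["grid"]),
        )


def cell_index(coord: float, n: int) -> int:
    """Half-open binning of [0,1] into n cells; 1.0 belongs to the last cell."""
    return min(int(coord * n), n - 1)


def project_denudation(
    mask: LabelVolume,
    frame: SurfaceFrame,
    grid_shape: tuple[int, int] = (100, 100),
) -> np.ndarray:
    """Project denuded surface voxels into (u, v) cells.

    Returns a boolean (n_u, n_v) array marking every cell receiving at least
    one denuded boundary point. An empty mask yields an all-False grid.
    """
    n_u, n_v = grid_shape
    out = np.zeros((n_u, n_v), dtype=bool)
    voxels = np.argwhere(mask.labels > 0)
    span = frame.lateral_slice - frame.medial_slice
    for s, _r, c in voxels:
        s = int(s)
        if s not in frame.boundaries:
            continue
        boundary = frame.boundaries[s]
        a, p = boundary.anterior_col, boundary.posterior_col
        if not a <= c <= p:
            continue
        u = (c - a) / (p - a)
        v = (s - frame.medial_slice) / span
        if not (0.0 <= v <= 1.0):
            continue
        out[cell_index(u, n_u), cell_index(v, n_v)] = True
    return out


def cells_for_lesions(
    lesions: Sequence[LesionSpec], grid_shape: tuple[int, int] = (100, 100)
) -> np.ndarray:
    """Fast-mode projection: mark cells whose center a full-depth lesion covers."""
    n_u, n_v = grid_shape
    uc = (np.arange(n_u) + 0.5) / n_u
    vc = (np.arange(n_v) + 0.5) / n_v
    Uc, Vc = np.meshgrid(uc, vc, indexing="ij")
    out = np.zeros((n_u, n_v), dtype=bool)
    for lesion in lesions:
        if lesion.depth_fraction >= 1.0:
            out |= lesion.covers(Uc, Vc)
    return out


def accumulate_frequency(
    masks: Iterable[np.ndarray], surface: str
) -> FrequencyMap:
    """Count, per cell, how many knees show denudation there."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks to accumulate")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("all masks must share one grid shape")
    counts = np.sum([m.astype(int) for m in masks], axis=0)
    return FrequencyMap(counts=counts, n_knees=len(masks), surface=surface)


def select_informative_locations(
    freq: FrequencyMap,
    threshold_quantile: float = 0.75,
    margin_uv: float = 0.05,
    loc_grid: tuple[int, int] = (3, 3),
) -> LocationSet:
    """Place the informative locations over the dominant denudation region.

    Procedure: threshold the map at ``threshold_quantile`` of its positive
    values; keep the 8-connected component with the largest total count
    (ties: the more posterior component, larger mean u); dilate its bounding
    box by ``margin_uv`` clipped to [0,1]^2; tile that box with an even
    ``loc_grid`` partition and put one location at each cell center.
    """
    counts = freq.counts
    positive = counts[counts > 0]
    if positive.size == 0:
        raise NoDenudationError("no denudation observed")
    thr = np.quantile(positive, threshold_quantile)
    binary = counts >= thr
    labeled, n_comp = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        raise NoDenudationError("no denudation observed")
    n_u, n_v = counts.shape
    uc = (np.arange(n_u) + 0.5) / n_u
    best, best_key = None, None
    for lab in range(1, n_comp + 1):
        comp = labeled == lab
        total = int(counts[comp].sum())
        mean_u = float(uc[np.nonzero(comp)[0]].mean())
        key = (total, mean_u)
        if best_key is None or key > best_key:
            best, best_key = comp, key
    iu, iv = np.nonzero(best)
    u_lo = max(iu.min() / n_u - margin_uv, 0.0)
    u_hi = min((iu.max() + 1) / n_u + margin_uv, 1.0)
    v_lo = max(iv.min() / n_v - margin_uv, 0.0)
    v_hi = min((iv.max() + 1) / n_v + margin_uv, 1.0)
    g_u, g_v = loc_grid
    du = (u_hi - u_lo) / g_u
    dv = (v_hi - v_lo) / g_v
    locations, cells = [], []
    for j in range(g_v):
        for i in range(g_u):
            cells.append((u_lo + i * du, v_lo + j * dv, du, dv))
            locations.append((u_lo + (i + 0.5) * du, v_lo + (j + 0.5) * dv))
    return LocationSet(
        surface=freq.surface, locations=locations, cells=cells, grid_shape=loc_grid
    )


def build_atlas(
    mask_volumes: Sequence[LabelVolume],
    frames: Sequence[SurfaceFrame],
    surface: str,
    grid_shape: tuple[int, int] = (100, 100),
    threshold_quantile: float = 0.75,
    margin_uv: float = 0.05,
) -> tuple[FrequencyMap, LocationSet]:
    """Full atlas stage: project every knee, accumulate, select locations."""
    masks = [
        project_denudation(m, f, grid_shape) for m, f in zip(mask_volumes, frames)
    ]
    freq = accumulate_frequency(masks, surface)
    locs = select_informative_locations(
        freq, threshold_quantile=threshold_quantile, margin_uv=margin_uv
    )
    return freq, locs
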