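"""Metastasis-probability heatmap over a sampled grid.

The volume is sampled with a lattice Omega of per-axis strides (alpha_x,
alpha_y, alpha_z) in voxels.  The seeding model is evaluated at every lattice
point inside the lung mask — using the single spanning-tree path from the
tumor's vessel to the point's nearest vessel — and the resulting settled-cell
counts are L1-normalized into a probability field.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .biophysics import ModelParams, SeedingModel
from .io import VolumeImage
from .segmentation import LungMask, TumorSpec
from .vesselgraph import VesselGraph

__all__ = ["GridSpec", "Heatmap", "sample_grid", "generate_heatmap"]


@dataclass
class GridSpec:
    """Per-axis grid strides (voxels)."""

    alpha: tuple = (4, 4, 4)

    def __post_init__(self):
        self.alpha = tuple(int(a) for a in self.alpha)
        if any(a < 1 for a in self.alpha):
            raise ValueError("grid strides must be at least 1")

    def validate_for(self, shape) -> None:
        if any(a > n for a, n in zip(self.alpha, shape)):
            raise ValueError(f"grid strides {self.alpha} exceed volume shape {shape}")


@dataclass
class Heatmap:
    """Non-negative field over the volume, nonzero only at grid points."""

    values: np.ndarray
    grid: GridSpec
    normalized: bool
    grid_points: np.ndarray = field(default=None, repr=False)

    def nearest_grid_value(self, voxel_idx) -> float:
        """Heatmap value at the lattice point nearest a voxel index."""
        idx = np.asarray(voxel_idx)
        alpha = np.asarray(self.grid.alpha)
        shape = np.asarray(self.values.shape)
        snapped = np.round(idx / alpha).astype(int) * alpha
        limit = ((shape - 1) // alpha) * alpha
        snapped = np.minimum(snapped, limit)
        return float(self.values[tuple(snapped)])

    def nonzero_grid_values(self) -> np.ndarray:
        vals = self.values[tuple(self.grid_points.T)]
        return vals[vals > 0]


def sample_grid(shape, grid: GridSpec) -> list[tuple[int, int, int]]:
    """Lattice points of Omega in voxel units, ordered z-major then y then x."""
    grid.validate_for(shape)
    ax, ay, az = grid.alpha
    return [
        (x, y, z)
        for z in range(0, shape[2], az)
        for y in range(0, shape[1], ay)
        for x in range(0, shape[0], ax)
    ]


def generate_heatmap(
    volume: VolumeImage,
    tumor: TumorSpec,
    lung: LungMask,
    G: VesselGraph,
    grid: GridSpec,
    params: ModelParams,
) -> Heatmap:
    """Evaluate the seeding model on Omega and L1-normalize into probabilities.

    Grid points outside the lung mask get probability 0 without a model
    evaluation.  If every count is zero the map is returned un-normalized with
    a warning.
    """
    points = sample_grid(volume.shape, grid)
    if not points:
        raise ValueError("empty grid")
    spacing = np.asarray(volume.spacing)
    model = SeedingModel(G, tumor, lung, params, spacing=volume.spacing)
    values = np.zeros(volume.shape, dtype=float)
    for pt in points:
        if not lung.mask[pt]:
            continue
        tau = np.asarray(pt) * spacing
        values[pt] = model.predict(tau).c
    total = values.sum()
    normalized = False
    if total > 0:
        values = values / total
        normalized = True
    else:
        warnings.warn("all grid counts are zero; heatmap left un-normalized")
    return Heatmap(values, grid, normalized, grid_points=np.array(points))
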