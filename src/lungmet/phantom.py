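"""Synthetic CT-like phantoms with exact ground truth.

A phantom contains two ellipsoidal lungs, a branching cylindrical vessel tree
grown from a root inside a lung, a spherical primary tumor, and planted
ground-truth metastasis sites near distal vessel endpoints.  Intensities are a
four-level piecewise-constant model (background 0.1, lung 0.3, vessel 0.7,
tumor 0.9) with additive Gaussian noise; ground-truth masks are noise-free.

Metastasis sites are sampled from vessel endpoints away from the primary tumor
with probability proportional to the vessel radius, so a transport model that
prefers wide, well-perfused vessels is correlated with the planted truth by
construction.  Planted sites are *not* painted into the intensity volume: they
emulate lesions below imaging resolution, which is exactly the regime the
heatmap is for.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import PhantomError
from .io import VolumeImage
from .segmentation import TumorSpec
from .vesselgraph import VesselSegment

__all__ = [
    "Ellipsoid",
    "VesselTreeSpec",
    "PhantomSpec",
    "GroundTruth",
    "child_radii",
    "generate_phantom",
]

INTENSITY = {"background": 0.1, "lung": 0.3, "vessel": 0.7, "tumor": 0.9}


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid, optionally rotated about the z axis."""

    center: tuple = (20.0, 32.0, 32.0)
    semi_axes: tuple = (11.0, 16.0, 22.0)
    rotation_z: float = 0.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership for an (..., 3) array of mm points."""
        d = np.asarray(pts, dtype=float) - np.asarray(self.center)
        if self.rotation_z:
            ct, st = math.cos(self.rotation_z), math.sin(self.rotation_z)
            dx = ct * d[..., 0] + st * d[..., 1]
            dy = -st * d[..., 0] + ct * d[..., 1]
            d = np.stack([dx, dy, d[..., 2]], axis=-1)
        ax = np.asarray(self.semi_axes)
        return np.sum((d / ax) ** 2, axis=-1) <= 1.0


@dataclass
class VesselTreeSpec:
    """Branching spec of the phantom vessel tree.

    Orientations are drawn in the (o_xy, o_xz) parameter space of the endpoint
    formula, so every generated branch is exactly representable by a
    :class:`VesselSegment`.
    """

    root_start: tuple = (14.0, 32.0, 16.0)
    root_o_xy: float = 7 * math.pi / 4   # direction (cos, cos(pi/4-o), cos) = (.71, 0, .71)
    root_o_xz: float = math.pi / 4
    root_h: float = 12.0
    root_radius: float = 2.5
    depth: int = 4
    n_children: int = 2
    radius_exponent: float = 3.0     # Murray-style closure n * r_child^e = r_parent^e
    height_decay: float = 0.78
    branch_angle_range: tuple = (0.35, 0.7)


@dataclass
class PhantomSpec:
    shape: tuple = (64, 64, 64)
    voxel_spacing: tuple = (1.0, 1.0, 1.0)
    lung_ellipsoids: tuple = (
        Ellipsoid((20.0, 32.0, 32.0), (11.0, 16.0, 22.0)),
        Ellipsoid((44.0, 32.0, 32.0), (11.0, 16.0, 22.0)),
    )
    vessel_tree: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    tumor: TumorSpec = field(default_factory=lambda: TumorSpec((17.0, 36.0, 20.0), 4.0))
    n_metastases: int = 3
    metastasis_radius: float = 1.5   # mm, planted lesion size (below CT visibility)
    min_distal_mm: float = 10.0      # planted sites keep this distance from the tumor
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(s < 16 for s in self.shape):
            raise PhantomError("each shape component must be at least 16")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomError("voxel spacing must be positive")
        if not self.vessel_tree.root_radius > 0:
            raise PhantomError("root radius must be positive")
        if self.vessel_tree.depth < 1:
            raise PhantomError("branching depth must be at least 1")
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be non-negative")

    def to_yaml(self, path) -> None:
        from pathlib import Path

        payload = {
            "shape": list(self.shape),
            "voxel_spacing": list(self.voxel_spacing),
            "lung_ellipsoids": [
                {"center": list(e.center), "semi_axes": list(e.semi_axes),
                 "rotation_z": e.rotation_z}
                for e in self.lung_ellipsoids
            ],
            "vessel_tree": {
                "root_start": list(self.vessel_tree.root_start),
                "root_o_xy": self.vessel_tree.root_o_xy,
                "root_o_xz": self.vessel_tree.root_o_xz,
                "root_h": self.vessel_tree.root_h,
                "root_radius": self.vessel_tree.root_radius,
                "depth": self.vessel_tree.depth,
                "n_children": self.vessel_tree.n_children,
                "radius_exponent": self.vessel_tree.radius_exponent,
                "height_decay": self.vessel_tree.height_decay,
                "branch_angle_range": list(self.vessel_tree.branch_angle_range),
            },
            "tumor": {"location": list(map(float, self.tumor.location)),
                      "size": self.tumor.size},
            "n_metastases": self.n_metastases,
            "metastasis_radius": self.metastasis_radius,
            "min_distal_mm": self.min_distal_mm,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


@dataclass
class GroundTruth:
    """Exact, noise-free ground truth of a phantom."""

    lung_mask: np.ndarray
    vessel_segments: list
    vessel_tree_edges: list
    tumor: TumorSpec
    metastasis_mask: np.ndarray
    vessel_mask: np.ndarray


def child_radii(parent_radius: float, n_children: int, exponent: float) -> list[float]:
    """Equal child radii satisfying the closure ``n * r_child^e = r_parent^e``."""
    if not parent_radius > 0:
        raise ValueError("parent_radius must be positive")
    if n_children < 1:
        raise ValueError("n_children must be at least 1")
    if not exponent > 0:
        raise ValueError("exponent must be positive")
    r = parent_radius / n_children ** (1.0 / exponent)
    return [r] * n_children


def _world_grid(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _capsule_mask(shape, spacing, sl, el, r) -> np.ndarray:
    """Voxels within distance r of the sl-el segment (bounding-box cropped)."""
    spacing = np.asarray(spacing, dtype=float)
    lo_mm = np.minimum(sl, el) - r - spacing
    hi_mm = np.maximum(sl, el) + r + spacing
    lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    axes = [np.arange(lo[d], hi[d]) * spacing[d] for d in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    ab = el - sl
    denom = float(ab @ ab)
    rel = pts - sl
    t = np.clip(np.tensordot(rel, ab, axes=([-1], [0])) / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = sl + t[..., None] * ab if denom > 0 else np.broadcast_to(sl, pts.shape)
    d = np.linalg.norm(pts - closest, axis=-1)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d <= r
    return mask


def _ball_mask(shape, spacing, center, r) -> np.ndarray:
    return _capsule_mask(shape, spacing, np.asarray(center, float), np.asarray(center, float), r)


def _grow_tree(spec: PhantomSpec, rng: np.random.Generator):
    """Depth-first recursive tree growth in (o_xy, o_xz, h) parameter space."""
    ts = spec.vessel_tree
    lungs = spec.lung_ellipsoids

    def in_lung(p) -> bool:
        return any(bool(e.contains(np.asarray(p))) for e in lungs)

    segments: list[VesselSegment] = []
    edges: list[tuple[int, int]] = []

    def grow(start, o_xy, o_xz, h, r, depth_left, parent):
        seg = VesselSegment.from_start(start, h, r, o_xy, o_xz)
        idx = len(segments)
        segments.append(seg)
        if parent is not None:
            edges.append((parent, idx))
        if depth_left <= 1:
            return
        radii = child_radii(r, ts.n_children, ts.radius_exponent)
        h_child = h * ts.height_decay
        for k in range(ts.n_children):
            sign = 1.0 if k % 2 == 0 else -1.0
            c_xy, c_xz = o_xy, o_xz
            for attempt in range(10):
                d_xy = sign * rng.uniform(*ts.branch_angle_range)
                d_xz = rng.uniform(-0.5, 0.5) * ts.branch_angle_range[1]
                c_xy = (o_xy + d_xy) % (2 * math.pi)
                c_xz = float(np.clip(o_xz + d_xz, 0.05, math.pi - 0.05))
                child = VesselSegment.from_start(seg.el, h_child, radii[k], c_xy, c_xz)
                if in_lung(child.el):
                    break
            grow(seg.el, c_xy, c_xz, h_child, radii[k], depth_left - 1, idx)

    grow(np.asarray(ts.root_start, float), ts.root_o_xy, ts.root_o_xz,
         ts.root_h, ts.root_radius, ts.depth, None)
    return segments, edges


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Render a phantom volume and its exact ground truth (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = tuple(spec.voxel_spacing)

    grid = _world_grid(shape, spacing)
    lung_mask = np.zeros(shape, dtype=bool)
    for ell in spec.lung_ellipsoids:
        lung_mask |= ell.contains(grid)

    segments, edges = _grow_tree(spec, rng)
    root = segments[0]
    probes = root.sl + np.linspace(0, 1, 21)[:, None] * (root.el - root.sl)
    if not any(e.contains(probes).any() for e in spec.lung_ellipsoids):
        raise PhantomError("vessel tree root does not intersect a lung ellipsoid")

    vessel_mask = np.zeros(shape, dtype=bool)
    for seg in segments:
        vessel_mask |= _capsule_mask(shape, spacing, seg.sl, seg.el, seg.r)

    tumor = spec.tumor
    tumor_mask = _ball_mask(shape, spacing, tumor.location, tumor.size)

    met_mask = np.zeros(shape, dtype=bool)
    if spec.n_metastases > 0:
        dist = np.array([np.linalg.norm(s.c - tumor.location) for s in segments])
        cand = np.nonzero(dist > spec.min_distal_mm)[0]
        if cand.size == 0:
            cand = np.arange(len(segments))
        weights = np.array([segments[i].r for i in cand], dtype=float)
        weights /= weights.sum()
        planted = 0
        tries = 0
        chosen: set[int] = set()
        while planted < spec.n_metastases and tries < 20 * spec.n_metastases:
            tries += 1
            pick = int(rng.choice(cand, p=weights))
            if pick in chosen and len(chosen) < cand.size:
                continue
            ball = _ball_mask(shape, spacing, segments[pick].el, spec.metastasis_radius)
            ball &= lung_mask
            if ball.any():
                met_mask |= ball
                chosen.add(pick)
                planted += 1
        if planted < spec.n_metastases:
            raise PhantomError("could not place the requested metastases inside the lungs")

    vol = np.full(shape, INTENSITY["background"], dtype=float)
    vol[lung_mask] = INTENSITY["lung"]
    vol[vessel_mask] = INTENSITY["vessel"]
    vol[tumor_mask] = INTENSITY["tumor"]
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, shape)

    truth = GroundTruth(
        lung_mask=lung_mask,
        vessel_segments=segments,
        vessel_tree_edges=edges,
        tumor=tumor,
        metastasis_mask=met_mask,
        vessel_mask=vessel_mask,
    )
    return VolumeImage(vol, spacing), truth
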