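"""Volume container and NIfTI / JSON / YAML input-output.

The in-memory volume convention follows the axis order (x, y, z): ``data[i, j, k]``
is the voxel with 0-based index ``(i, j, k)``, and its world coordinate in mm is
``index * voxel_spacing`` per axis.
"""
from __future__ import annotations

import gzip
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError


@dataclass
class VolumeImage:
    """A 3D scalar grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, point) -> tuple[int, int, int]:
        """Nearest voxel index for a world-coordinate point (mm)."""
        idx = np.round(np.asarray(point, dtype=float) / np.asarray(self.spacing))
        return tuple(int(i) for i in idx)

    def contains_world(self, point) -> bool:
        idx = self.world_to_voxel(point)
        return all(0 <= i < n for i, n in zip(idx, self.shape))


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _write_nifti(img: nib.Nifti1Image, path: Path) -> None:
    # gzip with mtime=0 so byte-identical data gives byte-identical files
    raw = img.to_bytes()
    if str(path).endswith(".gz"):
        buf = _io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
            fh.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        path.write_bytes(raw)


def write_volume(volume: VolumeImage, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(volume.data, _affine(volume.spacing))
    _write_nifti(img, path)


def read_volume(path) -> VolumeImage:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises a zoo of types on malformed input
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeImage(data, tuple(float(z) for z in zooms))


def write_mask(mask: np.ndarray, spacing, path) -> None:
    """Binary mask as uint8 NIfTI."""
    write_volume(VolumeImage(np.asarray(mask).astype(np.uint8), spacing), path)


def read_mask(path) -> np.ndarray:
    return read_volume(path).data.astype(bool)


def write_graph_json(graph, path) -> None:
    """Serialize a VesselGraph (nodes with cylinder fields, weighted edge list)."""
    payload = {
        "nodes": [
            {
                "id": i,
                "c": [float(v) for v in seg.c],
                "h": float(seg.h),
                "r": float(seg.r),
                "o_xy": float(seg.o_xy),
                "o_xz": float(seg.o_xz),
            }
            for i, seg in enumerate(graph.segments)
        ],
        "edges": [
            {
                "i": int(i),
                "j": int(j),
                "dist": float(d),
                "weight": float(min(graph.segments[i].r, graph.segments[j].r)),
            }
            for (i, j), d in sorted(graph.edges.items())
        ],
        "is_tree": bool(graph.is_tree),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_graph_json(path):
    from .vesselgraph import VesselGraph, VesselSegment

    try:
        payload = json.loads(Path(path).read_text())
        nodes = sorted(payload["nodes"], key=lambda n: n["id"])
        segments = [
            VesselSegment(np.array(n["c"], dtype=float), n["h"], n["r"], n["o_xy"], n["o_xz"])
            for n in nodes
        ]
        edges = {(e["i"], e["j"]): e["dist"] for e in payload["edges"]}
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed graph JSON {path}: {exc}") from exc
    return VesselGraph(segments, edges, is_tree=payload.get("is_tree", False))
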