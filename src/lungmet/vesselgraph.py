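"""Cylinder-approximated vessel segments and the blood-flow graph.

A vessel segment is the tuple ``b = (c, h, r, o_xy, o_xz)``: center of mass ``c``
(mm), height ``h`` (mm), average radius ``r`` (mm) and two orientation angles,
``o_xy`` in [0, 2pi] and ``o_xz`` in [0, pi].  Its start/end locations are

    sl = c - h/2 * u,   el = c + h/2 * u,
    u  = [cos(o_xy), cos(pi/4 - o_xy), cos(o_xz)]

Note that ``u`` is deliberately *not* unit-norm; the same parametrization is used
when generating phantoms and when fitting detected vessels, so the geometry stays
self-consistent throughout.  A consequence worth knowing: directions close to the
pure z axis are not representable (cos(o_xy) and cos(pi/4 - o_xy) cannot vanish
simultaneously), so all representable cylinders rise at most ~62 degrees out of
the xy plane.

The flow graph ``G = (B, E)`` connects segments whose start point falls within a
growing search radius of another segment's endpoint; once connected, it is reduced
to the spanning tree that keeps the widest vessels (edge weight = the smaller of
the two incident radii, the hemodynamically limiting bore).
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .errors import GraphConstructionError
from .io import VolumeImage

__all__ = [
    "VesselSegment",
    "VesselGraph",
    "GraphBuildParams",
    "direction_vector",
    "orientation_from_displacement",
    "segment_endpoints",
    "build_graph",
    "max_radius_spanning_tree",
    "nearest_vessel",
    "enumerate_paths",
    "detect_vessels",
]


def direction_vector(o_xy: float, o_xz: float) -> np.ndarray:
    """The (non-unit) direction vector of the endpoint parametrization."""
    return np.array([np.cos(o_xy), np.cos(np.pi / 4 - o_xy), np.cos(o_xz)])


def orientation_from_displacement(v) -> tuple[float, float, float]:
    """Invert the endpoint parametrization: displacement ``el - sl`` -> (o_xy, o_xz, h).

    Exact whenever ``v`` is representable (i.e. was produced by the forward
    formula); otherwise cos(o_xz) is clamped into [-1, 1], which preserves the
    in-plane components at the cost of the z component.
    """
    vx, vy, vz = (float(c) for c in v)
    if abs(vx) < 1e-12 and abs(vy) < 1e-12:
        raise ValueError("pure-z displacements are not representable by the parametrization")
    if abs(vx) < 1e-12:
        # cos(o_xy) = 0 -> o_xy in {pi/2, 3pi/2}; pick the branch giving h > 0
        o_xy = np.pi / 2 if vy > 0 else 3 * np.pi / 2
        h = vy / np.cos(np.pi / 4 - o_xy)
    else:
        # from cos(pi/4 - o)/cos(o) = vy/vx:  tan(o) = (sqrt(2) vy - vx)/vx.
        # atan2 with vx as the "cos" argument selects the branch where h > 0.
        o_xy = float(np.arctan2(np.sqrt(2) * vy - vx, vx)) % (2 * np.pi)
        h = vx / np.cos(o_xy)
    cos_oxz = np.clip(vz / h, -1.0, 1.0)
    o_xz = float(np.arccos(cos_oxz))
    return float(o_xy), o_xz, float(h)


@dataclass
class VesselSegment:
    """One cylinder blood vessel ``b = (c, h, r, o_xy, o_xz)``."""

    c: np.ndarray
    h: float
    r: float
    o_xy: float
    o_xz: float

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (3,):
            raise ValueError("c must be a 3-vector")
        if not self.h > 0:
            raise ValueError("h must be positive")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if not 0 <= self.o_xy <= 2 * np.pi + 1e-12:
            raise ValueError("o_xy must lie in [0, 2pi]")
        if not 0 <= self.o_xz <= np.pi + 1e-12:
            raise ValueError("o_xz must lie in [0, pi]")

    @property
    def direction(self) -> np.ndarray:
        return direction_vector(self.o_xy, self.o_xz)

    @property
    def sl(self) -> np.ndarray:
        return self.c - self.h / 2 * self.direction

    @property
    def el(self) -> np.ndarray:
        return self.c + self.h / 2 * self.direction

    @classmethod
    def from_start(cls, start, h, r, o_xy, o_xz) -> "VesselSegment":
        """Build a segment anchored at its start location instead of its center."""
        u = direction_vector(o_xy, o_xz)
        c = np.asarray(start, dtype=float) + h / 2 * u
        return cls(c, h, r, o_xy, o_xz)

    @classmethod
    def from_endpoints(cls, sl, el, r) -> "VesselSegment":
        """Build a segment from its endpoints (must be a representable displacement)."""
        sl = np.asarray(sl, dtype=float)
        el = np.asarray(el, dtype=float)
        o_xy, o_xz, h = orientation_from_displacement(el - sl)
        return cls((sl + el) / 2, h, r, o_xy, o_xz)


def segment_endpoints(b: VesselSegment) -> tuple[np.ndarray, np.ndarray]:
    """Start and end locations (sl, el) of a cylinder vessel."""
    return b.sl, b.el


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def segment_surface_distance(b: VesselSegment, p) -> float:
    """Distance from a point to the vessel surface (centerline distance - r, floored at 0)."""
    p = np.asarray(p, dtype=float)
    return max(0.0, _point_segment_distance(p, b.sl, b.el) - b.r)


@dataclass
class GraphBuildParams:
    """User-set parameters of the iterative search-radius edge insertion."""

    R0: float = 2.0
    delta_R: float = 1.0
    max_rounds: int = 1000

    def __post_init__(self):
        if not self.R0 > 0:
            raise ValueError("R0 must be positive")
        if not self.delta_R > 0:
            raise ValueError("delta_R must be positive")


@dataclass
class VesselGraph:
    """Graph over vessel segments; nodes are indices into ``segments``.

    ``edges`` maps sorted index pairs to the endpoint distance that created the
    edge. ``final_R``/``rounds`` record how far the search radius had to grow.
    """

    segments: list
    edges: dict = field(default_factory=dict)
    is_tree: bool = False
    final_R: float | None = None
    rounds: int = 0

    def __len__(self) -> int:
        return len(self.segments)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.segments)))
        for (i, j), d in self.edges.items():
            g.add_edge(i, j, dist=d, weight=min(self.segments[i].r, self.segments[j].r))
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def endpoint_gap(self, i: int, j: int) -> float:
        """Smallest distance between any endpoints of segments i and j."""
        si, sj = self.segments[i], self.segments[j]
        return min(
            float(np.linalg.norm(ei - ej))
            for ei in (si.sl, si.el)
            for ej in (sj.sl, sj.el)
        )


def build_graph(segments, params: GraphBuildParams | None = None) -> VesselGraph:
    """Connect vessel segments by iteratively growing the search radius R.

    Segments are sorted by height (descending, stable) before indexing.  Each
    round tests every segment's start location ``sl`` against a sphere of radius
    R around every other segment's endpoints, connecting it to the closest such
    endpoint's segment that it is not already linked to (so later rounds can
    keep making progress).  A round that adds no new edge grows R by delta_R;
    the process halts once the graph is connected and a round at the final
    radius adds nothing more, so every endpoint pair within R is linked and
    junction ambiguities are left for the spanning-tree reduction to resolve.
    """
    params = params or GraphBuildParams()
    if len(segments) == 0:
        raise GraphConstructionError("cannot build a graph from zero segments")
    segments = sorted(segments, key=lambda s: -s.h)
    n = len(segments)
    sl = np.array([s.sl for s in segments])
    el = np.array([s.el for s in segments])

    edges: dict[tuple[int, int], float] = {}
    uf = list(range(n))

    def find(a):
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    def connected() -> bool:
        return len({find(i) for i in range(n)}) == 1

    R = params.R0
    rounds = 0
    saturated = False
    while not (connected() and saturated):
        rounds += 1
        if rounds > params.max_rounds:
            comps = {}
            for i in range(n):
                comps.setdefault(find(i), []).append(i)
            raise GraphConstructionError(
                f"not connected after {params.max_rounds} rounds "
                f"(R={R:.3g}); components: {sorted(comps.values())}"
            )
        added = False
        for i in range(n):
            d_sl = np.linalg.norm(sl - sl[i], axis=1)
            d_el = np.linalg.norm(el - sl[i], axis=1)
            d_sl[i] = d_el[i] = np.inf
            d = np.minimum(d_sl, d_el)
            for j in np.argsort(d, kind="stable"):  # ties resolve to the lower index
                j = int(j)
                if d[j] > R:
                    break
                key = (min(i, j), max(i, j))
                if key not in edges:
                    edges[key] = float(d[j])
                    uf[find(i)] = find(j)
                    added = True
                    break
        saturated = not added
        if not added and not connected():
            R += params.delta_R
    return VesselGraph(segments, edges, is_tree=False, final_R=R, rounds=rounds)


def max_radius_spanning_tree(G: VesselGraph) -> VesselGraph:
    """Spanning tree maximizing total edge weight, weight = min incident radius.

    Kruskal with deterministic tie-breaking: equal-weight edges are taken in
    ascending (i, j) order.
    """
    n = len(G.segments)
    g = G.to_networkx()
    if n > 1 and not nx.is_connected(g):
        raise GraphConstructionError("spanning tree requires a connected graph")
    order = sorted(G.edges.items(), key=lambda kv: (-min(G.segments[kv[0][0]].r, G.segments[kv[0][1]].r), kv[0]))
    uf = list(range(n))

    def find(a):
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    kept: dict[tuple[int, int], float] = {}
    for (i, j), d in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            uf[ri] = rj
            kept[(i, j)] = d
    return VesselGraph(G.segments, kept, is_tree=True, final_R=G.final_R, rounds=G.rounds)


def nearest_vessel(G: VesselGraph, p, return_distance: bool = False):
    """Segment whose surface is closest to point ``p`` (ties -> lower id)."""
    p = np.asarray(p, dtype=float)
    if len(G.segments) == 0:
        raise ValueError("empty vessel graph")
    dists = np.array([segment_surface_distance(s, p) for s in G.segments])
    i = int(np.argmin(dists))
    if return_distance:
        return i, float(dists[i])
    return i


def path_length(G: VesselGraph, path) -> float:
    """Length of a node path: heights of traversed segments (excluding the source,
    where cells enter) plus the inter-segment endpoint gaps."""
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        total += G.endpoint_gap(a, b) + G.segments[b].h
    return total


def enumerate_paths(G: VesselGraph, S: int, T: int, nu: float) -> list[list[int]]:
    """All simple paths from S to T strictly shorter than ``nu``.

    Breadth-first expansion with per-branch pruning once the accumulated length
    reaches ``nu``.  On a spanning tree there is at most one such path.  An empty
    result signals extinction before arrival.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    if S == T:
        return [[S]]
    adj = {i: G.neighbors(i) for i in range(len(G.segments))}
    out: list[list[int]] = []
    queue: deque[tuple[list[int], float]] = deque([([S], 0.0)])
    while queue:
        path, length = queue.popleft()
        for j in adj[path[-1]]:
            if j in path:
                continue
            lj = length + G.endpoint_gap(path[-1], j) + G.segments[j].h
            if lj >= nu:
                continue
            if j == T:
                out.append(path + [j])
            else:
                queue.append((path + [j], lj))
    return out


def tree_path(G: VesselGraph, S: int, T: int) -> list[int] | None:
    """The unique S->T path on a spanning tree (None if disconnected)."""
    if S == T:
        return [S]
    adj = {i: G.neighbors(i) for i in range(len(G.segments))}
    prev = {S: None}
    queue = deque([S])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in prev:
                prev[v] = u
                if v == T:
                    path = [T]
                    while prev[path[-1]] is not None:
                        path.append(prev[path[-1]])
                    return path[::-1]
                queue.append(v)
    return None


# --------------------------------------------------------------------------
# vessel detection (threshold -> skeleton -> branch split -> cylinder fit)
# --------------------------------------------------------------------------

_CUBE = np.ones((3, 3, 3), dtype=bool)


def detect_vessels(
    volume: VolumeImage,
    lung,
    min_branch_voxels: int = 4,
) -> list[VesselSegment]:
    """Cylinder-fit vessel segments inside the lung mask.

    Vessel voxels are separated from parenchyma by Otsu's threshold on in-lung
    intensities, skeletonized, and the skeleton is split at branch points; each
    simple branch is fit with a cylinder: centroid, principal-axis direction,
    height from the axial extent (trimmed for the discrete skeleton's overshoot
    into the rounded caps), radius from the mean distance transform along the
    branch.  Segments are then oriented root-outward (see ``_orient_outward``)
    and the orientation angles recovered by inverting the endpoint
    parametrization on the oriented displacement.
    """
    mask = np.asarray(getattr(lung, "mask", lung)).astype(bool)
    data = volume.data
    spacing = np.asarray(volume.spacing)
    vals = data[mask]
    if vals.size == 0:
        return []
    if np.ptp(vals) < 1e-12:
        return []
    thr = threshold_otsu(vals)
    vmask = mask & (data > thr)
    if not vmask.any():
        return []

    skel = skeletonize(vmask).astype(bool)
    if not skel.any():
        return []
    nb_count = ndimage.convolve(skel.astype(np.uint8), _CUBE.astype(np.uint8), mode="constant") - skel
    junctions = skel & (nb_count >= 3)
    branches = skel & ~junctions
    labels, nlab = ndimage.label(branches, structure=_CUBE)
    edt = ndimage.distance_transform_edt(vmask, sampling=spacing)

    fits: list[tuple] = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        # reattach junction voxels adjacent to this branch so branches meet
        comp_ext = comp | (ndimage.binary_dilation(comp, structure=_CUBE) & junctions)
        vox = np.argwhere(comp_ext)
        if len(vox) < min_branch_voxels:
            continue
        pts = vox * spacing
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        t = centered @ axis
        span = float(t.max() - t.min())
        r_est = float(edt[comp].mean()) if comp.any() else float(edt[comp_ext].mean())
        # the medial axis of a capsule is its core segment; the discrete skeleton
        # overshoots into each rounded cap by about one voxel
        length = max(span - 2.0 * float(spacing.mean()), float(spacing.mean()))
        if length <= 0:
            continue
        v = axis * length
        if r_est <= 0:
            continue
        fits.append((centroid, v, r_est))

    return _orient_outward(fits)


def _orient_outward(fits) -> list[VesselSegment]:
    """Turn (centroid, axis-displacement, radius) fits into oriented segments.

    A fitted cylinder has no intrinsic direction, but the edge-insertion rule
    keys on start locations, so orientation decides the junction wiring.  Flow
    runs from the widest segment (the root) outward: starting there, segments
    are claimed in order of endpoint proximity to the already-oriented
    structure, and each one's ``sl`` is set to its endpoint nearest that
    structure.
    """
    if not fits:
        return []
    ends = [(c - v / 2, c + v / 2) for c, v, _ in fits]
    n = len(fits)
    root = max(range(n), key=lambda i: (fits[i][2], -i))
    flip = [False] * n
    oriented = {root}
    while len(oriented) < n:
        best = None  # (dist, i, flip_i)
        for i in range(n):
            if i in oriented:
                continue
            for j in oriented:
                for k, e in enumerate(ends[i]):
                    d = min(
                        float(np.linalg.norm(e - ends[j][0])),
                        float(np.linalg.norm(e - ends[j][1])),
                    )
                    # sl must be the end facing the oriented structure;
                    # end index 0 is already sl, end 1 needs a flip
                    if best is None or d < best[0]:
                        best = (d, i, k == 1)
        _, i, fl = best
        flip[i] = fl
        oriented.add(i)

    segments: list[VesselSegment] = []
    for (c, v, r), fl in zip(fits, flip):
        if fl:
            v = -v
        try:
            o_xy, o_xz, h = orientation_from_displacement(v)
        except ValueError:
            continue  # near-vertical branch, not representable
        if h <= 0:
            continue
        segments.append(VesselSegment(c, h, r, o_xy, o_xz))
    return segments
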