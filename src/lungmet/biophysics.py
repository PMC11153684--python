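"""Three-layer biophysical model of metastatic seeding.

The model composes three stages, evaluated deterministically (expected-value
semantics) for a query location tau:

1. **Primary growth.** The tumor grows by Gompertz kinetics,
   ``N(t) = K * exp(ln(N0/K) * exp(-a t))``, from an initial burden set by the
   tagged radius, until its equivalent radius reaches the nearest vessel
   surface.  From that contact time onward it sheds cells into the bloodstream
   at rate ``d`` (cells/hour).

2. **Bloodstream transport.** Shed cells ride the vessel tree from the segment
   nearest the tumor to the segment nearest tau.  Circulating cells die at rate
   ``lambda_decay`` (1/h), so the arriving population is ``N_in * exp(-lambda t)``
   with ``t`` the summed edge transit times from a steady Hagen-Poiseuille
   network solve.  Populations that fall below the extinction threshold ``xi``
   are set to zero — this rule implicitly bounds the survivable path length
   (``nu_t = ln(N_in/xi) / lambda`` in transit-time units).

3. **Colonization.** Arriving cells extravasate and settle in the healthy
   tissue around the target vessel.  Settlement saturates with supply and is
   weighted by the local healthy-tissue fraction and by a Gaussian falloff in
   the distance between tau and the vessel it is served by (cells leave the
   bloodstream toward the tissue *around* the vessel, not across the lung).

All rate/scale parameters live in :class:`ModelParams`; none of them are fixed
by clinical data, so every default is exposed in configuration and logged.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .errors import FlowError
from .segmentation import LungMask, TumorSpec
from .vesselgraph import (
    VesselGraph,
    nearest_vessel,
    segment_surface_distance,
    tree_path,
)

__all__ = [
    "ModelParams",
    "FlowField",
    "CellCountResult",
    "grow_tumor",
    "time_to_vessel_contact",
    "solve_flow",
    "transit_survival",
    "colonize",
    "predict_cell_count",
    "SeedingModel",
]


@dataclass
class ModelParams:
    """Tunable parameters of the seeding model (units in field comments).

    All defaults are order-of-magnitude choices, not fitted values; see the
    methods note for the reasoning behind each.
    """

    d: float = 1e6                   # shedding rate, cells/hour
    lambda_decay: float = 2.0        # bloodstream death rate, 1/hour
    xi: int = 100                    # extinction threshold, cells
    T: float = 720.0                 # stop time, hours
    growth_a: float = 0.01           # Gompertz rate, 1/hour
    growth_K: float = 1e12           # carrying capacity, cells
    cells_per_mm3: float = 1e6       # tumor cell density, cells/mm^3
    p_extravasate: float = 1e-3      # per-arrival extravasation probability scale
    colonization_capacity: float = 1e6   # local settlement saturation, cells
    colonization_radius: float = 3.0     # tissue-sampling ball radius, mm
    extravasation_spread: float = 5.0    # Gaussian falloff scale of settlement
                                         # around the serving vessel, mm
    inlet_velocity: float = 50.0     # effective advection speed at the inlet, mm/hour

    def __post_init__(self):
        for name in ("d", "lambda_decay", "growth_a", "growth_K", "cells_per_mm3",
                     "p_extravasate", "colonization_capacity", "colonization_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.xi < 1:
            raise ValueError("xi must be at least 1")
        if not self.T > 0:
            raise ValueError("T must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


def _radius_from_count(n_cells: float, cells_per_mm3: float) -> float:
    return (3.0 * n_cells / (4.0 * math.pi * cells_per_mm3)) ** (1.0 / 3.0)


def _count_from_radius(radius_mm: float, cells_per_mm3: float) -> float:
    return cells_per_mm3 * 4.0 / 3.0 * math.pi * radius_mm**3


def grow_tumor(tumor: TumorSpec, params: ModelParams, t: float) -> tuple[float, float]:
    """Gompertz cell count and equivalent spherical radius at time t (hours)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    n0 = _count_from_radius(tumor.size, params.cells_per_mm3)
    if n0 >= params.growth_K:
        raise ValueError("initial tumor burden exceeds the carrying capacity")
    n = params.growth_K * math.exp(math.log(n0 / params.growth_K) * math.exp(-params.growth_a * t))
    return n, _radius_from_count(n, params.cells_per_mm3)


def time_to_vessel_contact(tumor: TumorSpec, G: VesselGraph, params: ModelParams) -> float:
    """Smallest t at which the growing tumor's radius reaches the nearest vessel.

    Returns 0 if already in contact and ``math.inf`` if even the carrying-capacity
    radius cannot span the gap (the tumor then never sheds and c = 0 downstream).
    Solved by bisection to 1e-7 h.
    """
    _, dist = nearest_vessel(G, tumor.location, return_distance=True)
    if tumor.size >= dist:
        return 0.0
    k_radius = _radius_from_count(params.growth_K, params.cells_per_mm3)
    if k_radius < dist or params.growth_a == 0:
        return math.inf

    def gap(t: float) -> float:
        return grow_tumor(tumor, params, t)[1] - dist

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    lo = 0.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if gap(mid) >= 0:
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class FlowField:
    """Steady network flow on a vessel tree.

    ``edge_flow[(i, j)]`` (keys sorted, i < j) is the signed volumetric flow,
    positive from i to j; ``edge_velocity`` and ``edge_length`` give the mean
    advection speed and traversal length of the edge.  Pressures are in
    arbitrary units (unit inlet, zero leaves).
    """

    pressures: dict
    edge_flow: dict
    edge_velocity: dict
    edge_length: dict
    inlet: int

    def balance_residual(self, interior_nodes) -> float:
        """Largest relative net in/outflow over the given interior nodes."""
        scale = max((abs(q) for q in self.edge_flow.values()), default=1.0) or 1.0
        worst = 0.0
        for node in interior_nodes:
            net = 0.0
            for (i, j), q in self.edge_flow.items():
                if i == node:
                    net -= q
                elif j == node:
                    net += q
            worst = max(worst, abs(net) / scale)
        return worst


def solve_flow(
    tree: VesselGraph,
    inlet: int | None = None,
    inlet_velocity: float | None = None,
) -> FlowField:
    """Steady Poiseuille solve on the spanning tree.

    Edge conductance is ``min(r_i, r_j)^4 / L`` (Hagen-Poiseuille, constant
    factors absorbed), with ``L`` the endpoint gap plus the mean of the incident
    heights.  Unit pressure is imposed at the inlet (largest-radius segment by
    default) and zero at every leaf; flows follow from the pressure solve and
    velocities are flow / (pi r^2).  If ``inlet_velocity`` is given, flows and
    velocities are rescaled so the total inlet outflow moves at that speed.
    """
    n = len(tree.segments)
    if n == 0:
        raise FlowError("empty tree")
    g = tree.to_networkx()
    if n > 1 and not nx.is_connected(g):
        raise FlowError("flow solve requires a connected tree (isolated node present)")
    if len(tree.edges) != n - 1:
        raise FlowError("flow solve requires a spanning tree")
    if inlet is None:
        radii = [s.r for s in tree.segments]
        inlet = int(np.argmax(radii))  # ties -> lower id
    if n == 1:
        return FlowField({0: 1.0}, {}, {}, {}, inlet)

    cond: dict[tuple[int, int], float] = {}
    length: dict[tuple[int, int], float] = {}
    radius: dict[tuple[int, int], float] = {}
    for (i, j), _ in tree.edges.items():
        L = tree.endpoint_gap(i, j) + 0.5 * (tree.segments[i].h + tree.segments[j].h)
        r = min(tree.segments[i].r, tree.segments[j].r)
        cond[(i, j)] = r**4 / L
        length[(i, j)] = L
        radius[(i, j)] = r

    degree = dict(g.degree())
    leaves = [v for v in range(n) if degree[v] == 1 and v != inlet]
    if not leaves:
        raise FlowError("tree has no outlet leaves")

    A = np.zeros((n, n))
    b = np.zeros(n)
    dirichlet = {inlet: 1.0, **{leaf: 0.0 for leaf in leaves}}
    for node in range(n):
        if node in dirichlet:
            A[node, node] = 1.0
            b[node] = dirichlet[node]
        else:
            for (i, j), gij in cond.items():
                if node in (i, j):
                    other = j if node == i else i
                    A[node, node] += gij
                    A[node, other] -= gij
    try:
        p = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise FlowError(f"singular flow system: {exc}") from exc

    flow = {(i, j): gij * (p[i] - p[j]) for (i, j), gij in cond.items()}
    vel = {e: abs(q) / (math.pi * radius[e] ** 2) for e, q in flow.items()}
    if inlet_velocity is not None:
        out = sum(abs(q) for e, q in flow.items() if inlet in e)
        v_in = out / (math.pi * tree.segments[inlet].r ** 2)
        if v_in > 0:
            s = inlet_velocity / v_in
            flow = {e: q * s for e, q in flow.items()}
            vel = {e: v * s for e, v in vel.items()}
    return FlowField({i: float(p[i]) for i in range(n)}, flow, vel, length, inlet)


def transit_survival(
    path, flow: FlowField, N_in: float, params: ModelParams
) -> tuple[float, float]:
    """Population surviving transit along ``path`` and the transit time (hours).

    ``N_out = N_in * exp(-lambda t)``; any result below the extinction threshold
    xi is set to zero.  A zero-velocity edge means infinite transit and hence
    extinction.
    """
    if N_in < 0:
        raise ValueError("N_in must be non-negative")
    t = 0.0
    for a, b in zip(path[:-1], path[1:]):
        key = (min(a, b), max(a, b))
        if key not in flow.edge_velocity:
            raise FlowError(f"path edge {key} not present in the flow field")
        v = flow.edge_velocity[key]
        if v <= 0:
            return 0.0, math.inf
        t += flow.edge_length[key] / v
    n_out = N_in * math.exp(-params.lambda_decay * t)
    if n_out < params.xi:
        n_out = 0.0
    return n_out, t


# cached ball offsets for the tissue-fraction lookup, keyed by (radius, spacing)
_BALL_CACHE: dict = {}


def _ball_offsets(radius: float, spacing: tuple) -> tuple[np.ndarray, int]:
    key = (round(radius, 6), spacing)
    if key not in _BALL_CACHE:
        sp = np.asarray(spacing)
        ext = np.maximum(np.floor(radius / sp).astype(int), 0)
        rng = [np.arange(-e, e + 1) for e in ext]
        grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
        d = np.linalg.norm(grid * sp, axis=1)
        offs = grid[d <= radius]
        _BALL_CACHE[key] = (offs, len(offs))
    return _BALL_CACHE[key]


def tissue_fraction(lung: LungMask, site, radius_mm: float, spacing) -> float:
    """Healthy-tissue fraction in a fixed-radius ball around a world point.

    Zero if the site voxel itself lies outside the lungs.  Out-of-volume ball
    voxels count as non-tissue.
    """
    mask = lung.mask
    spacing = tuple(float(s) for s in spacing)
    idx = np.round(np.asarray(site, dtype=float) / np.asarray(spacing)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        return 0.0
    if not mask[tuple(idx)]:
        return 0.0
    offs, n_ball = _ball_offsets(radius_mm, spacing)
    pts = offs + idx
    ok = np.all((pts >= 0) & (pts < np.asarray(mask.shape)), axis=1)
    pts = pts[ok]
    return float(mask[pts[:, 0], pts[:, 1], pts[:, 2]].sum()) / n_ball


def colonize(
    arrived: float,
    site,
    lung: LungMask,
    params: ModelParams,
    spacing=(1.0, 1.0, 1.0),
    vessel_distance: float = 0.0,
) -> int:
    """Expected settled cell count at a site.

    ``settled = round(C * f_eff * (1 - exp(-p * arrived / C)))`` with C the local
    colonization capacity and ``f_eff`` the healthy-tissue ball fraction times a
    Gaussian falloff ``exp(-(vessel_distance/spread)^2)`` in the distance to the
    serving vessel.  Monotone and saturating in the arriving supply; zero without
    tissue; never exceeds the arrivals (conservation).
    """
    if arrived < 0:
        raise ValueError("arrived must be non-negative")
    if arrived == 0:
        return 0
    f = tissue_fraction(lung, site, params.colonization_radius, spacing)
    if params.extravasation_spread > 0 and vessel_distance > 0:
        f *= math.exp(-((vessel_distance / params.extravasation_spread) ** 2))
    if f <= 0:
        return 0
    cap = params.colonization_capacity
    settled = round(cap * f * (1.0 - math.exp(-params.p_extravasate * arrived / cap)))
    return int(min(settled, math.floor(arrived)))


@dataclass
class CellCountResult:
    """Outcome of one model evaluation at a query location tau."""

    c: int
    path_used: list | None
    transit_time: float
    arrived: float
    shed: float


class SeedingModel:
    """Prepared evaluator: fixes tumor, lungs, tree and flow, answers per-tau queries.

    Precomputes the vessel nearest the tumor, the contact time, the shed total
    and the per-target-segment transit survival, so grid sweeps stay cheap while
    remaining bit-identical to one-shot :func:`predict_cell_count` calls.
    """

    def __init__(
        self,
        G: VesselGraph,
        tumor: TumorSpec,
        lung: LungMask,
        params: ModelParams,
        spacing=(1.0, 1.0, 1.0),
        flow: FlowField | None = None,
    ):
        if not G.is_tree and len(G.segments) > 1 and len(G.edges) != len(G.segments) - 1:
            raise FlowError("SeedingModel expects the spanning tree")
        self.G = G
        self.tumor = tumor
        self.lung = lung
        self.params = params
        self.spacing = tuple(float(s) for s in spacing)
        self.source = nearest_vessel(G, tumor.location)
        self.t_contact = time_to_vessel_contact(tumor, G, params)
        window = params.T - self.t_contact
        self.shed = params.d * window if math.isfinite(self.t_contact) and window > 0 else 0.0
        self.flow = flow
        if self.flow is None and self.shed > 0:
            self.flow = solve_flow(G, inlet_velocity=params.inlet_velocity)
        self._survival: dict[int, tuple[float, float, list | None]] = {}

    def _arrival_at(self, target: int) -> tuple[float, float, list | None]:
        if target not in self._survival:
            path = tree_path(self.G, self.source, target)
            if path is None:
                self._survival[target] = (0.0, math.inf, None)
            else:
                n_out, t = transit_survival(path, self.flow, self.shed, self.params)
                self._survival[target] = (n_out, t, path)
        return self._survival[target]

    def predict(self, tau) -> CellCountResult:
        tau = np.asarray(tau, dtype=float)
        if self.shed <= 0:
            return CellCountResult(0, None, math.inf, 0.0, 0.0)
        target, vdist = nearest_vessel(self.G, tau, return_distance=True)
        arrived, t, path = self._arrival_at(target)
        settled = colonize(
            arrived, tau, self.lung, self.params,
            spacing=self.spacing, vessel_distance=vdist,
        )
        return CellCountResult(settled, path, t, arrived, self.shed)


def predict_cell_count(
    G: VesselGraph,
    tumor: TumorSpec,
    lung: LungMask,
    tau,
    params: ModelParams,
    spacing=(1.0, 1.0, 1.0),
    flow: FlowField | None = None,
) -> CellCountResult:
    """Full model chain M(G, p[l], I, tau) -> c for a single query location."""
    return SeedingModel(G, tumor, lung, params, spacing=spacing, flow=flow).predict(tau)
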