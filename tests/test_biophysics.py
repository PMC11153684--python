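"""Growth, flow, transport and colonization layers of the seeding model."""
import math

import numpy as np
import pytest

from lungmet.biophysics import (
    ModelParams,
    SeedingModel,
    colonize,
    grow_tumor,
    predict_cell_count,
    solve_flow,
    time_to_vessel_contact,
    transit_survival,
)
from lungmet.errors import FlowError
from lungmet.segmentation import LungMask, TumorSpec
from lungmet.vesselgraph import GraphBuildParams, VesselGraph, VesselSegment, build_graph

from tests.test_vesselgraph import seg_x


def chain_tree(radii=(1.0, 0.8, 0.6), h=8.0, start=(2.0, 8.0, 8.0)):
    """Three x-aligned touching segments forming a chain tree."""
    segs = []
    cursor = np.asarray(start, dtype=float)
    for r in radii:
        s = seg_x(cursor, h, r)
        segs.append(s)
        cursor = s.el
    return build_graph(segs, GraphBuildParams(R0=1.0))


@pytest.fixture
def full_lung():
    return LungMask(np.ones((16, 16, 16), dtype=bool))


class TestGrowth:
    def test_time_zero_returns_initial_count(self):
        p = ModelParams()
        tumor = TumorSpec((5.0, 5.0, 5.0), 3.0)
        n0 = p.cells_per_mm3 * 4 / 3 * math.pi * 27
        n, r = grow_tumor(tumor, p, 0.0)
        assert n == pytest.approx(n0, rel=1e-12)
        assert r == pytest.approx(3.0, rel=1e-12)

    def test_asymptote_at_carrying_capacity(self):
        p = ModelParams(growth_a=1.0)
        n, _ = grow_tumor(TumorSpec((0, 0, 0), 1.0), p, 50.0)
        assert n == pytest.approx(p.growth_K, rel=1e-6)

    def test_closed_form_at_inflection_start(self):
        # N0 = K/e, a = 1, t = 1 -> N = K * exp(-1/e)
        K = 1e12
        r0 = (3.0 * (K / math.e) / (4.0 * math.pi * 1e6)) ** (1 / 3)
        p = ModelParams(growth_a=1.0, growth_K=K, cells_per_mm3=1e6)
        n, _ = grow_tumor(TumorSpec((0, 0, 0), r0), p, 1.0)
        assert n == pytest.approx(K * math.exp(-1.0 / math.e), rel=1e-9)


class TestTimeToContact:
    def test_touching_vessel_is_zero(self):
        G = chain_tree()
        tumor = TumorSpec(G.segments[0].c, 5.0)  # radius exceeds the bore
        assert time_to_vessel_contact(tumor, G, ModelParams()) == 0.0

    def test_unreachable_returns_infinity(self):
        G = chain_tree()
        p = ModelParams(growth_K=1e6)  # K-radius ~0.62 mm
        tumor = TumorSpec(G.segments[0].c + np.array([0, 500.0, 0]), 0.5)
        assert time_to_vessel_contact(tumor, G, p) == math.inf

    def test_inverts_growth_curve(self):
        p = ModelParams(growth_a=0.05)
        G = chain_tree()
        t_target = 10.0
        _, r10 = grow_tumor(TumorSpec((0, 0, 0), 2.0), p, t_target)
        # place the tumor so the vessel surface sits exactly r10 away
        s = G.segments[0]
        mid = (s.sl + s.el) / 2
        tumor = TumorSpec(mid + np.array([0.0, r10 + s.r, 0.0]), 2.0)
        t = time_to_vessel_contact(tumor, G, p)
        assert t == pytest.approx(t_target, abs=1e-5)


def series_conductance(gs):
    inv = sum(1.0 / g for g in gs)
    return 1.0 / inv


class TestFlow:
    def test_single_edge_velocity(self):
        G = chain_tree(radii=(1.0, 0.8))
        f = solve_flow(G)
        (e, q), = f.edge_flow.items()
        assert f.edge_velocity[e] == pytest.approx(abs(q) / (math.pi * 0.8**2))

    def test_symmetric_y_splits_half_half(self):
        root = seg_x((0.0, 20.0, 20.0), 8.0, 2.0)
        c1 = VesselSegment.from_start(root.el, 8.0, 1.5, 7 * np.pi / 4 + 0.4, np.pi / 2)
        c2 = VesselSegment.from_start(root.el, 8.0, 1.5, 7 * np.pi / 4 - 0.4, np.pi / 2)
        from lungmet.vesselgraph import max_radius_spanning_tree
        G = max_radius_spanning_tree(build_graph([root, c1, c2], GraphBuildParams(R0=1.0)))
        f = solve_flow(G)
        flows = sorted(abs(q) for q in f.edge_flow.values())
        assert flows[0] == pytest.approx(flows[1], rel=1e-12)
        total = sum(abs(q) for (i, j), q in f.edge_flow.items() if 0 in (i, j))
        assert flows[0] == pytest.approx(total / 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_balance_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        segs = [seg_x((2.0, 30.0, 30.0), 8.0, 3.0)]
        for i in range(1, 10):
            parent = segs[int(rng.integers(0, i))]
            jitter = rng.uniform(-2, 2, 3)
            segs.append(seg_x(parent.el + jitter, float(rng.uniform(4, 9)),
                              float(rng.uniform(0.4, 2.5))))
        G = build_graph(segs, GraphBuildParams(R0=4.0))
        from lungmet.vesselgraph import max_radius_spanning_tree
        tree = max_radius_spanning_tree(G)
        f = solve_flow(tree)
        import networkx as nx
        g = tree.to_networkx()
        interior = [v for v in g.nodes
                    if g.degree(v) > 1 and v != f.inlet]
        assert f.balance_residual(interior) < 1e-9

    def test_chain_matches_series_circuit_reduction(self):
        G = chain_tree(radii=(1.0, 0.8, 0.6), h=8.0)
        f = solve_flow(G)
        # independent series-resistor oracle with the same conductance law
        gs = []
        for (i, j) in sorted(G.edges):
            L = G.endpoint_gap(i, j) + 0.5 * (G.segments[i].h + G.segments[j].h)
            gs.append(min(G.segments[i].r, G.segments[j].r) ** 4 / L)
        q_expected = series_conductance(gs) * 1.0  # unit pressure drop
        for q in f.edge_flow.values():
            assert abs(q) == pytest.approx(q_expected, rel=1e-9)

    def test_disconnected_fails(self):
        segs = [seg_x((0, 0, 0), 4, 1), seg_x((50, 50, 50), 4, 1)]
        with pytest.raises(FlowError):
            solve_flow(VesselGraph(segs, {}, is_tree=True))


class TestTransit:
    def test_no_decay_preserves_population(self):
        G = chain_tree()
        f = solve_flow(G, inlet_velocity=50.0)
        p = ModelParams(lambda_decay=0.0, xi=1)
        n, t = transit_survival([0, 1, 2], f, 1e5, p)
        assert n == pytest.approx(1e5)
        assert t > 0

    def test_closed_form_with_threshold(self):
        # N = 1000, t = 10 h, lambda = 0.1/h -> 1000 e^-1 = 367.88; xi=400 -> 0
        G = chain_tree(radii=(1.0, 0.8))
        f = solve_flow(G)
        (e,) = list(f.edge_velocity)
        f.edge_velocity[e] = f.edge_length[e] / 10.0  # force t = 10 h
        p_pass = ModelParams(lambda_decay=0.1, xi=100)
        n, t = transit_survival([0, 1], f, 1000.0, p_pass)
        assert t == pytest.approx(10.0)
        assert n == pytest.approx(1000.0 * math.exp(-1.0), abs=1e-9)
        p_cut = ModelParams(lambda_decay=0.1, xi=400)
        n_cut, _ = transit_survival([0, 1], f, 1000.0, p_cut)
        assert n_cut == 0.0

    def test_entry_below_threshold_dies(self):
        G = chain_tree()
        f = solve_flow(G, inlet_velocity=50.0)
        p = ModelParams(xi=100)
        n, _ = transit_survival([0, 1], f, 50.0, p)
        assert n == 0.0

    def test_survivable_length_bound_matches_extinction_onset(self):
        # nu_t = ln(N_in/xi)/lambda in transit-time units
        p = ModelParams(lambda_decay=0.5, xi=1000)
        n_in = 1e6
        nu_t = math.log(n_in / p.xi) / p.lambda_decay
        G = chain_tree(radii=(1.0, 0.8))
        f = solve_flow(G)
        (e,) = list(f.edge_velocity)
        for frac in (0.99, 1.01):
            f.edge_velocity[e] = f.edge_length[e] / (nu_t * frac)
            n, _ = transit_survival([0, 1], f, n_in, p)
            assert (n > 0) == (frac < 1)


class TestColonize:
    def test_site_outside_lung_settles_nothing(self, full_lung):
        assert colonize(1e9, (100.0, 100.0, 100.0), full_lung, ModelParams()) == 0

    def test_zero_arrivals_settle_nothing(self, full_lung):
        assert colonize(0.0, (8.0, 8.0, 8.0), full_lung, ModelParams()) == 0

    def test_saturates_at_capacity(self, full_lung):
        p = ModelParams(colonization_capacity=5000.0, p_extravasate=1.0)
        settled = colonize(1e12, (8.0, 8.0, 8.0), full_lung, p)
        assert settled == pytest.approx(5000, abs=1)

    def test_monotone_in_arrivals(self, full_lung):
        p = ModelParams()
        vals = [colonize(a, (8.0, 8.0, 8.0), full_lung, p)
                for a in (0, 1e4, 1e6, 1e8, 1e10)]
        assert vals == sorted(vals)

    def test_distance_attenuation_reduces_settlement(self, full_lung):
        p = ModelParams()
        near = colonize(1e9, (8.0, 8.0, 8.0), full_lung, p, vessel_distance=0.0)
        far = colonize(1e9, (8.0, 8.0, 8.0), full_lung, p, vessel_distance=10.0)
        assert far < near


class TestPredictCellCount:
    def test_no_shedding_window_gives_zero(self, full_lung):
        G = chain_tree()
        tumor = TumorSpec(G.segments[0].c + np.array([0.0, 10.0, 0.0]), 0.5)
        p = ModelParams(T=1e-6, growth_a=1e-4)
        res = predict_cell_count(G, tumor, full_lung, (8.0, 8.0, 8.0), p)
        assert res.c == 0

    def test_degenerate_path_equals_direct_colonization(self, full_lung):
        G = chain_tree()
        s = G.segments[0]
        tumor = TumorSpec(s.c, 5.0)  # touching -> t_contact = 0
        tau = (s.sl + s.el) / 2  # on the source segment's centerline
        p = ModelParams()
        res = predict_cell_count(G, tumor, full_lung, tau, p)
        shed = p.d * p.T
        assert res.arrived == pytest.approx(shed)
        assert res.c == colonize(shed, tau, full_lung, p, vessel_distance=0.0)

    def test_hand_stepped_three_segment_chain(self, full_lung):
        """Full chain vs an explicit arithmetic walk-through of the same model."""
        radii = (1.0, 0.8, 0.6)
        h = 8.0
        G = chain_tree(radii=radii, h=h)
        s0, s2 = G.segments[0], G.segments[2]
        tumor = TumorSpec(s0.c, 5.0)
        tau = s2.el
        p = ModelParams()
        res = predict_cell_count(G, tumor, full_lung, tau, p)

        # --- independent hand computation -------------------------------
        shed = p.d * p.T  # contact at t=0
        L = h  # touching endpoints: gap 0, symmetric length (h+h)/2 + 0
        g1 = 0.8**4 / L
        g2 = 0.6**4 / L
        q = 1.0 / (1.0 / g1 + 1.0 / g2)  # series, unit pressure drop
        v1 = q / (math.pi * 0.8**2)
        v2 = q / (math.pi * 0.6**2)
        v_inlet_raw = q / (math.pi * 1.0**2)
        scale = p.inlet_velocity / v_inlet_raw
        t_transit = L / (v1 * scale) + L / (v2 * scale)
        arrived = shed * math.exp(-p.lambda_decay * t_transit)
        if arrived < p.xi:
            arrived = 0.0
        # tau is on the lung border: the tissue ball is half inside the volume
        from lungmet.biophysics import tissue_fraction
        f = tissue_fraction(full_lung, tau, p.colonization_radius, (1.0, 1.0, 1.0))
        expected = round(p.colonization_capacity * f *
                         (1 - math.exp(-p.p_extravasate * arrived /
                                       p.colonization_capacity)))
        assert res.transit_time == pytest.approx(t_transit, rel=1e-9)
        assert res.arrived == pytest.approx(arrived, rel=1e-9)
        assert res.c == expected

    def test_monotonicity_in_decay_stoptime_and_shedding(self, full_lung):
        G = chain_tree()
        tumor = TumorSpec(G.segments[0].c, 5.0)
        tau = G.segments[2].el
        base = dict(d=1e6, T=720.0, lambda_decay=2.0)
        cs = [predict_cell_count(G, tumor, full_lung, tau,
                                 ModelParams(**{**base, "lambda_decay": lam})).c
              for lam in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert cs == sorted(cs, reverse=True)
        cs = [predict_cell_count(G, tumor, full_lung, tau,
                                 ModelParams(**{**base, "T": T})).c
              for T in (10.0, 100.0, 720.0)]
        assert cs == sorted(cs)
        cs = [predict_cell_count(G, tumor, full_lung, tau,
                                 ModelParams(**{**base, "d": d})).c
              for d in (1e3, 1e5, 1e7)]
        assert cs == sorted(cs)

    def test_conservation_settled_arrived_shed(self, full_lung):
        G = chain_tree()
        tumor = TumorSpec(G.segments[0].c, 5.0)
        p = ModelParams()
        model = SeedingModel(G, tumor, full_lung, p)
        rng = np.random.default_rng(0)
        for _ in range(20):
            res = model.predict(rng.uniform(0, 15, 3))
            assert res.c <= res.arrived + 1e-9
            assert res.arrived <= res.shed + 1e-9
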