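"""Network flow: Poiseuille closed forms, conservation, brute-force oracles,
and the synthetic generator's contract."""

import numpy as np
import pytest

from chemocycle.rheology import apparent_viscosity, relative_viscosity
from chemocycle.vasculature import (
    INLET,
    INTERIOR,
    OUTLET,
    VascularNetwork,
    WallParams,
    boundary_flow_imbalance,
    generate_synthetic_network,
    read_network_csv,
    solve_network_flow,
    starling_leak,
    write_network_csv,
)


def single_segment(d_um=10.0, length=1e-4, p_in=2000.0, p_out=1000.0):
    return VascularNetwork(
        positions=np.array([[0.0, 0.0], [length, 0.0]]),
        kinds=np.array([INLET, OUTLET]),
        edges=np.array([[0, 1]]),
        diam_um=np.array([d_um]),
        hematocrit=np.array([0.45]),
        inlet_pressure=p_in,
        outlet_pressure=p_out,
    )


class TestStarlingLeak:
    def test_equilibrium_gives_zero(self):
        # P_b - P_i exactly balances the osmotic term
        q = starling_leak(10.0, 1e-4, 1e-11, 1500.0, 1000.0, 0.5, 3000.0, 2000.0)
        assert q == pytest.approx(0.0, abs=1e-25)

    def test_closed_form_without_osmosis(self):
        q = starling_leak(10.0, 1e-4, 1e-11, 1000.0, 0.0, 0.0, 2660.0, 2000.0)
        assert q == pytest.approx(np.pi * 10e-6 * 1e-4 * 1e-11 * 1000.0, rel=1e-14)

    def test_linear_in_wall_conductivity(self):
        args = (10.0, 1e-4, 1500.0, 200.0, 0.82, 2660.0, 2000.0)
        q1 = starling_leak(args[0], args[1], 1e-11, *args[2:])
        q2 = starling_leak(args[0], args[1], 2e-11, *args[2:])
        assert q2 == pytest.approx(2.0 * q1, rel=1e-14)


class TestNetworkFlow:
    def test_single_segment_poiseuille_closed_form(self):
        net = single_segment()
        net.evaluate_rheology(1e-3)
        solve_network_flow(net)
        mu = apparent_viscosity(1e-3, relative_viscosity(10.0, 0.45))
        q_exact = np.pi * (10e-6) ** 4 * 1000.0 / (128.0 * mu * 1e-4)
        assert net.segment_flow[0] == pytest.approx(q_exact, rel=1e-12)

    def test_conservation_without_leakage(self, default_network):
        net = default_network.copy()
        net.evaluate_rheology()
        solve_network_flow(net)
        assert boundary_flow_imbalance(net) < 1e-10

    def test_y_junction_against_hand_assembled_system(self):
        # inlet -- junction -- two outlets, with Starling leakage; the nodal
        # system is assembled by hand (dense 4x4) and solved independently
        pos = np.array([[0, 0], [1e-4, 0], [2e-4, 0.5e-4], [2e-4, -0.5e-4]])
        net = VascularNetwork(
            positions=pos,
            kinds=np.array([INLET, INTERIOR, OUTLET, OUTLET]),
            edges=np.array([[0, 1], [1, 2], [1, 3]]),
            diam_um=np.array([12.0, 8.0, 9.0]),
            hematocrit=np.full(3, 0.45),
            inlet_pressure=3000.0,
            outlet_pressure=1200.0,
        )
        net.evaluate_rheology(1e-3)
        wall = WallParams(L_p=1e-11, sigma_s=0.8, pi_b=2660.0, pi_i=2000.0)
        p_i = np.array([100.0, 150.0, 120.0])
        solve_network_flow(net, p_i, wall)

        g = net.conductances()
        k = np.pi * net.diam_um * 1e-6 * net.lengths() * 1e-11
        sink = p_i + 0.8 * (2660.0 - 2000.0)
        A = np.zeros((4, 4))
        b = np.zeros(4)
        for (a_, b_), gi, ki, si in zip(net.edges, g, k, sink):
            for u, v in ((a_, b_), (b_, a_)):
                A[u, u] += gi + ki / 4.0
                A[u, v] += -gi + ki / 4.0
                b[u] += ki / 2.0 * si
        # Dirichlet rows for boundary nodes
        for node, p in ((0, 3000.0), (2, 1200.0), (3, 1200.0)):
            A[node, :] = 0.0
            A[node, node] = 1.0
            b[node] = p
        expected = np.linalg.solve(A, b)
        assert net.node_pressure == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_random_small_network_matches_dense_solve(self, seed):
        rng = np.random.default_rng(seed)
        n = 14
        pos = rng.uniform(0, 1e-3, size=(n, 2))
        # random connected graph: spanning chain plus extra chords
        edges = [[i, i + 1] for i in range(n - 1)]
        extra = rng.integers(0, n, size=(6, 2))
        edges += [[a, b] for a, b in extra if a != b]
        edges = np.unique(np.sort(np.asarray(edges), axis=1), axis=0)
        kinds = np.full(n, INTERIOR, dtype=np.int8)
        kinds[0] = INLET
        kinds[n - 1] = OUTLET
        net = VascularNetwork(
            positions=pos, kinds=kinds, edges=edges,
            diam_um=rng.uniform(6, 20, size=edges.shape[0]),
            hematocrit=np.full(edges.shape[0], 0.45),
            inlet_pressure=3330.0, outlet_pressure=1330.0,
        )
        net.evaluate_rheology(1e-3)
        wall = WallParams(L_p=2.1e-11, sigma_s=0.82, pi_b=2660.0, pi_i=2000.0)
        p_i = rng.uniform(0, 500, size=edges.shape[0])
        solve_network_flow(net, p_i, wall)

        g = net.conductances()
        k = np.pi * net.diam_um * 1e-6 * net.lengths() * 2.1e-11
        sink = p_i + 0.82 * 660.0
        A = np.zeros((n, n))
        b = np.zeros(n)
        for (u, v), gi, ki, si in zip(net.edges, g, k, sink):
            for a_, b_ in ((u, v), (v, u)):
                A[a_, a_] += gi + ki / 4.0
                A[a_, b_] += -gi + ki / 4.0
                b[a_] += ki / 2.0 * si
        A[0, :] = 0.0; A[0, 0] = 1.0; b[0] = 3330.0
        A[n - 1, :] = 0.0; A[n - 1, n - 1] = 1.0; b[n - 1] = 1330.0
        expected = np.linalg.solve(A, b)
        assert np.allclose(net.node_pressure, expected, rtol=1e-10, atol=1e-8)

    def test_errors_on_missing_boundary_or_disconnection(self):
        net = single_segment()
        net.kinds = np.array([INTERIOR, INTERIOR], dtype=np.int8)
        net.evaluate_rheology()
        with pytest.raises(ValueError):
            solve_network_flow(net)


class TestGenerator:
    def test_determinism(self):
        a = generate_synthetic_network(1e-3, 20000.0, seed=7)
        b = generate_synthetic_network(1e-3, 20000.0, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.diam_um, b.diam_um)

    @pytest.mark.parametrize("seed", [1, 2, 11])
    def test_realized_surface_density_within_band(self, seed):
        net = generate_synthetic_network(2e-3, 20000.0, seed=seed, tumor_radius=0.5e-3)
        assert 18000.0 <= net.surface_per_volume(2e-3) <= 22000.0

    def test_structure_contract(self):
        net = generate_synthetic_network(1e-3, 20000.0, seed=5)
        assert net.is_connected()
        assert np.any(net.kinds == INLET) and np.any(net.kinds == OUTLET)
        # inlets/outlets sit on the domain boundary
        for kind, x in ((INLET, 0.0), (OUTLET, 1e-3)):
            sel = net.kinds == kind
            assert np.allclose(net.positions[sel, 0], x, atol=1e-12)
        assert np.all(net.diam_um > 1.1)
        assert np.all(net.lengths() > 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_network(1e-3, 0.0, seed=1)
        with pytest.raises(ValueError):
            generate_synthetic_network(0.0, 20000.0, seed=1)

    def test_intravascular_velocity_scale(self, default_flow):
        # peak capillary-bed velocity is of order 0.1 m/s on the default
        # geometry (order-of-magnitude check, not equality)
        _, flow = default_flow
        assert 0.01 <= flow.max_intravascular_velocity() <= 1.0


def test_network_csv_round_trip(tmp_path):
    net = generate_synthetic_network(1e-3, 20000.0, seed=9)
    write_network_csv(net, tmp_path / "nodes.csv", tmp_path / "segments.csv")
    back = read_network_csv(tmp_path / "nodes.csv", tmp_path / "segments.csv")
    assert np.allclose(back.positions, net.positions)
    assert np.array_equal(back.edges, net.edges)
    assert np.allclose(back.diam_um, net.diam_um)
    assert np.array_equal(back.kinds, net.kinds)
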