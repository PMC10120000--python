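import networkx as nx
import numpy as np
import pytest

from neuroperc import (
    EdgeOrdering,
    EPDConfig,
    GCSPParams,
    clustering_and_pathlength,
    erdos_renyi_gnm,
    gcsp_P,
    preferential_attachment,
    simulate_epd,
    simulate_gcsp_growth,
    spatial_random,
    targeted_attack,
    watts_strogatz,
)
from neuroperc.fitting import fit_alpha, fit_alpha_trajectory


class TestGcspGrowth:
    def test_first_step_always_branches(self):
        for seed in range(5):
            _, traj = simulate_gcsp_growth(GCSPParams(alpha=11.0, N=20), 3.0, seed)
            assert traj.rho[0] == pytest.approx(2 / 20)

    def test_trajectory_bookkeeping(self):
        N = 50
        _, traj = simulate_gcsp_growth(GCSPParams(alpha=8.0, N=N), 10.0, seed=1)
        np.testing.assert_allclose(np.diff(traj.kappa), 2.0 / N)
        steps = np.diff(np.concatenate([[1 / N], traj.rho]))
        assert set(np.round(steps * N).astype(int)) <= {0, 1}

    def test_single_cluster_throughout(self):
        g, traj = simulate_gcsp_growth(GCSPParams(alpha=11.0, N=100), 10.0, seed=4)
        # the grown graph is connected and node recruitment was one at a time
        recruited = int(round(traj.rho[-1] * 100))
        assert nx.number_connected_components(g) == 100 - recruited + 1
        sub = g.subgraph(max(nx.connected_components(g), key=len))
        assert sub.number_of_nodes() == recruited

    def test_mean_trajectory_matches_closed_form(self):
        # Monte-Carlo mean of rho(kappa) vs the large-N closed form, 2 SE band
        N, n_seeds = 300, 40
        params = GCSPParams(alpha=11.0, N=N)
        rhos = []
        for seed in range(n_seeds):
            _, traj = simulate_gcsp_growth(params, 30.0, seed)
            rhos.append(traj.rho)
        rhos = np.array(rhos)
        kappa = 2.0 * np.arange(1, rhos.shape[1] + 1) / N
        mean = rhos.mean(axis=0)
        se = rhos.std(axis=0, ddof=1) / np.sqrt(n_seeds)
        theory = gcsp_P(kappa, params)
        mask = kappa >= 1.0  # skip the strongly finite-size early regime
        # allow the finite-size offset on top of the Monte-Carlo band
        assert np.all(np.abs(mean[mask] - theory[mask]) < 2 * se[mask] + 2.0 / N * 5)

    def test_infeasible_k_final(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_gcsp_growth(GCSPParams(alpha=5.0, N=10), 20.0, seed=0)


class TestEpd:
    def test_density_follows_aging_rule(self, small_epd):
        config, conn, _ = small_epd
        T = conn.n_edges
        densities = sorted((d for _, d in conn.edges.values()), reverse=True)
        expected = config.density_scale ** (T - 1 - np.arange(T))
        np.testing.assert_allclose(densities, sorted(expected, reverse=True), rtol=1e-9)

    def test_lengths_match_final_coordinates(self, small_epd):
        _, conn, _ = small_epd
        for (i, j), (length, _) in conn.edges.items():
            assert length == pytest.approx(
                float(np.linalg.norm(conn.coordinates[i] - conn.coordinates[j]))
            )

    def test_terminal_giant_fraction_matches_trajectory(self, small_epd):
        from neuroperc import giant_fraction

        _, conn, traj = small_epd
        assert giant_fraction(conn) == pytest.approx(traj.rho[-1])

    def test_density_attack_is_time_reversed_growth(self, small_epd):
        _, conn, traj = small_epd
        curve = targeted_attack(
            conn, EdgeOrdering(property="tract_density", direction="increasing")
        )
        np.testing.assert_array_equal(curve.giant_fraction[:-1], traj.rho[::-1])
        assert curve.giant_fraction[-1] == pytest.approx(1 / conn.n_nodes)

    def test_length_attack_approximates_reversed_growth(self):
        # at the full published scale the length order is a noisy version of
        # the creation order, so the curve only approximately replays growth —
        # the origin of the higher fitted alpha for distance attack
        conn, traj = simulate_epd(EPDConfig(seed=123))
        curve = targeted_attack(
            conn,
            EdgeOrdering(property="tract_length", direction="increasing"),
            record_census=False,
        )
        delta = np.abs(curve.giant_fraction[:-1] - traj.rho[::-1])
        assert delta.mean() < 0.05

    def test_reproducible_for_fixed_seed(self):
        config = EPDConfig(N=40, k_final=6.0, seed=9)
        c1, t1 = simulate_epd(config)
        c2, t2 = simulate_epd(config)
        assert c1.edges == c2.edges
        np.testing.assert_array_equal(c1.coordinates, c2.coordinates)
        np.testing.assert_array_equal(t1.rho, t2.rho)


class TestErdosRenyi:
    def test_complete_graph(self):
        g = erdos_renyi_gnm(4, 6, seed=0)
        assert g.number_of_edges() == 6
        assert nx.density(g) == 1.0

    def test_exact_edge_count(self):
        g = erdos_renyi_gnm(100, 250, seed=1)
        assert g.number_of_nodes() == 100
        assert g.number_of_edges() == 250

    def test_clustering_near_analytic_expectation(self):
        # E[C] = <k>/(N-1) = 29.9/726 ~ 0.0412 for the brain-matched ER graph
        vals = [
            clustering_and_pathlength(erdos_renyi_gnm(727, 10869, seed=s))[
                "mean_clustering"
            ]
            for s in range(3)
        ]
        assert np.mean(vals) == pytest.approx(29.9 / 726, rel=0.1)

    def test_infeasible_m(self):
        with pytest.raises(ValueError):
            erdos_renyi_gnm(4, 7, seed=0)


class TestPreferentialAttachment:
    def test_m1_yields_tree(self):
        g, _ = preferential_attachment(50, m=1, exponent=1.0, seed=0)
        assert g.number_of_edges() == 49
        assert nx.is_connected(g)

    def test_exponent_zero_is_uniform_attachment(self):
        g, _ = preferential_attachment(400, m=2, exponent=0.0, seed=1)
        assert g.number_of_edges() == 2 * (400 - 2)
        # uniform attachment has an exponential-ish degree tail, far less
        # skewed than linear PA
        g_lin, _ = preferential_attachment(400, m=2, exponent=1.0, seed=1)
        assert max(dict(g.degree()).values()) < max(dict(g_lin.degree()).values())

    def test_trajectory_slope_after_burn_in(self):
        for m in (1, 3):
            _, traj = preferential_attachment(500, m=m, exponent=1.0, seed=2)
            late = slice(len(traj.kappa) // 2, None)
            slope = np.polyfit(traj.kappa[late], traj.rho[late], 1)[0]
            assert slope == pytest.approx(1.0 / (2 * m), rel=0.05)

    def test_m_too_large(self):
        with pytest.raises(ValueError):
            preferential_attachment(5, m=5, exponent=1.0, seed=0)


class TestWattsStrogatz:
    def test_lattice_clustering_formula(self):
        k = 6
        c = watts_strogatz(101, k_ring=k, p_rewire=0.0, seed=0)
        out = clustering_and_pathlength(c.to_networkx())
        assert out["mean_clustering"] == pytest.approx(3 * (k - 2) / (4 * (k - 1)))

    def test_fully_rewired_limit(self):
        c = watts_strogatz(1000, k_ring=10, p_rewire=1.0, seed=0)
        out = clustering_and_pathlength(c.to_networkx())
        assert out["mean_clustering"] == pytest.approx(10 / 1000, abs=0.01)

    def test_lattice_has_abrupt_percolation_drop(self):
        # the ring lattice stays fully connected down to <k> = 2 under
        # increasing-distance attack — a critical point the GCSP curve lacks
        c = watts_strogatz(101, k_ring=6, p_rewire=0.0, seed=0)
        curve = targeted_attack(c, EdgeOrdering(property="tract_length", tie_seed=0))
        at_two = np.flatnonzero(np.isclose(curve.mean_degree, 2.0))[0]
        assert curve.giant_fraction[at_two] == 1.0
        assert gcsp_P(2.0, GCSPParams(alpha=11.0)) < 0.5

    def test_invalid_k_ring(self):
        with pytest.raises(ValueError):
            watts_strogatz(10, k_ring=3, p_rewire=0.0, seed=0)


class TestSpatialRandom:
    def test_lengths_within_ball_diameter(self):
        c = spatial_random(100, 300, seed=0)
        lengths = [ln for ln, _ in c.edges.values()]
        assert max(lengths) <= 2.0

    def test_complete_geometric_graph(self):
        c = spatial_random(12, 66, seed=1)
        assert c.n_edges == 66

    def test_distance_attack_poorly_fit_by_gcsp(self):
        # spatially random edges decimate like a random graph; the GCSP
        # closed form cannot absorb that shape
        c = spatial_random(300, 2250, seed=2)  # <k> = 15
        curve = targeted_attack(c, EdgeOrdering(property="tract_length"))
        fit = fit_alpha(curve)
        assert fit.sse > 0.01


class TestClusteringAndPathlength:
    def test_triangle(self, triangle):
        out = clustering_and_pathlength(triangle)
        assert out["mean_clustering"] == 1.0
        assert out["mean_shortest_path"] == 1.0

    def test_star(self):
        g = nx.star_graph(4)
        out = clustering_and_pathlength(g)
        assert out["mean_clustering"] == 0.0
        assert out["mean_shortest_path"] == pytest.approx(1.6)

    def test_disconnected_uses_giant_cluster(self):
        g = nx.Graph([(0, 1), (1, 2), (3, 4)])
        with pytest.warns(UserWarning, match="giant cluster"):
            out = clustering_and_pathlength(g)
        assert out["mean_shortest_path"] == pytest.approx((1 + 1 + 2) / 3)
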