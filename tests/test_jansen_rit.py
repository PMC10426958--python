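"""Jansen-Rit node equations, coupling, integration and fixed points."""

import numpy as np
import pytest

import thalnet as tn
from thalnet.jansen_rit import (
    CouplingConfig,
    DriveConfig,
    JRParameters,
    SimulationConfig,
    SimulationResult,
    bifurcation_scan,
    fixed_point,
    fixed_points,
    jr_derivatives,
    network_input,
    sigmoid,
    simulate_network,
)


class TestSigmoid:
    def test_midpoint_is_vmax(self, jr):
        assert sigmoid(jr.v0, jr) == pytest.approx(jr.vmax)
        assert sigmoid(6.0, jr) == pytest.approx(0.0025)

    def test_saturation_limits(self, jr):
        assert sigmoid(1e4, jr) == pytest.approx(2 * jr.vmax)
        assert sigmoid(-1e4, jr) == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("v", np.linspace(-60, 60, 13))
    def test_bounds_and_monotonicity(self, v, jr):
        s = sigmoid(v, jr)
        assert 0 < s < 2 * jr.vmax
        assert sigmoid(v + 0.5, jr) > s


class TestDerivatives:
    def test_position_derivatives_are_velocities(self, jr):
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = rng.normal(size=6) * 10
            d = jr_derivatives(state, rng.uniform(0, 0.3), jr)
            np.testing.assert_allclose(d[:3], state[3:])

    def test_zero_state_zero_input_closed_form(self, jr):
        # ydot3 = A*a*S[0] with S[0] = 2*vmax / (1 + exp(r*v0))
        d = jr_derivatives(np.zeros(6), 0.0, jr)
        s0 = 2 * jr.vmax / (1 + np.exp(jr.r * jr.v0))
        assert d[3] == pytest.approx(jr.A * jr.a * s0)
        assert d[4] == pytest.approx(jr.A * jr.a * jr.C2 * s0)
        assert d[5] == pytest.approx(jr.B * jr.b * jr.C4 * s0)

    @pytest.mark.parametrize("p", [0.0, 0.05, 0.09])
    def test_vanishes_at_fixed_point(self, p, jr):
        root = fixed_point(jr, p)
        d = jr_derivatives(root.y, p, jr)
        assert np.abs(d).max() < 1e-10


class TestNetworkInput:
    def test_uncoupled_is_drive_plus_noise(self, toy_sc):
        drive = DriveConfig.uniform(toy_sc.n_regions, p=0.11, eta=0.0)
        val = network_input(0, np.zeros(toy_sc.n_regions), drive,
                            CouplingConfig(g=0.0), toy_sc, noise_sample=0.003)
        assert val == pytest.approx(0.11 + 0.003)

    def test_two_node_hand_value(self, jr):
        # donor sitting at the sigmoid midpoint contributes exactly g * vmax
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        sc = tn.StructuralConnectome(["a", "b"], ["cortical"] * 2, w, w * 10)
        drive = DriveConfig.uniform(2, p=0.09, eta=0.0)
        delayed = np.array([0.0, jr.v0])
        val = network_input(0, delayed, drive, CouplingConfig(g=2.0), sc, 0.001, jr)
        s_zero = sigmoid(0.0, jr)  # the self-column weight is 0, but donor j=1 at v0
        assert val == pytest.approx(0.09 + 0.001 + 2.0 * jr.vmax)

    def test_wrong_history_shape_rejected(self, toy_sc):
        drive = DriveConfig.uniform(toy_sc.n_regions)
        with pytest.raises(ValueError, match="one value per region"):
            network_input(0, np.zeros(3), drive, CouplingConfig(), toy_sc, 0.0)


class TestSimulation:
    def test_bit_identical_given_seed(self, single_node, jr):
        drive = DriveConfig.uniform(1, p=0.09, eta=0.022)
        cfg = SimulationConfig(duration=3000, transient=1000, seed=12)
        a = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        b = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        np.testing.assert_array_equal(a.signals, b.signals)
        c = simulate_network(single_node, jr, drive, CouplingConfig(),
                             SimulationConfig(duration=3000, transient=1000, seed=13))
        assert not np.array_equal(a.signals, c.signals)

    def test_damped_node_stays_at_fixed_point(self, single_node, jr):
        drive = DriveConfig.uniform(1, p=0.09, eta=2.2e-8)
        cfg = SimulationConfig(duration=10_000, transient=2_000, seed=0)
        res = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        assert np.ptp(res.post_transient()) < 1e-3

    @pytest.mark.parametrize("p,lo,hi", [(0.15, 8, 12), (0.2, 8, 12), (0.3, 8, 12)])
    def test_limit_cycle_oscillates_in_alpha(self, p, lo, hi, single_node, jr):
        drive = DriveConfig.uniform(1, p=p, eta=2.2e-8)
        cfg = SimulationConfig(duration=10_000, transient=2_000, seed=1)
        res = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        peak = tn.spectral_summary(res.post_transient(), res.fs)["peak_hz"]
        assert lo <= peak <= hi

    def test_identical_uncoupled_nodes_agree_without_noise(self, jr):
        n = 4
        sc = tn.StructuralConnectome([f"r{i}" for i in range(n)], ["cortical"] * n,
                                     np.zeros((n, n)), np.zeros((n, n)))
        drive = DriveConfig.uniform(n, p=0.12, eta=0.0)
        cfg = SimulationConfig(duration=4000, transient=1000, seed=0)
        res = simulate_network(sc, jr, drive, CouplingConfig(), cfg)
        for i in range(1, n):
            np.testing.assert_allclose(res.signals[i], res.signals[0], atol=1e-12)

    def test_dt_refinement_preserves_spectral_peak(self, single_node, jr):
        peaks = {}
        for dt in (0.1, 0.05):
            drive = DriveConfig.uniform(1, p=0.15, eta=0.0)
            cfg = SimulationConfig(duration=12_000, transient=2_000, dt=dt, seed=0)
            res = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
            peaks[dt] = tn.spectral_summary(res.post_transient(), res.fs, nperseg_s=8)["peak_hz"]
        assert abs(peaks[0.1] - peaks[0.05]) / peaks[0.05] < 0.02

    def test_save_load_round_trip(self, single_node, jr, tmp_path):
        drive = DriveConfig.uniform(1, p=0.09, eta=0.022)
        cfg = SimulationConfig(duration=2000, transient=500, seed=5)
        res = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        res.save(tmp_path / "run.h5")
        back = SimulationResult.load(tmp_path / "run.h5")
        np.testing.assert_array_equal(back.signals, res.signals)
        assert back.config == res.config
        assert back.fs == res.fs


class TestFixedPoints:
    @pytest.mark.parametrize("p", [0.0, 0.05, 0.09, 0.12])
    def test_residual_below_tolerance(self, p, jr):
        for state, _ in fixed_points(jr, p):
            assert np.abs(jr_derivatives(state.y, p, jr)).max() < 1e-10

    def test_zero_input_root_algebraically_consistent(self, jr):
        root = fixed_point(jr, 0.0)
        y0, y1, y2 = root.y[:3]
        assert y1 == pytest.approx(jr.A / jr.a * (0.0 + jr.C2 * sigmoid(jr.C1 * y0, jr)))
        assert y2 == pytest.approx(jr.B / jr.b * jr.C4 * sigmoid(jr.C3 * y0, jr))

    def test_resting_branch_is_lowest_stable(self, jr):
        roots = fixed_points(jr, 0.05)
        stable_v = sorted(s.output for s, ok in roots if ok)
        assert fixed_point(jr, 0.05).output == pytest.approx(stable_v[0])

    @pytest.mark.parametrize("p", [0.0, 0.05, 0.09])
    def test_noise_free_simulation_converges_to_root(self, p, single_node, jr):
        root = fixed_point(jr, p)
        drive = DriveConfig.uniform(1, p=p, eta=0.0)
        cfg = SimulationConfig(duration=6000, transient=2000, seed=0)
        res = simulate_network(single_node, jr, drive, CouplingConfig(), cfg)
        assert np.abs(res.final_state.ravel() - root.y).max() < 1e-6


class TestBifurcationScan:
    def test_damped_grid_extrema_match_fixed_point(self, single_node, jr):
        drive = DriveConfig.uniform(1, p=0.09, eta=0.0)
        table = bifurcation_scan(
            single_node, jr, drive, CouplingConfig(), "g", [0.0],
            SimulationConfig(duration=5000, transient=3000, seed=0),
        )
        fp_out = fixed_point(jr, 0.09).output
        row = table[table["group"] == "cortical"].iloc[0]
        assert row["vmax"] == pytest.approx(fp_out, abs=1e-4)
        assert row["vmin"] == pytest.approx(fp_out, abs=1e-4)

    def test_table_shape_per_group(self, toy_sc, jr):
        drive = DriveConfig.with_driver(toy_sc, "thalamic")
        grid = [0.0, 2.0, 4.0]
        table = bifurcation_scan(
            toy_sc, jr, drive, CouplingConfig(), "p_driver", grid,
            SimulationConfig(duration=2000, transient=500, seed=0),
        )
        assert len(table) == len(grid) * 3  # cortical, driver, all
        assert set(table["group"]) == {"cortical", "driver", "all"}
        assert (table["vmax"] >= table["vmin"]).all()
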