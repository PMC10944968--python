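"""Forward model: architecture rules, dynamics, linearization, spectra."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from specdcm.microcircuit import (
    SP,
    SS,
    Edge,
    MicrocircuitParams,
    NetworkArchitecture,
    NetworkModel,
    build_chain_network,
    build_default_network,
    build_sfg_top_network,
    load_architecture,
    numerical_jacobian,
    save_architecture,
)
from specdcm.spectra import FrequencyGrid


class TestArchitecture:
    def test_default_edge_counts(self):
        arch = build_default_network()
        assert arch.edge_counts() == {"feedforward": 12, "feedback": 12, "lateral": 6}
        assert len(arch.b_mask) == 30

    def test_feedback_edges_reverse_feedforward(self):
        arch = build_default_network()
        ff = {(e.source, e.target) for e in arch.edges_of_kind("feedforward")}
        fb = {(e.target, e.source) for e in arch.edges_of_kind("feedback")}
        assert ff == fb

    def test_lateral_edges_link_homologues_only(self):
        arch = build_default_network()
        for e in arch.edges_of_kind("lateral"):
            assert e.source.split("_")[0] == e.target.split("_")[0]
            assert e.source != e.target

    def test_sfg_top_preset_also_consistent(self):
        arch = build_sfg_top_network()
        assert arch.edge_counts() == {"feedforward": 12, "feedback": 12, "lateral": 6}
        assert arch.hierarchy["SFG"] > arch.hierarchy["MFG_contra"]

    def test_hierarchy_rules_enforced(self):
        with pytest.raises(ValueError, match="ascend"):
            NetworkArchitecture(
                ("a", "b"),
                {"a": 2, "b": 1},
                (Edge("a", "b", "feedforward"),),
                (),
            )
        with pytest.raises(ValueError, match="unequal"):
            NetworkArchitecture(
                ("a", "b"),
                {"a": 2, "b": 1},
                (Edge("a", "b", "lateral"),),
                (),
            )

    def test_b_mask_subset_enforced(self):
        with pytest.raises(ValueError, match="b_mask"):
            NetworkArchitecture(
                ("a", "b"),
                {"a": 1, "b": 2},
                (),
                (Edge("a", "b", "feedforward"),),
            )

    def test_json_roundtrip(self, tmp_path):
        arch = build_default_network()
        path = tmp_path / "arch.json"
        save_architecture(arch, path)
        back = load_architecture(path)
        assert back == arch


class TestDynamics:
    def test_leak_equilibrium_has_zero_voltage_derivative(self, chain_model):
        p = chain_model.params
        x = chain_model.resting_state().reshape(3, 4, 3)
        x[..., 1] = 0.0  # zero synaptic conductances
        x[..., 2] = 0.0
        x[..., 0] = p.v_leak
        dv = chain_model.rhs(x.ravel()).reshape(3, 4, 3)[..., 0]
        assert np.allclose(dv, 0.0)

    def test_leak_only_fixed_point_at_leak_potential(self, chain_arch):
        p = MicrocircuitParams()
        p.background_drive = np.zeros(4)
        p.w_ss_sp = p.w_sp_ss = p.w_dp_sp = 0.0
        p.w_ii_exc = np.zeros(3)
        p.w_from_ii = np.zeros(4)
        p.w_self_inh = np.zeros(4)
        p.w_feedforward = p.w_feedback = p.w_lateral = 0.0
        m = NetworkModel(chain_arch, p)
        x = m.fixed_point().reshape(3, 4, 3)
        assert np.allclose(x[..., 0], p.v_leak, atol=1e-8)
        assert np.allclose(x[..., 1:], 0.0, atol=1e-10)

    def test_frozen_conductances_follow_first_order_ode(self, chain_arch):
        """With channel kinetics frozen, V follows the closed-form linear ODE."""
        p = MicrocircuitParams()
        p.kappa_exc = np.full(4, 1e-12)
        p.kappa_inh = np.full(4, 1e-12)
        m = NetworkModel(chain_arch, p)
        x0 = m.resting_state().reshape(3, 4, 3)
        x0[..., 0] = -60.0
        ge, gi = x0[0, 0, 1], x0[0, 0, 2]
        x0 = x0.ravel()
        u = np.full(3, 0.05)
        sol = solve_ivp(
            lambda t, x: m.rhs(x, u),
            (0, 0.05),
            x0,
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        # analytic solution for one (node, population): ss of node 0
        g_tot = p.g_leak[SS] + ge + gi
        v_eq = (
            p.g_leak[SS] * p.v_leak + ge * p.v_exc + gi * p.v_inh + u[0]
        ) / g_tot
        rate = g_tot / p.capacitance[SS]
        for t in (0.01, 0.03, 0.05):
            v_expect = v_eq + (-60.0 - v_eq) * np.exp(-rate * t)
            v_num = sol.sol(t).reshape(3, 4, 3)[0, SS, 0]
            assert v_num == pytest.approx(v_expect, abs=1e-6)

    def test_nonfinite_state_rejected(self, chain_model):
        x = chain_model.resting_state()
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            chain_model.rhs(x)


class TestFixedPointAndJacobian:
    def test_fixed_point_residual(self, chain_model):
        x = chain_model.fixed_point()
        assert np.abs(chain_model.rhs(x)).max() < 1e-9

    def test_uncoupled_fixed_point_equals_single_node(self, chain_arch):
        p = MicrocircuitParams()
        p.w_feedforward = p.w_feedback = p.w_lateral = 0.0
        multi = NetworkModel(chain_arch, p).fixed_point().reshape(3, 4, 3)
        single_arch = NetworkArchitecture(("n1",), {"n1": 1}, (), ())
        single = NetworkModel(single_arch, p).fixed_point().reshape(1, 4, 3)
        for node in range(3):
            assert np.allclose(multi[node], single[0], atol=1e-8)

    def test_fixed_point_continuous_in_coupling(self, chain_arch):
        x0 = NetworkModel(chain_arch).fixed_point()
        e = chain_arch.edges[0]
        x1 = NetworkModel(chain_arch, a_log={e: 1e-6}).fixed_point()
        assert np.linalg.norm(x1 - x0) < 1e-3

    def test_analytic_jacobian_matches_finite_differences(self, chain_model):
        x = chain_model.fixed_point()
        j_ana = chain_model.jacobian(x)
        j_num = numerical_jacobian(chain_model, x)
        scale = np.abs(j_ana).max()
        assert np.abs(j_ana - j_num).max() / scale < 1e-6

    def test_uncoupled_jacobian_block_diagonal(self, chain_arch):
        p = MicrocircuitParams()
        p.w_feedforward = p.w_feedback = p.w_lateral = 0.0
        m = NetworkModel(chain_arch, p)
        j = m.jacobian(m.fixed_point())
        for a in range(3):
            for b in range(3):
                if a != b:
                    block = j[a * 12 : (a + 1) * 12, b * 12 : (b + 1) * 12]
                    assert np.abs(block).max() == 0.0

    def test_edge_removal_zeroes_coupling_entries(self, chain_arch):
        e = chain_arch.edges[0]  # n1 -> n2 feedforward
        m_full = NetworkModel(chain_arch)
        m_cut = NetworkModel(chain_arch.drop_edge(e))
        x = m_full.fixed_point()
        src_v_sp = (m_full.architecture.node_index("n1") * 4 + SP) * 3
        tgt_ge_ss = (m_full.architecture.node_index("n2") * 4 + SS) * 3 + 1
        assert m_full.jacobian(x)[tgt_ge_ss, src_v_sp] != 0.0
        assert m_cut.jacobian(x)[tgt_ge_ss, src_v_sp] == 0.0

    def test_modulation_scales_coupling_by_exp_b(self, chain_arch):
        e = chain_arch.edges[0]
        m0 = NetworkModel(chain_arch)
        m1 = NetworkModel(chain_arch, b={e: 0.3})
        x = m0.fixed_point()  # same state for both evaluations
        src_v_sp = (chain_arch.node_index("n1") * 4 + SP) * 3
        tgt_ge_ss = (chain_arch.node_index("n2") * 4 + SS) * 3 + 1
        ratio = m1.jacobian(x)[tgt_ge_ss, src_v_sp] / m0.jacobian(x)[tgt_ge_ss, src_v_sp]
        assert ratio == pytest.approx(np.exp(0.3), rel=1e-12)


class TestStability:
    def test_default_parameters_stable(self, chain_model):
        ok, abscissa = chain_model.stability()
        assert ok and abscissa < 0

    def test_default_seven_node_stable(self):
        ok, abscissa = NetworkModel(build_default_network()).stability()
        assert ok and abscissa < 0

    def test_strong_excitation_destabilizes(self, chain_arch):
        p = MicrocircuitParams()
        p.w_ss_sp *= 100
        p.w_sp_ss *= 100
        p.w_dp_sp *= 100
        ok, _ = NetworkModel(chain_arch, p).stability()
        assert not ok

    def test_abscissa_continuous_in_coupling(self, chain_arch):
        e = chain_arch.edges[0]
        vals = [
            NetworkModel(chain_arch, a_log={e: a}).stability()[1]
            for a in np.linspace(0.0, 0.2, 6)
        ]
        assert np.abs(np.diff(vals)).max() < 5.0


class TestPredictedCSD:
    def test_unstable_system_raises(self, chain_arch):
        p = MicrocircuitParams()
        p.w_ss_sp *= 100
        p.w_sp_ss *= 100
        with pytest.raises(RuntimeError, match="fixed point|unstable"):
            NetworkModel(chain_arch, p).predicted_csd()

    def test_uncoupled_nodes_have_zero_cross_spectra(self, chain_arch):
        p = MicrocircuitParams()
        p.w_feedforward = p.w_feedback = p.w_lateral = 0.0
        cs = NetworkModel(chain_arch, p).predicted_csd()
        off = ~np.eye(3, dtype=bool)
        assert np.abs(cs.values[:, off]).max() == 0.0

    def test_zero_modulation_is_exact_identity(self, chain_arch):
        base = NetworkModel(chain_arch).predicted_csd()
        mod = NetworkModel(
            chain_arch, b={e: 0.0 for e in chain_arch.b_mask}
        ).predicted_csd()
        assert np.array_equal(base.values, mod.values)

    def test_hermitian_psd_on_grid(self, chain_csd):
        chain_csd.check_hermitian()
        eigs = np.linalg.eigvalsh(chain_csd.values)
        assert eigs.min() > 0

    def test_hermitian_psd_on_random_stable_draws(self, chain_arch):
        rng = np.random.default_rng(0)
        n_ok = 0
        while n_ok < 3:
            a_log = {e: float(rng.normal(0, 0.2)) for e in chain_arch.edges}
            m = NetworkModel(chain_arch, a_log=a_log)
            if not m.stability()[0]:
                continue
            cs = m.predicted_csd(FrequencyGrid(2, 100, 7))
            cs.check_hermitian()
            assert np.linalg.eigvalsh(cs.values).min() > -1e-15
            n_ok += 1

    def test_spectra_continuous_in_modulation(self, chain_arch):
        e = chain_arch.edges[0]
        grid = FrequencyGrid(2, 100, 7)
        prev = NetworkModel(chain_arch).predicted_csd(grid).values
        for b in (0.05, 0.1, 0.15):
            cur = NetworkModel(chain_arch, b={e: b}).predicted_csd(grid).values
            assert np.abs(cur - prev).max() / np.abs(prev).max() < 0.2
            prev = cur


class TestSimulation:
    def test_zero_noise_stays_at_fixed_point(self, chain_arch):
        p = MicrocircuitParams()
        p.innovations_amp = 0.0
        p.obs_noise_psd = 1e-300
        m = NetworkModel(chain_arch, p)
        y = m.simulate_timecourses(0.5, fs=1000.0, seed=0, burn_in_s=0.1)
        assert np.abs(y).max() < 1e-6

    def test_same_seed_identical(self, chain_model):
        y1 = chain_model.simulate_timecourses(0.5, seed=3, burn_in_s=0.2)
        y2 = chain_model.simulate_timecourses(0.5, seed=3, burn_in_s=0.2)
        assert np.array_equal(y1, y2)

    def test_sample_spectrum_tracks_analytic_shape(self, chain_model, chain_csd):
        """Short-run check; the long-run convergence is exercised at 300 s
        in the acceptance suite."""
        from specdcm.spectra import estimate_csd

        y = chain_model.simulate_timecourses(60.0, seed=8)
        ep = y[:, : 30 * 2000].reshape(3, 30, 2000).transpose(1, 0, 2)
        est = estimate_csd(ep, 1000.0, half_bandwidth_hz=1.5)
        psd_e = est.values.diagonal(axis1=1, axis2=2).real
        psd_a = chain_csd.values.diagonal(axis1=1, axis2=2).real
        for node in range(3):
            peak = psd_a[:, node].argmax()
            assert psd_e[peak, node] == pytest.approx(
                psd_a[peak, node], rel=0.3
            )
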