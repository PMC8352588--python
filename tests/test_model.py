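"""Unit tests of the secretion model's building blocks.

Long calibrated runs (oscillation frequency, apical-basal gradient, the
KCa density sweep) live in the acceptance suite; here the individual
fluxes, steppers and readouts are checked on short runs and closed forms.
"""

from dataclasses import replace

import numpy as np
import pytest

from acinarca import model as M


@pytest.fixture(scope="module")
def params():
    return M.default_params()


@pytest.fixture
def rest_state(params):
    geom, cap, tp = params
    return M.initial_state(geom, cap, tp)


class TestDefaults:
    def test_paper_anchored_values(self, params):
        _, cap, tp = params
        assert cap.V_plc == pytest.approx(0.008)
        assert cap.V_ryr == 0.0
        assert tp.nak_basal_frac == pytest.approx(0.70)
        assert tp.rho_kca_apical == 1.0

    def test_geometry_regions_partition(self, params):
        geom, _, _ = params
        ap, cy, ba = geom.region_slices()
        n = (ap.stop - ap.start) + (cy.stop - cy.start) + (ba.stop - ba.start)
        assert n == geom.n_compartments
        assert ap.start == 0 and ba.stop == geom.n_compartments

    def test_ip3_diffusion_two_orders_above_calcium(self, params):
        _, cap, _ = params
        assert cap.D_p / cap.D_c == pytest.approx(100.0)


class TestIprOpen:
    def test_zero_at_no_ip3(self, params):
        _, cap, _ = params
        assert M.ipr_open(0.3, 0.0, 0.8, cap) == 0.0

    def test_zero_at_full_inactivation(self, params):
        _, cap, _ = params
        assert M.ipr_open(0.3, 0.1, 0.0, cap) == 0.0

    def test_increasing_in_ip3(self, params):
        _, cap, _ = params
        po = [M.ipr_open(0.3, p, 0.8, cap) for p in np.linspace(0.001, 0.2, 30)]
        assert np.all(np.diff(po) > 0)

    def test_steady_state_biphasic_in_calcium(self, params):
        """With h at its Ca2+-dependent steady state the open probability
        rises then falls: sequential activation and inactivation."""
        _, cap, _ = params
        cs = np.linspace(0.01, 5.0, 400)
        po = np.array([M.ipr_open(c, 0.05, float(M.h_infinity(c, cap)), cap) for c in cs])
        imax = int(po.argmax())
        assert 0 < imax < len(cs) - 1


class TestIp3Dynamics:
    def test_stays_zero_without_production(self):
        assert M.ip3_dynamics(0.0, 0.0, 0.25, 1.0) == 0.0

    def test_steady_state_closed_form(self):
        p = 0.0
        for _ in range(5000):
            p = M.ip3_dynamics(p, 0.008, 0.25, 0.01)
        assert p == pytest.approx(0.008 / 0.25, rel=1e-4)

    def test_exponential_relaxation_rate(self):
        # after a step in production, p relaxes with rate k_deg
        k = 0.25
        ts = np.arange(0, 20, 0.01)
        p = np.empty_like(ts)
        p[0] = 0.0
        for i in range(1, len(ts)):
            p[i] = M.ip3_dynamics(p[i - 1], 0.008, k, 0.01)
        p_inf = 0.008 / k
        # log-linear fit of the residual
        resid = p_inf - p
        mask = resid > 1e-9
        slope = np.polyfit(ts[mask], np.log(resid[mask]), 1)[0]
        assert -slope == pytest.approx(k, rel=1e-3)


class TestChannelGating:
    def test_closed_at_zero_calcium(self, params):
        _, _, tp = params
        assert M.channel_open_fractions(0.0, tp) == (0.0, 0.0)

    def test_half_open_at_half_activation(self, params):
        _, _, tp = params
        po_cl, _ = M.channel_open_fractions(tp.K_tmem_um, tp)
        _, po_k = M.channel_open_fractions(tp.K_kca_um, tp)
        assert po_cl == pytest.approx(0.5)
        assert po_k == pytest.approx(0.5)

    def test_monotone_nondecreasing(self, params):
        _, _, tp = params
        fr = np.array([M.channel_open_fractions(c, tp) for c in np.linspace(0, 5, 200)])
        assert np.all(np.diff(fr[:, 0]) >= 0)
        assert np.all(np.diff(fr[:, 1]) >= 0)

    def test_kca_redistribution_conserves_total(self, params):
        geom, _, tp = params
        for rho in (0.0, 0.5, 1.0, 2.0, 4.0, 10.0):
            g_a, g_b = M.kca_conductances(replace(tp, rho_kca_apical=rho), geom)
            assert g_a + g_b == pytest.approx(tp.g_kca_total)
            assert g_a >= 0 and g_b >= 0


class TestStepCalcium:
    def test_no_fluxes_leaves_uniform_calcium(self, params):
        geom, cap, tp = params
        cap0 = replace(cap, k_ipr=0.0, V_serca=0.0, V_ryr=0.0)
        state = M.initial_state(geom, cap0, tp)
        state.c[:] = 0.2
        solver = M._DiffusionSolver(geom.n_compartments, geom.dx_um, cap0.D_c, 1e-3)
        for _ in range(100):
            M.step_calcium(state, geom, cap0, 1e-3, solver)
        np.testing.assert_allclose(state.c, 0.2, rtol=1e-12)

    def test_apical_release_profile_monotone_and_matches_explicit_oracle(self, params):
        """Apical-only release on a coarse chain: the implicit stepper must
        agree with an explicit-Euler oracle and keep the profile
        nonincreasing from apical to basal."""
        geom = M.CellGeometry(n_compartments=5, length_um=12.0)
        _, cap, tp = params
        cap5 = replace(cap, basal_release_frac=0.0, V_serca=0.0,
                       mito_uptake_factor=1.0, release_depth_um=geom.dx_um)
        state = M.initial_state(geom, cap5, tp)
        state.p = 0.05
        state.h[:] = 0.8
        dt = 2e-5
        solver = M._DiffusionSolver(geom.n_compartments, geom.dx_um, cap5.D_c, dt)
        # explicit oracle with matching reactions
        c_exp = state.c.copy()
        c_er, h = state.c_er, state.h.copy()
        r = cap5.D_c * dt / geom.dx_um**2
        for _ in range(5000):
            J = M.calcium_reaction_terms(c_exp, c_er, h, state.p, geom, cap5)
            lap = np.zeros_like(c_exp)
            lap[1:-1] = c_exp[:-2] - 2 * c_exp[1:-1] + c_exp[2:]
            lap[0] = c_exp[1] - c_exp[0]
            lap[-1] = c_exp[-2] - c_exp[-1]
            c_exp = c_exp + r * lap + dt * J
            M.step_calcium(state, geom, cap5, dt, solver)
            state.h[:] = 0.8  # freeze gating in both routes
        assert np.all(np.diff(state.c) <= 1e-12)
        np.testing.assert_allclose(state.c, c_exp, rtol=0.02)

    def test_closed_cell_conservation_over_1000_steps(self, params):
        geom, cap, tp = params
        state = M.initial_state(geom, cap, tp)
        state.p = 0.03  # stimulated: large fluxes active
        total0 = M.total_calcium(state, cap)
        solvers = {}
        for i in range(1000):
            M._advance(state, geom, cap, tp, 1e-3, cap.V_plc, solvers)
        drift = abs(M.total_calcium(state, cap) - total0) / total0
        assert drift < 1e-3


class TestStepIonsAndVolume:
    def test_all_transport_off_is_fixed_point(self, params):
        geom, cap, tp = params
        tp0 = replace(tp, g_tmem=0.0, g_kca_total=0.0, g_k_leak=0.0, g_cl_leak=0.0,
                      g_na_leak=0.0, J_nak_bar=0.0, V_nkcc=0.0, V_ae=0.0,
                      g_para=0.0, L_a=0.0, L_b=0.0)
        state = M.initial_state(geom, cap, tp0)
        before = [state.Na_i, state.K_i, state.Cl_i, state.Na_L, state.K_L,
                  state.Cl_L, state.w]
        for _ in range(100):
            M.step_ions_and_volume(state, geom, tp0, 1e-3)
        after = [state.Na_i, state.K_i, state.Cl_i, state.Na_L, state.K_L,
                 state.Cl_L, state.w]
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_membrane_charge_balance(self, params):
        """The algebraic potentials zero the net charge flux across the
        cell membrane and into the lumen at any state."""
        geom, cap, tp = params
        state = M.initial_state(geom, cap, tp)
        state.c[:5] = 0.8  # stimulated apical Ca2+
        fx = M.ion_fluxes(state, geom, tp)
        cell_charge = (fx["J_ka"] + fx["J_kb"] + fx["P_a"] + fx["P_b"]
                       - fx["J_cl"] - fx["J_na_leak"])
        lumen_charge = fx["J_ka"] + fx["P_a"] + fx["J_para"] - fx["J_cl"]
        assert abs(cell_charge) < 1e-10
        assert abs(lumen_charge) < 1e-10

    def test_rest_secretion_negligible(self, params):
        geom, cap, tp = params
        state = M.initial_state(geom, cap, tp)
        fx = M.ion_fluxes(state, geom, tp)
        # resting secretion is ~1.6% of the stimulated rate (~0.005/s)
        assert abs(fx["q_sec"]) < 0.02 * 0.005


class TestSimulateShort:
    def test_unstimulated_run_is_flat(self, params):
        geom, cap, tp = params
        res = M.simulate((geom, replace(cap, V_plc=0.0), tp),
                         t_end_s=60.0, stim_onset_s=30.0)
        assert np.ptp(res.apical) < 1e-6
        assert np.all(res.q < 2e-4)
        for key in ("Na_i", "K_i", "Cl_i"):
            assert np.ptp(res.ions[key]) / res.ions[key].mean() < 0.01

    def test_stimulation_raises_apical_calcium_and_secretion(self, params):
        geom, cap, tp = params
        res = M.simulate((geom, cap, tp), t_end_s=80.0, stim_onset_s=20.0)
        sl = res.window(50, 80)
        rest = M.rest_level(res, res.apical)
        assert res.apical[sl].mean() > rest + 0.1
        assert res.q[sl].mean() > 5 * res.q[res.window(10, 20)].mean()

    def test_model_linescan_shape_and_uniformity(self, params):
        geom, cap, tp = params
        res = M.simulate((geom, replace(cap, V_plc=0.0), tp),
                         t_end_s=5.0, stim_onset_s=2.0)
        scan = M.model_linescan(res)
        assert scan.shape[0] == geom.n_compartments
        # unstimulated: uniform in space
        assert np.ptp(scan) < 1e-6


class TestReadouts:
    def _result_with_traces(self, apical, basal=None, fs=100.0, onset=10.0):
        n = len(apical)
        t = np.arange(n) / fs
        basal = basal if basal is not None else np.zeros(n)
        return M.SimulationResult(
            t=t, c_xt=np.tile(apical[:, None], (1, 4)).astype(np.float32),
            apical=np.asarray(apical, dtype=float), cytoplasmic=np.zeros(n),
            basal=np.asarray(basal, dtype=float), q=np.zeros(n), w=np.ones(n),
            p=np.zeros(n), c_er=np.full(n, 60.0), V_c=np.zeros(n), V_L=np.zeros(n), ions={},
            stim_onset_s=onset, geometry=M.CellGeometry(n_compartments=4),
        )

    def test_flat_trace_zero_frequency_no_latency(self):
        res = self._result_with_traces(np.full(20000, 0.05))
        freq, lat = M.oscillation_metrics(res, analysis_window_s=100.0)
        assert freq == 0.0
        assert lat is None

    def test_injected_sinusoid_frequency_recovered(self):
        fs = 100.0
        t = np.arange(0, 200, 1 / fs)
        apical = 0.05 + 0.4 * (t > 10) * (1 + np.sin(2 * np.pi * 0.8 * t))
        res = self._result_with_traces(apical, fs=fs)
        freq, lat = M.oscillation_metrics(res, analysis_window_s=100.0)
        assert freq == pytest.approx(0.8, rel=0.05)
        assert lat is not None and lat < 1.0

    def test_ratio_extremes(self):
        n = 30000
        apical = np.full(n, 0.05)
        apical[10000:] = 0.55
        same = self._result_with_traces(apical, basal=apical, onset=100.0)
        zero = self._result_with_traces(
            apical, basal=np.full(n, 0.05), onset=100.0
        )
        assert M.apical_basal_ratio(same) == pytest.approx(1.0)
        assert M.apical_basal_ratio(zero) == pytest.approx(0.0, abs=1e-9)


class TestMonotonicityOverStimulation:
    def test_frequency_latency_secretion_trends(self, params):
        """Stronger stimulation: frequency and secretion up, latency down."""
        geom, cap, tp = params
        freqs, lats, qs = [], [], []
        for v in (0.002, 0.006, 0.008):
            res = M.simulate((geom, replace(cap, V_plc=v), tp),
                             t_end_s=250.0, stim_onset_s=100.0)
            f, lat = M.oscillation_metrics(res, analysis_window_s=100.0)
            freqs.append(f)
            lats.append(np.inf if lat is None else lat)
            qs.append(M.mean_secretion(res, window_s=100.0))
        assert freqs == sorted(freqs)
        assert lats == sorted(lats, reverse=True)
        assert qs == sorted(qs)


class TestParamConfig:
    def test_yaml_round_trip_and_overrides(self, tmp_path, params):
        import yaml

        M.dump_params(params, tmp_path / "full.yaml")
        flat = yaml.safe_load((tmp_path / "full.yaml").read_text())
        assert flat["V_plc"] == pytest.approx(0.008)

        (tmp_path / "override.yaml").write_text("V_plc: 0.004\nn_compartments: 20\n")
        geom, cap, tp = M.load_params(tmp_path / "override.yaml")
        assert cap.V_plc == pytest.approx(0.004)
        assert geom.n_compartments == 20
        assert tp == params[2]

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "bad.yaml").write_text("no_such_knob: 1\n")
        with pytest.raises(KeyError):
            M.load_params(tmp_path / "bad.yaml")
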