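import numpy as np
import pytest

import ffwd_einet as fe
from ffwd_einet.neurons import (
    NeuronParams,
    NeuronState,
    apply_reset,
    load_registry,
    membrane_rhs,
    recovery_rhs,
)


class TestRegistry:
    def test_all_presets_load_and_validate(self):
        reg = load_registry()
        assert set(reg) == {"Src", "Int", "Tgt_subthreshold", "Tgt_network"}
        for p in reg.values():
            assert p.v_r < p.v_t < p.v_p
            assert p.c < p.v_p

    def test_fs_preset_has_vb_and_no_recovery_jump(self):
        fs = fe.get_params("Int")
        assert fs.is_fs and fs.v_b == -55.0 and fs.d == 0.0

    def test_target_variants_differ_in_excitability(self):
        sub, net = fe.get_params("Tgt_subthreshold"), fe.get_params("Tgt_network")
        assert (sub.C, sub.v_t) == (100.0, -40.0)
        assert (net.C, net.v_t) == (50.0, -45.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            fe.get_params("Pyramidal")

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams("RS", C=100, v_r=-40, v_t=-60, v_p=35, k=1, a=1, b=1, c=-50, d=0)
        with pytest.raises(ValueError):
            NeuronParams("FS", C=20, v_r=-55, v_t=-40, v_p=25, k=1, a=1, b=1, c=-45, d=0)


class TestMembraneRhs:
    @pytest.mark.parametrize(
        "preset,v,u,I,expected",
        [
            ("Src", -60.0, 0.0, 0.0, 0.0),        # v = v_r zeroes the quadratic
            ("Src", -50.0, 0.0, 0.0, -0.7),       # 0.7*10*(-10)/100
            ("Src", -40.0, 0.0, 140.0, 1.4),      # at v_t only I/C remains
            ("Int", -40.0, 0.0, 40.0, 2.0),
        ],
    )
    def test_hand_values(self, preset, v, u, I, expected):
        p = fe.get_params(preset)
        got = membrane_rhs(NeuronState(v, u), p, I_app=I)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rest_is_fixed_point(self, rs_params, fs_params):
        for p in (rs_params, fs_params):
            s = NeuronState.resting(p)
            assert membrane_rhs(s, p) == 0.0
            assert recovery_rhs(s, p) == 0.0

    def test_non_finite_rejected(self, rs_params):
        with pytest.raises(ValueError):
            membrane_rhs(NeuronState(np.nan, 0.0), rs_params)
        with pytest.raises(ValueError):
            membrane_rhs(NeuronState(-60.0, 0.0), rs_params, I_app=np.inf)


class TestRecoveryRhs:
    @pytest.mark.parametrize(
        "preset,v,u,expected",
        [
            ("Int", -60.0, 4.0, -0.8),    # below v_b: pure decay 0.2*(0-4)
            ("Int", -50.0, 0.0, 0.625),   # 0.2 * 0.025 * 5^3
            ("Src", -60.0, 0.0, 0.0),
            ("Src", -50.0, 10.0, 0.03 * (-2 * 10 - 10)),
        ],
    )
    def test_hand_values(self, preset, v, u, expected):
        p = fe.get_params(preset)
        assert recovery_rhs(NeuronState(v, u), p) == pytest.approx(expected)


class TestReset:
    def test_rs_reset_increments_recovery(self, rs_params):
        state, spiked = apply_reset(NeuronState(36.0, 10.0), rs_params)
        assert spiked and state.v == -50.0 and state.u == 110.0

    def test_fs_reset_leaves_recovery(self, fs_params):
        state, spiked = apply_reset(NeuronState(26.0, 5.0), fs_params)
        assert spiked and state.v == -45.0 and state.u == 5.0

    def test_subthreshold_state_untouched(self, rs_params):
        state, spiked = apply_reset(NeuronState(0.0, 3.0), rs_params)
        assert not spiked and state.v == 0.0 and state.u == 3.0


class TestDynamics:
    def test_sustained_dc_gives_periodic_rs_spiking(self, rs_params):
        """A suprathreshold DC drives regular spiking with stable intervals."""
        net = fe.subthreshold._pair_network(rs_params, 0.0, holding=0.0)
        sched = fe.stimulus.InputSchedule(
            pulses=(fe.PulseInput(target=0, I0=200.0, t_inp=0.0, d_inp=500.0),)
        )
        raster, _ = fe.run(net, sched, fe.SimulationConfig(duration=500.0, dt=0.05))
        times = raster.time[raster.neuron == 0]
        assert times.size >= 4
        isis = np.diff(times)[1:]  # drop the first, transient, interval
        assert isis.std() / isis.mean() < 0.05

    def test_fs_at_holding_current_is_deterministic(self, fs_params):
        """Repeated runs of an isolated held FS cell are identical."""
        net = fe.subthreshold._pair_network(fs_params, 0.0, holding=50.0)
        cfg = fe.SimulationConfig(duration=200.0, dt=0.01, record_voltages=True)
        empty = fe.stimulus.InputSchedule(pulses=())
        _, tr1 = fe.engine._simulate(net, [empty], cfg)
        _, tr2 = fe.engine._simulate(net, [empty], cfg)
        assert np.array_equal(tr1.v, tr2.v)
        assert np.all(tr1.v < fs_params.v_p)

    def test_rs_spike_times_match_ode_oracle(self, rs_params):
        """Euler spike times agree with an adaptive ODE solve with reset events."""
        from scipy.integrate import solve_ivp

        p = rs_params
        I = 150.0

        def rhs(t, y):
            v, u = y
            return [
                (p.k * (v - p.v_r) * (v - p.v_t) - u + I) / p.C,
                p.a * (p.b * (v - p.v_r) - u),
            ]

        def hit_peak(t, y):
            return y[0] - p.v_p

        hit_peak.terminal = True
        hit_peak.direction = 1

        oracle_times, y0, t0 = [], [p.v_r, 0.0], 0.0
        for _ in range(3):
            sol = solve_ivp(rhs, (t0, 300.0), y0, events=hit_peak,
                            max_step=0.05, rtol=1e-8, atol=1e-8)
            t0 = sol.t_events[0][0]
            oracle_times.append(t0)
            y0 = [p.c, sol.y_events[0][0][1] + p.d]

        net = fe.subthreshold._pair_network(rs_params, 0.0, holding=0.0)
        sched = fe.stimulus.InputSchedule(
            pulses=(fe.PulseInput(target=0, I0=I, t_inp=0.0, d_inp=300.0),)
        )
        raster, _ = fe.run(net, sched, fe.SimulationConfig(duration=300.0, dt=0.01))
        euler_times = raster.time[raster.neuron == 0][:3]
        assert np.allclose(euler_times, oracle_times, atol=0.5)
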