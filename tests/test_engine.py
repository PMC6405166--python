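import numpy as np
import pytest

import ffwd_einet as fe
from ffwd_einet.circuits import Network, CircuitSpec
from ffwd_einet.synapses import ChemicalSynapse, ElectricalSynapse


def _two_cell_net(rs_params, chemical=(), electrical=(), holding=0.0):
    return Network(
        spec=CircuitSpec.defaults("SCC"),
        cell_params=[rs_params, rs_params],
        populations={"A": np.array([0]), "B": np.array([1])},
        unit_of=np.array([0, 0]),
        holding=np.full(2, holding),
        chemical=list(chemical),
        electrical=list(electrical),
    )


class TestRun:
    def test_isolated_neuron_stays_at_rest(self, rs_params):
        net = _two_cell_net(rs_params)
        raster, trace = fe.run(
            net,
            fe.InputSchedule(pulses=()),
            fe.SimulationConfig.subthreshold(),
        )
        assert len(raster) == 0
        assert np.allclose(trace.of(0), rs_params.v_r)
        assert trace.t.size == int(100.0 / 0.01) + 1

    def test_scc_default_response(self, scc_run):
        raster, trace, onset = scc_run
        assert int((raster.neuron == 0).sum()) == 1  # Src spikes once
        assert int((raster.neuron == 1).sum()) == 1  # Int follows
        assert int((raster.neuron == 2).sum()) == 0  # Tgt stays subthreshold
        src_t = raster.time[raster.neuron == 0][0]
        int_t = raster.time[raster.neuron == 1][0]
        assert 0 < int_t - src_t < 5.0
        assert trace.of(2).max() < fe.get_params("Tgt_subthreshold").v_t

    def test_membrane_never_left_above_peak(self, scc_run):
        raster, trace, _ = scc_run
        vp = np.array([p.v_p for p in raster.network.cell_params])
        assert np.all(trace.v < vp[None, :, None])

    def test_raster_times_ordered_and_in_range(self, ccn_uncoupled):
        r = ccn_uncoupled
        assert np.all(r.time > 0) and np.all(r.time <= 200.0)
        df = r.to_frame()
        for (_, _), grp in df.groupby(["trial", "neuron"]):
            assert np.all(np.diff(grp["t_ms"].values) > 0)

    def test_divergence_aborts_with_diagnostics(self, rs_params):
        net = _two_cell_net(rs_params)
        sched = fe.InputSchedule(
            pulses=(fe.PulseInput(target=0, I0=-1e5, t_inp=0.0, d_inp=50.0),)
        )
        with pytest.raises(RuntimeError, match="diverged"):
            fe.run(net, sched, fe.SimulationConfig(duration=50.0, dt=0.05))


class TestSynapticSemantics:
    def test_one_step_effective_latency(self, rs_params):
        """A zero-delay synapse first affects the target one step after the
        presynaptic spike is registered."""
        syn = ChemicalSynapse(0, 1, "AMPA", 10.0)
        net = _two_cell_net(rs_params, chemical=[syn])
        sched = fe.InputSchedule(
            pulses=(fe.PulseInput(target=0, I0=300.0, t_inp=0.0, d_inp=30.0),)
        )
        cfg = fe.SimulationConfig(duration=40.0, dt=0.05, record_voltages=True)
        raster, trace = fe.run(net, sched, cfg)
        spike_t = raster.time[raster.neuron == 0][0]
        spike_sample = int(round(spike_t / cfg.dt))  # sample after the spike step
        vB = trace.of(1)
        assert np.allclose(vB[: spike_sample + 1], rs_params.v_r)
        assert vB[spike_sample + 1] > rs_params.v_r + 1e-6

    def test_identical_coupled_pair_stays_identical(self, rs_params):
        """Pure electrical coupling between identical cells in identical
        states transmits zero net current, through spikes included."""
        net = _two_cell_net(
            rs_params, electrical=[ElectricalSynapse(0, 1, 5.0)]
        )
        pulses = tuple(
            fe.PulseInput(target=i, I0=200.0, t_inp=0.0, d_inp=200.0) for i in (0, 1)
        )
        cfg = fe.SimulationConfig(duration=200.0, dt=0.05, record_voltages=True)
        raster, trace = fe.run(net, fe.InputSchedule(pulses=pulses), cfg)
        assert np.array_equal(trace.of(0), trace.of(1))
        assert int((raster.neuron == 0).sum()) == int((raster.neuron == 1).sum()) >= 2

    def test_electrical_current_conserved_each_step(self, fs_params):
        """Summed gap-junction current over a coupled pair is identically 0:
        the asymmetric voltage deflections mirror each other's currents."""
        net = fe.subthreshold._pair_network(fs_params, 4.0, holding=0.0)
        sched = fe.InputSchedule(
            pulses=(fe.PulseInput(target=0, I0=-30.0, t_inp=10.0, d_inp=50.0),)
        )
        cfg = fe.SimulationConfig(duration=80.0, dt=0.01, record_voltages=True)
        _, trace = fe.run(net, sched, cfg)
        i01 = 4.0 * (trace.of(0) - trace.of(1))
        i10 = 4.0 * (trace.of(1) - trace.of(0))
        assert np.allclose(i01 + i10, 0.0, atol=1e-12)
        assert np.abs(i01).max() > 0  # the pair did exchange current


class TestTrials:
    def _factory(self, sigma=3.0):
        def factory(child):
            return fe.gaussian_schedule(2, sigma, 100.0, seed=child, targets=[0, 1])

        return factory

    def test_fixed_root_seed_reproduces_raster(self):
        net = fe.build_ccn(n=2)
        cfg = fe.SimulationConfig.network()
        r1 = fe.run_trials(net, self._factory(), cfg, n_trials=5, seed=9)
        r2 = fe.run_trials(net, self._factory(), cfg, n_trials=5, seed=9)
        assert np.array_equal(r1.time, r2.time)
        assert np.array_equal(r1.neuron, r2.neuron)
        assert np.array_equal(r1.trial, r2.trial)

    def test_single_trial_equals_run(self):
        net = fe.build_ccn(n=2)
        cfg = fe.SimulationConfig.network()
        raster = fe.run_trials(net, self._factory(), cfg, n_trials=1, seed=3)
        sched = self._factory()(np.random.SeedSequence(3).spawn(1)[0])
        direct, _ = fe.run(net, sched, cfg)
        assert np.array_equal(raster.time, direct.time)

    def test_out_of_network_pulse_rejected(self):
        net = fe.build_ccn(n=1)
        with pytest.raises(ValueError, match="outside the network"):
            fe.run(
                net,
                fe.stimulus.single_pulse_schedule(target=99),
                fe.SimulationConfig.network(),
            )


class TestStepSizeRobustness:
    @pytest.mark.parametrize("builder,dt", [("scc", 0.01), ("ccn1", 0.05)])
    def test_halving_dt_preserves_spikes(self, builder, dt):
        """Halving the step leaves spike counts unchanged and moves spike
        times by at most a couple of coarse steps (first-order error on the
        slow approach to threshold)."""
        net = fe.build_scc() if builder == "scc" else fe.build_ccn(n=1)
        sched = fe.stimulus.single_pulse_schedule(target=0)
        coarse, _ = fe.run(net, sched, fe.SimulationConfig(100.0, dt))
        fine, _ = fe.run(net, sched, fe.SimulationConfig(100.0, dt / 2))
        assert len(coarse) == len(fine)
        for n in np.unique(coarse.neuron):
            tc = coarse.time[coarse.neuron == n]
            tf = fine.time[fine.neuron == n]
            assert tc.size == tf.size
            assert np.all(np.abs(tc - tf) < 2 * dt + 1e-9)
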