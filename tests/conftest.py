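import warnings

import pytest

import ffwd_einet as fe


@pytest.fixture(scope="session")
def rs_params():
    return fe.get_params("Src")


@pytest.fixture(scope="session")
def fs_params():
    return fe.get_params("Int")


@pytest.fixture(scope="session")
def scc_run():
    """Default SCC driven by one source pulse: (raster, trace, onset)."""
    net = fe.build_scc()
    raster, trace = fe.run(
        net,
        fe.stimulus.single_pulse_schedule(target=0),
        fe.SimulationConfig.subthreshold(),
    )
    return raster, trace, fe.stimulus.SETTLE_MS


@pytest.fixture(scope="session")
def ccn_uncoupled():
    """50-unit network, sigma_inp = 5 ms, no Int coupling, 50 trials."""
    return fe.simulate_ccn(sigma_inp=5.0, sum_g_elec=0.0, n_trials=50, seed=11)


@pytest.fixture(scope="session")
def ccn_sigma1_by_coupling():
    """sigma_inp = 1 ms rasters across the coupling range, 20 trials each."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ge in (0.0, 2.0, 5.0):
            out[ge] = fe.simulate_ccn(sigma_inp=1.0, sum_g_elec=ge, n_trials=20, seed=5)
    return out
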