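import numpy as np
import pytest

import hepasim as h


@pytest.fixture(scope="session")
def refsim():
    return h.REFSIM


@pytest.fixture(scope="session")
def coupled_run_8h():
    """One full 8-hour coupled simulation (quasi-steady mode), shared."""
    return h.run_multiscale(h.REFSIM, 20.0, 8.0)


@pytest.fixture(scope="session")
def population_run():
    """Scaled-down virtual population (n = 20, CV 25 %), shared."""
    spec = h.PopulationSpec(n=20, base=h.REFSIM, cv=0.25, seed=7)
    return h.run_population(spec, 20.0, 8.0)


@pytest.fixture()
def sinusoid_state(refsim):
    cfg = h.SinusoidConfig.from_params(refsim)
    return h.build_sinusoid(cfg, h.subcell_params_from(refsim),
                            rb2p=(refsim["pbpk_Rb2p"], refsim["pbpk_Rb2pG"],
                                  refsim["pbpk_Rb2pS"]),
                            Fup=refsim["pbpk_Fup"])


def run_standalone_sinusoid(state, rates, inflow, n_steps, Fup=0.8):
    """Drive a standalone sinusoid with constant inflow concentration."""
    cfg = state.config
    dt = cfg.dt_transport
    spawn_every = max(1, int(round(cfg.dt_inflow / dt)))
    for step in range(n_steps):
        if step % spawn_every == 0:
            h.spawn_parcels(state, np.asarray(inflow, float),
                            dt=cfg.dt_inflow)
        h.transfer_step(state, h.contact_graph(state), rates, Fup, dt)
        h.advect(state, dt)
    return state
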