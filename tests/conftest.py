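"""Shared fixtures: one grid population, its EC spikes, and calibrated DG
networks, built once per session to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

import thetarecode.gridcells as gcm
from thetarecode import dg as dgm
from thetarecode.spiketrains import SpikeTrainSet

GRID_SEED = 1


@pytest.fixture(scope="session")
def population():
    return gcm.sample_grid_population(200, GRID_SEED)


@pytest.fixture(scope="session")
def rate_profile(population):
    return gcm.trajectory_rate_profiles(population, gcm.Trajectory())


@pytest.fixture(scope="session")
def ec_spikes(rate_profile):
    return gcm.poisson_spikes(rate_profile, 0)


@pytest.fixture(scope="session")
def phase_template(ec_spikes):
    return gcm.estimate_phase_template(ec_spikes)


@pytest.fixture(scope="session")
def calibrated_nets(ec_spikes):
    """Rate-calibrated DG surrogates for the full and no-feedback circuits."""
    nets = {}
    for cond in ("full", "no_fb"):
        net = dgm.build_dg(dgm.DGConfig(condition=cond, connectivity_seed=GRID_SEED))
        w = dgm.calibrate_pp_weight(net, ec_spikes,
                                    target_rate_band=(0.225, 0.245))
        nets[cond] = net.with_config(pp_weight=w)
    return nets


@pytest.fixture(scope="session")
def gc_spikes(calibrated_nets, ec_spikes):
    """Granule-cell outputs of the calibrated full and no_fb networks."""
    return {cond: dgm.run_dg(net, ec_spikes, sim_seed=0)
            for cond, net in calibrated_nets.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spike_set(trains, duration=2.0) -> SpikeTrainSet:
    return SpikeTrainSet([np.asarray(t, dtype=float) for t in trains], duration)
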