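"""Shared fixtures: frozen default parameters and a session-scoped cache
of ensemble runs so several tests can interrogate one computation."""

from __future__ import annotations

import numpy as np
import pytest

import sarcsim as ss

MASTER_SEED = 1202


@pytest.fixture(scope="session")
def params() -> ss.HalfSarcomereParams:
    return ss.HalfSarcomereParams()


@pytest.fixture(scope="session")
def topo50() -> ss.Topology:
    return ss.Topology(n_series=50)


@pytest.fixture(scope="session")
def standard_protocol() -> ss.Protocol:
    return ss.Protocol()


@pytest.fixture(scope="session")
def ensemble_cache(params, topo50):
    """Memoised paired-trial ensembles keyed by condition."""
    cache: dict = {}

    def get(alpha=0.2, beta=0.0, protocol=None, n_seeds=10,
            topology=None, master=MASTER_SEED):
        protocol = protocol or ss.Protocol()
        topology = topology or topo50
        key = (alpha, beta, protocol, n_seeds, topology, master)
        if key not in cache:
            het = ss.HeterogeneitySpec(alpha=alpha, beta=beta,
                                       n_units=topology.n_series)
            cache[key] = ss.run_ensemble(topology, params, protocol, het,
                                         n_seeds, master_seed=master)
        return cache[key]

    return get


def rfe_at(ens, protocol, tau=6.0):
    i = int(round((protocol.stretch_end + tau) / protocol.dt))
    return 100.0 * (ens.mean_stretch[i] / ens.mean_iso[i] - 1.0)
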