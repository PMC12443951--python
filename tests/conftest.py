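"""Shared fixtures: rig settings and cached simulator runs."""

import pytest

import hmecalc as hc

# Simulator grid shared by several tests (efficiencies x tidal volumes
# x target humidities of the bench protocol).
ETAS = (0.2, 0.5, 0.8)
TIDAL_VOLUMES = (0.25, 0.5, 0.75)
TARGETS_MG_L = (37.0, 44.0)
GRID = [(e, v, h) for e in ETAS for v in TIDAL_VOLUMES for h in TARGETS_MG_L]


@pytest.fixture(scope="session")
def rig44():
    """Reference rig: ha 44 mg/l, dry carrier gas, 30 ml dead space, 38 degC."""
    return hc.RigParameters.from_practical()


@pytest.fixture(scope="session")
def grid_sims():
    """Converged linear-class simulations over the full bench grid at dt=0.01 s."""
    sims = {}
    for eta, v, ha in GRID:
        params = hc.RigParameters.from_practical(ha_mg_l=ha)
        sims[(eta, v, ha)] = hc.simulate_rig(
            params,
            hc.HMEBehavior.linear(eta),
            hc.FlowProfile(tidal_volume=v),
            n_breaths=14,
            dt=0.01,
        )
    return sims


def recover_from_trace(res):
    """Trace route: segment/integrate the P2 record, evaluate the closure.

    Returns (recovered state, final-breath ledger) for comparison with
    the simulator's exact bookkeeping.
    """
    params = res.params
    cond = params.conditions
    summary = hc.summarize_trace(res.p2)[-1]
    mb = hc.absolute_to_fraction(summary.mean_concentration_mg_l, cond)
    state = hc.evaluate_from_mb(params, mb, summary.volume_mol)
    return state, res.breaths[-1]
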