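import numpy as np
import pytest

from arraxis.cell_model import (
    APTrace,
    ConductanceMultipliers,
    PacingProtocol,
    SolverSettings,
    simulate_ap,
)

#: a robustly ectopic parameter point: strong ICaL up-scaling, deep IKr block
ECTOPIC_POINT = (np.e, np.exp(-3.0), 1.0, 1.0)


def make_trace(beat_builder, n_beats=4, cl=1000.0, dt=1.0):
    """Assemble an APTrace from a per-beat voltage builder(t_in_beat)."""
    tb = np.arange(0.0, cl, dt)
    v = np.concatenate([beat_builder(tb, k) for k in range(n_beats)])
    t = np.concatenate([tb + k * cl for k in range(n_beats)])
    return APTrace(time=t, vm=v, protocol=PacingProtocol())


def single_peak_beat(tb, _k=0, rest=-88.0, peak=35.0, apd=280.0):
    """Upstroke then monotone repolarization: exactly one local maximum."""
    up = np.clip(tb / 2.0, 0.0, 1.0)
    env = np.exp(-tb / 500.0) / (1.0 + np.exp((tb - apd) / 15.0))
    return rest + (peak - rest) * up * env


def bump_beat(tb, _k=0, bump_t=400.0, bump_amp=45.0, bump_w=25.0, **kw):
    """Single-peak beat plus a late depolarizing bump (peak ~ -43 mV)."""
    v = single_peak_beat(tb, **kw)
    return v + bump_amp * np.exp(-(((tb - bump_t) / bump_w) ** 2))


@pytest.fixture(scope="session")
def short_protocol():
    return PacingProtocol(equilibration_beats=20, recorded_beats=4)


@pytest.fixture(scope="session")
def baseline_trace(short_protocol):
    """Baseline ORd myocyte, short equilibration (shared across tests)."""
    return simulate_ap(
        ConductanceMultipliers(), short_protocol, SolverSettings(method="rush-larsen")
    )
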