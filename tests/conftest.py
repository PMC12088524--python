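import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_neuron():
    from larvacpg import NeuronParameters

    return NeuronParameters()


@pytest.fixture(scope="session")
def ho_blueprint():
    from larvacpg.circuits import hemisegmental_oscillator

    return hemisegmental_oscillator()


@pytest.fixture(scope="session")
def ho_tonic_recording(ho_blueprint):
    """One tonically driven HO run shared by several tests (40 s)."""
    from larvacpg import StimulusProtocol, TonicCurrent, simulate

    prot = StimulusProtocol([TonicCurrent("C_B", 1000.0, 40000.0, 0.02)])
    return simulate(ho_blueprint.spec, prot, duration=40000.0,
                    record_connections=False)


@pytest.fixture(scope="session")
def abdominal_forwards():
    """Abdominal chain under tonic forwards command (60 s), with blueprint."""
    from larvacpg import StimulusProtocol, TonicCurrent, simulate
    from larvacpg.circuits import abdominal_chain

    bp = abdominal_chain()
    prot = StimulusProtocol([TonicCurrent("C_F", 1000.0, 60000.0, 0.02)])
    rec = simulate(bp.spec, prot, duration=60000.0, record_connections=False)
    return bp, rec


def oscillation_stats(time, trace, t_start=10000.0, prominence=8.0,
                      distance_ms=500.0):
    """(n_peaks, mean period ms, cv) of a voltage oscillation."""
    from scipy.signal import find_peaks

    sel = time >= t_start
    t, v = time[sel], trace[sel]
    dt = t[1] - t[0]
    pk, _ = find_peaks(v, prominence=prominence,
                       distance=max(int(distance_ms / dt), 1))
    if len(pk) < 3:
        return len(pk), np.nan, np.nan
    per = np.diff(t[pk])
    return len(pk), float(per.mean()), float(per.std() / per.mean())
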