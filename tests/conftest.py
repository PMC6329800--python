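import numpy as np
import pytest

from fsrpe import ephys, rl, task


@pytest.fixture(scope="session")
def reference_spec():
    """F-DW-Dec model at the published fitted parameter set."""
    return rl.ModelSpec(variant="F-DW-Dec", eta=0.22, beta=3.55,
                        phi=0.68, omega=0.92)


@pytest.fixture(scope="session")
def behavior_session(reference_spec):
    """One 9-block session generated by the fitted model."""
    cfg = task.TaskConfig()
    s = task.generate_session(cfg, rl.RLAgent(reference_spec), seed=11,
                              n_blocks=9)
    s.annotate_learning()
    return s


@pytest.fixture(scope="session")
def neural_session(reference_spec):
    """A 12-block (~390 trial) session for spike-train analyses."""
    cfg = task.TaskConfig()
    s = task.generate_session(cfg, rl.RLAgent(reference_spec), seed=7,
                              n_blocks=12)
    s.annotate_learning()
    return s


@pytest.fixture(scope="session")
def neural_trace(reference_spec, neural_session):
    return rl.rpe_trace(reference_spec, neural_session)


@pytest.fixture(scope="session")
def noise_neuron(neural_session, neural_trace):
    prof = ephys.NeuronProfile(baseline_hz=5.0)
    return ephys.simulate_neuron(prof, neural_session, neural_trace, seed=99)


def planted_neuron(session, trace, sign, gain, seed, dimension="color",
                   feature="c1", latency=0.2, duration=0.6, baseline=5.0):
    prof = ephys.NeuronProfile(
        baseline_hz=baseline,
        signals=(ephys.PlantedSignal(sign, gain, latency=latency,
                                     duration=duration, dimension=dimension,
                                     feature=feature),))
    return ephys.simulate_neuron(prof, session, trace, seed=seed)
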