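import numpy as np
import pytest

from deepernet.model import DeepERNet, NetConfig, TrainConfig, train
from deepernet.preprocess import preprocess_recording, segment_cohort
from deepernet.signal_sim import simulate_cohort

#: miniature sampling rates: every architectural relation (kernel/pool
#: spans in seconds, 20-s second-conv coverage) is preserved while keeping
#: model tests fast
TOY_CFG = NetConfig(fs_ecg=8.0, fs_resp=2.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four simulated subjects at 320 Hz ECG / 25 Hz RESP, de-noised."""
    recs = simulate_cohort(4, rng_seed=7, fs_ecg=320.0, fs_resp=25.0)
    return [preprocess_recording(r) for r in recs]


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    return segment_cohort(tiny_cohort)


@pytest.fixture(scope="session")
def toy_problem():
    """Linearly separable two-class toy segments at miniature rates."""
    rng = np.random.default_rng(0)
    n = 64
    y = np.repeat([0, 1], n // 2)
    ecg = rng.standard_normal((n, TOY_CFG.ecg_input_len)).astype(np.float32)
    ecg += y[:, None] * 2.0
    resp = rng.standard_normal((n, TOY_CFG.resp_input_len)).astype(np.float32)
    resp -= y[:, None] * 1.5
    return ecg, resp, y


@pytest.fixture(scope="session")
def toy_model(toy_problem):
    ecg, resp, y = toy_problem
    model = DeepERNet(TOY_CFG, rng_seed=0)
    history = train(model, ecg, resp, y, TrainConfig(epochs=8, rng_seed=0))
    return model, history


@pytest.fixture(scope="session")
def desk_report():
    """The full desk-scale comparison study (shared across acceptance
    checks; several minutes of CPU)."""
    from deepernet.workflows import desk_benchmark

    return desk_benchmark(seed=1)
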