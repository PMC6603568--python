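import numpy as np
import pytest

from eegbench.acquisition_chain import run_bench
from eegbench.quality_metrics import summarize
from eegbench.synthetic_eeg import EEGEpoch, GeneratorParams, generate_epochs


@pytest.fixture(scope="session")
def reference_epochs():
    """The bench's reference conditions: 15 x 30 s epochs at 250 Hz."""
    return generate_epochs(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def bench_run(reference_epochs):
    """One full nine-stage bench simulation plus its quality report."""
    recordings = run_bench(reference_epochs, seed=1)
    report = summarize(recordings, reference_epochs)
    return reference_epochs, recordings, report


@pytest.fixture()
def short_epoch():
    """A 4 s microvolt-scale epoch for fast chain tests."""
    rng = np.random.default_rng(42)
    t = np.arange(1000) / 250.0
    x = 50e-6 * np.sin(2 * np.pi * 7.0 * t) + 10e-6 * rng.standard_normal(1000)
    return EEGEpoch(samples=x, fs=250.0, label="test")
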