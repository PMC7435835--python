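import numpy as np
import pytest

import apneakit as ak


@pytest.fixture(scope="session")
def default_filter():
    return ak.design_bandpass(100.0, 0.5, 15.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-record, 6-minute cohort: cheap enough for every I/O test."""
    cfg = ak.SyntheticConfig(n_records=4, minutes_per_record=6, seed=123)
    records, truth = ak.generate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture()
def ramp_recording():
    """A 10-minute recording whose signal encodes its own sample index."""
    fs = 100.0
    n = int(10 * 60 * fs)
    signal = np.arange(n, dtype=float) * 1e-4
    labels = ["N", "A"] * 5
    return ak.ECGRecording("ramp", fs, signal, labels)
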