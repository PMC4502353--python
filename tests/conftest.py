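import numpy as np
import pytest

import selfloc as sl
from selfloc.preprocess import preprocess_subject


@pytest.fixture(scope="session")
def signal_subject():
    """Default strong-signal subject (pattern amplitude 3x noise SD)."""
    spec = sl.SimulationSpec(seed=11)
    return spec, sl.generate_subject(spec)


@pytest.fixture(scope="session")
def null_subject():
    spec = sl.SimulationSpec(seed=12)
    return spec, sl.generate_null_subject(spec)


@pytest.fixture(scope="session")
def signal_responses(signal_subject):
    spec, subj = signal_subject
    resp = preprocess_subject(
        subj.volume, subj.roi, subj.trials, spec.acquisition, sl.PreprocConfig()
    )
    clusters = sl.build_clusters(subj.roi, spec.acquisition, 15)
    return resp, clusters


@pytest.fixture(scope="session")
def null_responses(null_subject):
    spec, subj = null_subject
    resp = preprocess_subject(
        subj.volume, subj.roi, subj.trials, spec.acquisition, sl.PreprocConfig()
    )
    clusters = sl.build_clusters(subj.roi, spec.acquisition, 15)
    return resp, clusters
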