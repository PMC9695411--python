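import numpy as np
import pandas as pd
import pytest

from pnhmicro import NODULE_PRESETS, AnnotationTable, synthesize_recording


@pytest.fixture(scope="session")
def preset1():
    return NODULE_PRESETS[1]


@pytest.fixture(scope="session")
def recording():
    """A 20-minute nodule-1 surrogate with the four archetype units."""
    return synthesize_recording(nodule_id=1, duration_s=1200.0, seed=11)


@pytest.fixture
def make_annotations():
    def _make(rows):
        return AnnotationTable(
            pd.DataFrame(rows, columns=["label", "channel", "start_s", "end_s"])
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
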