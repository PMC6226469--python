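import numpy as np
import pytest

from teloforge.label_io import LabelMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_map(rng, n_labels, span=100_000, map_id="m"):
    labels = np.sort(
        rng.choice(np.arange(500, span, 500), size=n_labels, replace=False)
    ).astype(float)
    return LabelMap(map_id, float(span + 1000), labels)


@pytest.fixture
def make_map(rng):
    def _make(n_labels, span=100_000, map_id="m"):
        return random_map(rng, n_labels, span, map_id)

    return _make
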