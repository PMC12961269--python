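import numpy as np
import pytest

import fluorem as fm


@pytest.fixture
def two_channel_scheme():
    """Channel 0 labels C, channel 1 labels K."""
    return fm.LabelingScheme(channels=(frozenset("C"), frozenset("K")))


@pytest.fixture
def toy_dictionary():
    """Dictionary of the bundled synthetic five-protein database."""
    return fm.build_dictionary(fm.synthetic_proteins(), fm.DEFAULT_SCHEME)


def random_dictionary(rng, n_proteins=4, length=40):
    """A small random dictionary built from random protein sequences."""
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = [
        (f"R{i}", "".join(rng.choice(aa, size=length)))
        for i in range(n_proteins)
    ]
    return fm.build_dictionary(records, fm.DEFAULT_SCHEME)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
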