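import numpy as np
import pandas as pd
import pytest

from starterscope.community import CommunityTable


def make_table(values, samples=None, taxa=None, annotations=None, relative=False):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    taxa = taxa or [f"t{j}" for j in range(t)]
    if annotations is None:
        annotations = pd.DataFrame(
            {"kingdom": ["bacteria"] * t, "group": ["LAB"] * t}, index=taxa
        )
    return CommunityTable(pd.DataFrame(values, index=samples, columns=taxa),
                          annotations, relative=relative)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_relative_table():
    return make_table(
        [[0.7, 0.3, 0.0], [0.3, 0.7, 0.0], [0.0, 0.5, 0.5]],
        relative=True,
        annotations=pd.DataFrame(
            {"kingdom": ["bacteria", "bacteria", "fungi"],
             "group": ["LAB", "AAB", "yeast"]},
            index=["t0", "t1", "t2"],
        ),
    )
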