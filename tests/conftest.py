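import numpy as np
import pandas as pd
import pytest

from varray import VirtualArray


def make_virtual_array(values, genes=None, samples=None, batch=None, cell_type=None):
    """Build a small VirtualArray from a 2-D array plus optional metadata lists."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "platform": "p",
            "batch": batch if batch is not None else ["b1"] * n_samples,
            "cell_type": cell_type if cell_type is not None else ["x"] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return VirtualArray(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        metadata=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
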