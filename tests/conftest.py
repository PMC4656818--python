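import numpy as np
import pandas as pd
import pytest

from omicompare.microarray_de import IntensityMatrix


def make_matrix(values: np.ndarray, genotypes: list[str] | None = None) -> IntensityMatrix:
    """Build an IntensityMatrix from a raw array with auto-named rows/columns."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = None
    if genotypes is not None:
        meta = pd.DataFrame({"genotype": genotypes}, index=samples)
    return IntensityMatrix(values=pd.DataFrame(values, index=genes, columns=samples), sample_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    vals = 10.0 ** rng.normal(2.5, 1.0, size=(60, 6))
    return make_matrix(vals, genotypes=["control"] * 3 + ["case"] * 3)
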