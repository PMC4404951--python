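import numpy as np
import pandas as pd
import pytest

import halograss as hg


@pytest.fixture(scope="session")
def small_catalog():
    return hg.generate_catalog(hg.CatalogSpec(n_genes=60, seed=101))


@pytest.fixture(scope="session")
def counts_with_signal():
    """Moderate four-sample count matrix with a planted salt response."""
    cat = hg.generate_catalog(hg.CatalogSpec(n_genes=800, seed=202))
    spec = hg.DESpec(library_sizes={s: 300_000 for s in hg.SAMPLES})
    cm, truth = hg.generate_counts(cat, spec, seed=203)
    return cat, cm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_expr(rng):
    """Random strictly-positive 20 x 4 expression table."""
    vals = rng.integers(1, 60, size=(20, 4)).astype(float)
    return pd.DataFrame(vals, columns=list(hg.SAMPLES),
                        index=[f"g{i}" for i in range(20)])
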