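import numpy as np
import pandas as pd
import pytest

from nasip.fractions import FractionTable


def make_table(values, densities, missing=None, otus=None, medium="dna",
               scaled=False):
    """Build a FractionTable from a plain array; columns named F1..Fn."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    fids = [f"F{i}" for i in range(1, n + 1)]
    otus = otus or [f"otu{i}" for i in range(1, values.shape[0] + 1)]
    missing = missing or [False] * n
    vals = pd.DataFrame(values, index=pd.Index(otus, name="otu_id"),
                        columns=fids)
    for fid, m in zip(fids, missing):
        if m:
            vals[fid] = np.nan
    return FractionTable(
        vals,
        pd.Series(densities, index=fids, dtype=float),
        pd.Series(missing, index=fids),
        medium=medium,
        scaled=scaled,
    )


def random_count_table(rng, n_otu=6, n_frac=8, missing_p=0.15):
    densities = np.sort(rng.uniform(1.66, 1.83, n_frac))[::-1]
    counts = rng.integers(0, 500, size=(n_otu, n_frac)).astype(float)
    counts[rng.integers(0, n_otu), :] += 1  # avoid all-zero everywhere
    missing = list(rng.random(n_frac) < missing_p)
    return make_table(counts, densities, missing=missing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
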