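import numpy as np
import pandas as pd
import pytest

from dictycross.layout import GenomeLayout


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(
        chromosomes=(("c1", 1_000_000), ("c2", 600_000)),
        mito=("mt", 50_000),
    )


def make_obs(rows, columns=("progeny", "chrom", "pos", "contig_type",
                            "diag_parent", "depth", "n_alt", "n_ref",
                            "origin_call")) -> pd.DataFrame:
    """Hand-built observation table from tuples in column order."""
    return pd.DataFrame(rows, columns=list(columns))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
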