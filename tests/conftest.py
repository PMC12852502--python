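import numpy as np
import pandas as pd
import pytest

from streamsync.io import CommunityMatrix, CommunityTable


def make_matrix(X, site="SITE", years=None, taxa=None) -> CommunityMatrix:
    """Build a CommunityMatrix straight from a value array."""
    X = np.asarray(X, dtype=float)
    T, N = X.shape
    if years is None:
        years = np.arange(2014, 2014 + T)
    if taxa is None:
        taxa = tuple(f"t{i:02d}" for i in range(N))
    return CommunityMatrix(site, np.asarray(years), tuple(taxa), X)


@pytest.fixture
def small_table() -> CommunityTable:
    """One site, two years, two events/year, two taxa (partially recorded)."""
    rows = [
        ("A", 2014, 1, "Baetis", 1.0),
        ("A", 2014, 2, "Baetis", 3.0),
        ("A", 2014, 1, "Simulium", 2.0),
        ("A", 2015, 1, "Baetis", 5.0),
        ("A", 2015, 2, "Baetis", 7.0),
        ("A", 2015, 2, "Simulium", 4.0),
    ]
    return CommunityTable.from_frame(
        pd.DataFrame(rows, columns=["site", "year", "event", "taxon", "density"])
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140101)
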