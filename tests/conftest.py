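"""Shared fixtures: small design tables and a rendered silhouette sweep."""

from __future__ import annotations

import pandas as pd
import pytest

from dvmtest_helpers import make_silhouette_sweep, make_small_night_table


@pytest.fixture(scope="session")
def small_night_table() -> pd.DataFrame:
    return make_small_night_table()


@pytest.fixture(scope="session")
def silhouette_sweep() -> tuple[pd.DataFrame, pd.DataFrame]:
    return make_silhouette_sweep(n=120, scale_factor=1)


@pytest.fixture(scope="session")
def silhouette_sweep_scale4() -> tuple[pd.DataFrame, pd.DataFrame]:
    return make_silhouette_sweep(n=120, scale_factor=4, seed=9)
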