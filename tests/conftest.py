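"""Shared fixtures: small genotype tables and a reusable synthetic seascape."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seapop.core import GenotypeTable
from seapop.seascape import build_seascape, make_environment, place_sites


def random_table(
    n_sites: int = 3,
    n_per_site: int = 10,
    n_loci: int = 4,
    seed: int = 0,
    missing_rate: float = 0.0,
    n_alleles: int = 4,
) -> GenotypeTable:
    """A random multi-allelic table with ids following '<site>_<k>'."""
    rng = np.random.default_rng(seed)
    sites = [f"SITE{c}" for c in "ABCDEFGHIJKLMNOPQRST"[:n_sites]]
    ids, site_col, rows = [], [], []
    for s in sites:
        for k in range(n_per_site):
            ids.append(f"{s}_{k + 1:03d}")
            site_col.append(s)
            g = rng.integers(100, 100 + n_alleles, size=(n_loci, 2))
            if missing_rate:
                miss = rng.random(n_loci) < missing_rate
                g[miss] = 0
            rows.append(g)
    return GenotypeTable(
        ids, np.array(site_col, dtype=object), np.stack(rows).astype(np.int32),
        [f"LOC{j + 1}" for j in range(n_loci)],
    )


@pytest.fixture(scope="session")
def small_table() -> GenotypeTable:
    return random_table(n_sites=3, n_per_site=12, n_loci=5, seed=11)


@pytest.fixture(scope="session")
def basin():
    """One seascape + velocity field shared across the suite."""
    sea, field = build_seascape(seed=1, span_days=40)
    return sea, field


@pytest.fixture(scope="session")
def placement(basin):
    sea, _ = basin
    return place_sites(sea, 15, seed=2)


@pytest.fixture(scope="session")
def environment(basin, placement) -> pd.DataFrame:
    sea, _ = basin
    return make_environment(sea, placement, seed=3)
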