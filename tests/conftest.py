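"""Shared fixtures: tiny in-memory tables and the published study inputs.

The study-derived fixtures transcribe printed per-sample numbers (metal
concentrations, diversity values, read-accounting rows, core-OTU count rows)
that the exact-recomputation tests check against.
"""

import numpy as np
import pandas as pd
import pytest

from amplicore import OtuTable


@pytest.fixture
def small_table():
    """2 samples x 3 OTUs, integer counts (1,2,0)/(0,1,1)."""
    counts = pd.DataFrame([[1, 2, 0], [0, 1, 1]],
                          index=["A", "B"], columns=["Otu1", "Otu2", "Otu3"])
    return OtuTable(counts, label="0.03")


@pytest.fixture
def random_table_factory():
    """Factory for random integer tables with no all-zero columns."""

    def make(n_samples=5, n_otus=40, seed=0, max_count=50):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, max_count, size=(n_samples, n_otus))
        counts[0, counts.sum(axis=0) == 0] = 1
        frame = pd.DataFrame(
            counts, index=[f"S{i}" for i in range(n_samples)],
            columns=[f"Otu{j}" for j in range(n_otus)])
        return OtuTable(frame, label="0.03")

    return make


# --- published study inputs ------------------------------------------------

SAMPLES = ["A1", "A2", "O1", "O2", "O3"]

#: Bioavailable Zn (mg/kg) per sample.
ZN_BA = [521.0, 538.0, 863.0, 692.0, 1478.0]

#: Shannon's H' at the 0.03 and 0.10 OTU levels (subsample means).
SHANNON_003 = [6.367, 6.309, 5.978, 6.196, 5.321]
SHANNON_010 = [4.984, 4.800, 4.280, 4.810, 4.169]

#: Per-sample (raw, high-quality, chimera) read counts.
READ_TRIPLES = {
    "A1": (4235, 3054, 422),
    "A2": (5947, 4229, 783),
    "O1": (15967, 7474, 412),
    "O2": (17522, 6215, 363),
    "O3": (22714, 4836, 396),
}

#: Published core-OTU rows: per-sample read counts -> printed evenness.
CORE_EVENNESS_ROWS = [
    ((4, 3, 4, 6, 6), 0.979),
    ((13, 26, 24, 36, 41), 0.960),
    ((11, 3, 12, 4, 9), 0.925),
    ((6, 17, 18, 15, 3), 0.903),
    ((23, 79, 79, 140, 40), 0.902),
]


@pytest.fixture
def zn_bioavailable():
    return list(ZN_BA)


@pytest.fixture
def read_triples():
    return dict(READ_TRIPLES)
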