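import numpy as np
import pandas as pd
import pytest

import surveycost as sc


@pytest.fixture(scope="session")
def table1():
    """Packaged default cost parameters, keyed by method column."""
    return sc.default_cost_params()


@pytest.fixture(scope="session")
def rare_case():
    """Rare-case per-sample detectabilities (low-detection site)."""
    return sc.rare_case_estimates()


@pytest.fixture
def unit_design():
    return sc.EffortDesign(L=1, k=1, n=1)


@pytest.fixture(scope="session")
def plausible_list():
    return sc.load_plausible_list()


@pytest.fixture(scope="session")
def community_table():
    return sc.load_community_table()


@pytest.fixture(scope="session")
def goby_cost_map(table1):
    """Single-species cost parameters keyed by detection-method name."""
    return {
        "seine": table1["goby_seine"],
        "qPCR": table1["qPCR"],
        "metabarcode": table1["goby_metabarcode"],
    }


def tiny_incidence():
    """Three single-sample sites with known species sets (enumeration oracle)."""
    return pd.DataFrame(
        [
            {"site_id": "A", "s1": 1, "s2": 1, "s3": 0, "s4": 0},
            {"site_id": "B", "s1": 0, "s2": 1, "s3": 0, "s4": 0},
            {"site_id": "C", "s1": 0, "s2": 0, "s3": 1, "s4": 1},
        ]
    )


@pytest.fixture
def tiny_matrix():
    return tiny_incidence()


def enumerate_orderings(matrix):
    """Exact collector-curve mean/median by brute force over all site orderings.

    Independent oracle for the resampler: every permutation of the sites is
    enumerated (one sample per site), cumulative richness recorded, and the
    mean/median taken with equal weight per ordering.
    """
    from itertools import permutations

    species = [c for c in matrix.columns if c not in ("site_id", "sample_id")]
    sets = [frozenset(s for s in species if row[s] > 0) for _, row in matrix.iterrows()]
    k = len(sets)
    richness = []  # one row per ordering, one column per prefix length
    for order in permutations(range(k)):
        seen, row = set(), []
        for i in order:
            seen |= sets[i]
            row.append(len(seen))
        richness.append(row)
    arr = np.array(richness)
    return arr.mean(axis=0), np.median(arr, axis=0)
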