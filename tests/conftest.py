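from math import comb

import numpy as np
import pytest

from icgflap import ConfusionTable, simulate_case


@pytest.fixture(scope="session")
def table2() -> ConfusionTable:
    """The study's predictor-vs-necrosis confusion counts (9 positives,
    8 true, across 53 breasts)."""
    return ConfusionTable(tp=8, fp=1, fn=0, tn=44)


@pytest.fixture(scope="session")
def noise_free_case():
    """Small noise-free recording with ~20% hypoperfused ground truth."""
    return simulate_case(
        height=96, width=112, n_territories=10,
        target_dropout_fraction=20.0, dropout_factor=0.15, seed=11,
    )


def fisher_enumeration_oracle(tp: int, fp: int, fn: int, tn: int) -> float:
    """Two-sided Fisher p by full enumeration with exact integer arithmetic.

    Sums hypergeometric probabilities (computed from binomial coefficients,
    independent of any statistics library) of every margin-consistent table
    whose probability is at most the observed table's, with a 1e-7 relative
    tolerance for floating-point ties.
    """
    r1, r2, c1 = tp + fp, fn + tn, tp + fn
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(a: int) -> float:
        return comb(r1, a) * comb(r2, c1 - a) / denom

    p_obs = pmf(tp)
    total = sum(
        pmf(a)
        for a in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(a) <= p_obs * (1 + 1e-7)
    )
    return min(1.0, total)


def random_confusion_tables(n_tables: int, seed: int, max_cell: int = 25):
    rng = np.random.default_rng(seed)
    tables = rng.integers(0, max_cell + 1, size=(n_tables, 4))
    # at least one observation per table
    tables[tables.sum(axis=1) == 0, 0] = 1
    return [tuple(int(v) for v in row) for row in tables]
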