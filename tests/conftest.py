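import math

import numpy as np
import pandas as pd
import pytest

from ratecap import RatingDataset


def naive_mi_bits(counts):
    """Independent brute-force MI oracle: explicit loops over every cell.

    Scalar arithmetic only, no vectorization; shared by unit and
    acceptance tests as the reference for the plug-in estimator.
    """
    counts = [[int(c) for c in row] for row in counts]
    n = sum(sum(row) for row in counts)
    row_tot = [sum(row) for row in counts]
    col_tot = [sum(counts[i][j] for i in range(len(counts)))
               for j in range(len(counts[0]))]
    total = 0.0
    for i in range(len(counts)):
        for j in range(len(counts[0])):
            c = counts[i][j]
            if c == 0:
                continue
            pxy = c / n
            px = row_tot[i] / n
            py = col_tot[j] / n
            total += pxy * math.log2(pxy / (px * py))
    return total


def make_dataset(ratings_by_cell, scale=(1, 10), repetitions=None):
    """Build a RatingDataset from {participant: {block: {stimulus: [r...]}}}."""
    rows = []
    for p, blocks in ratings_by_cell.items():
        for b, stimuli in blocks.items():
            for s, ratings in stimuli.items():
                for i, r in enumerate(ratings, start=1):
                    rows.append({"participant": p, "block": b,
                                 "stimulus": s, "repetition": i,
                                 "rating": r})
    return RatingDataset(pd.DataFrame(rows), scale[0], scale[1],
                         repetitions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_tables(rng):
    """200 random contingency tables up to 10x10, occupancy varied."""
    tables = []
    for _ in range(200):
        kx = rng.integers(2, 11)
        ky = rng.integers(2, 11)
        counts = rng.integers(0, 8, size=(kx, ky))
        if counts.sum() == 0:
            counts[0, 0] = 1
        tables.append(counts)
    return tables
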