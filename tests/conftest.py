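import numpy as np
import pandas as pd
import pytest

import radsexing as rs


@pytest.fixture
def noiseless_cohort():
    """3 males + 3 females, one planted Y locus, no dropout."""
    truth, counts = rs.simulate_cohort(
        n_males=3, n_females=3, n_contigs=20, n_y_loci=1, dropout_prob=0.0, seed=11
    )
    return truth, counts


@pytest.fixture
def small_pedigree():
    """100 unrelated founders plus 10 offspring of distinct founder pairs."""
    founders = [f"f{i:03d}" for i in range(100)]
    kids = [f"o{i:02d}" for i in range(10)]
    ped = pd.DataFrame({
        "individual_id": founders + kids,
        "mother_id": [None] * 100 + [f"f{2 * i:03d}" for i in range(10)],
        "father_id": [None] * 100 + [f"f{2 * i + 1:03d}" for i in range(10)],
    })
    return ped, founders, kids


def presence_from_bool(rows, individuals, ids=None):
    """Build a PresenceMatrix directly from a 0/1 array."""
    arr = np.asarray(rows, dtype=bool)
    ids = ids or [f"c{i}" for i in range(arr.shape[0])]
    return rs.PresenceMatrix(
        contig_ids=tuple(ids),
        individual_ids=tuple(individuals),
        matrix=arr,
        min_reads=1,
    )
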