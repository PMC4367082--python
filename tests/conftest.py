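import pytest

from predbench.consensus import ConsensusCategory as C

# Per-class consensus category counts for the two panels (all_correct /
# two_correct / two_incorrect / all_incorrect / inconsistent splits by
# credibility class), used to build deterministic consensus fixtures.
RAS_CONSENSUS_COUNTS = {
    C.ALL_CORRECT: {"credibly_pathogenic": 18, "credibly_benign": 11},
    C.TWO_CORRECT: {"credibly_pathogenic": 11, "credibly_benign": 6},
    C.TWO_INCORRECT: {"credibly_pathogenic": 2},
    C.INCONSISTENT: {"credibly_pathogenic": 3, "credibly_benign": 2},
}
LGMD_CONSENSUS_COUNTS = {
    C.ALL_CORRECT: {"credibly_pathogenic": 21, "credibly_benign": 11},
    C.TWO_CORRECT: {"credibly_pathogenic": 11, "credibly_benign": 11},
    C.ALL_INCORRECT: {"credibly_pathogenic": 2, "credibly_benign": 1},
    C.TWO_INCORRECT: {"credibly_benign": 8},
    C.INCONSISTENT: {"credibly_pathogenic": 3},
}

# Confusion compositions (TP, FP, TN, FN, n_possible) realizing published
# per-program performance rows, with the seven statistics each should yield
# after 3-decimal half-up rounding.
TABLE_ROWS = {
    ("SIFT", "RAS"): ((27, 2, 16, 2, 7), (0.931, 0.889, 0.889, 0.931, 0.915, 0.870, 0.796)),
    ("MutationTaster", "RAS"): ((34, 12, 3, 0, 4), (0.739, 1.000, 0.200, 1.000, 0.755, 0.925, 0.698)),
    ("MutPred", "RAS"): ((28, 0, 16, 0, 9), (1.000, 1.000, 1.000, 1.000, 1.000, 0.830, 0.830)),
    ("MutPred", "LGMD"): ((31, 3, 25, 2, 7), (0.912, 0.926, 0.893, 0.939, 0.918, 0.897, 0.824)),
    ("PMut", "LGMD"): ((11, 7, 10, 8, 32), (0.611, 0.556, 0.588, 0.579, 0.583, 0.529, 0.309)),
    ("Mutation assessor", "LGMD"): ((4, 0, 11, 12, 19), (1.000, 0.478, 1.000, 0.250, 0.556, 0.587, 0.326)),
}


@pytest.fixture
def ras_consensus_counts():
    return RAS_CONSENSUS_COUNTS


@pytest.fixture
def lgmd_consensus_counts():
    return LGMD_CONSENSUS_COUNTS


@pytest.fixture
def table_rows():
    return TABLE_ROWS
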