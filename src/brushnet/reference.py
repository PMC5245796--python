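"""Published-style summary statistics of the study cohort.

The empirical cohort behind this package is a single-school sample of 201
female middle-school students in 7 classrooms, assessed twice five months
apart.  Only marginal summaries of that cohort are public: the brushing
frequency table, the out-degree histogram, and the binned mutual-friendship
percentages.  These constants are the package's single source for those
summaries — the synthetic-cohort generator uses them as its default targets
and the reporting tools recompute the headline means from them.

Brushing is scored on an ordinal 1–4 scale where *lower is better*:
1 = twice or more per day, 2 = once daily, 3 = a few times per week,
4 = never.
"""

from __future__ import annotations

import numpy as np

N_STUDENTS = 201
N_CLASSROOMS = 7

#: Brushing-level counts (levels 1..4) at each assessment round.
BRUSHING_COUNTS_ROUND1 = {1: 79, 2: 97, 3: 21, 4: 4}
BRUSHING_COUNTS_ROUND2 = {1: 98, 2: 88, 3: 11, 4: 4}

#: Out-degree histogram (number of friends named, 0..5) at each round.
OUT_DEGREE_COUNTS_ROUND1 = {0: 11, 1: 0, 2: 8, 3: 34, 4: 41, 5: 107}
OUT_DEGREE_COUNTS_ROUND2 = {0: 13, 1: 1, 2: 7, 3: 23, 4: 60, 5: 97}

#: Binned per-student mutual-friendship percentages at each round.
MUTUALITY_BIN_COUNTS_ROUND1 = {0: 34, 20: 53, 40: 57, 60: 43, 80: 8, 100: 6}
MUTUALITY_BIN_COUNTS_ROUND2 = {0: 44, 20: 54, 40: 38, 60: 39, 80: 20, 100: 6}

#: Observed network turnover between the two rounds, D = sum |y_ij - x_ij|,
#: out of the maximum N * 2 * mean-ish out-degree bound of 1608.
EMPIRICAL_NETWORK_CHANGE_D = 628

#: Calibrated weekly behaviour-change probability, static-network model.
U_STATIC = 0.02
#: Calibrated weekly behaviour-change probability, rewiring-network model.
U_DYNAMIC = 0.023
#: Calibrated weekly rewiring probability.
P_REWIRE = 0.2
#: Elapsed weeks between the two assessments (5 months).
FOLLOWUP_WEEKS = 22
#: Replicates averaged for every reported simulation result.
ENSEMBLE_SIZE = 100
#: Students trained in the intervention scenarios.
N_TRAINED = 10


def histogram_mean(counts: dict[int, int]) -> float:
    """Weighted mean of a value→count histogram."""
    values = np.array(list(counts.keys()), dtype=float)
    weights = np.array(list(counts.values()), dtype=float)
    return float(np.average(values, weights=weights))


def histogram_to_vector(counts: dict[int, int]) -> np.ndarray:
    """Expand a value→count histogram into the per-student value vector."""
    return np.repeat(
        np.array(list(counts.keys())), np.array(list(counts.values()))
    )


def probability_mass(counts: dict[int, int]) -> np.ndarray:
    """Normalise a histogram over consecutive keys into a probability mass."""
    keys = sorted(counts)
    total = sum(counts.values())
    return np.array([counts[k] / total for k in keys], dtype=float)
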