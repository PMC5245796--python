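"""Synthetic school cohorts matching the study's published marginals.

Only marginal summaries of the empirical cohort are public: 201 girls in 7
classrooms, the out-degree histogram (mean ~4.06, cap 5), ~35.6% mean
mutual naming, classroom-dominated clustering, the brushing-level marginals
(mean 1.75 at round 1), a positive friend–friend behaviour association and
a negative popularity–score association.  This module generates cohorts
reproducing those marginals so the whole pipeline — statistics,
calibration, scenarios — is exercisable without the (unpublished)
individual-level data.

The generator works in two stages.  ``generate_network`` lays down mutual
dyads first (to hit the reciprocity target exactly by construction) and
then fills the remaining out-stubs with one-way, mostly within-classroom
edges.  ``generate_behavior`` draws the exact level counts implied by the
marginal distribution and assigns them to students by the rank of a latent
propensity mixing a network-smoothed field (friend–friend assortativity)
and in-degree (popularity coupling) — a reassignment of a fixed multiset,
so the marginal counts are conserved by construction at any strengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .behavior import BehaviorVector
from .network import MAX_NAMED_FRIENDS, FriendshipMatrix, NetworkError
from .simulate import SimulationParams, SimulationState, run


def _default_out_degree_dist() -> np.ndarray:
    return ref.probability_mass(ref.OUT_DEGREE_COUNTS_ROUND1)


def _default_brushing_dist() -> np.ndarray:
    return ref.probability_mass(ref.BRUSHING_COUNTS_ROUND1)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study cohort's published round-1 marginals;
    ``assortativity`` and ``popularity_coupling`` are free strengths in
    [0, 1] tuned (see docs) so the default cohort shows a clearly
    significant direct-friend association, a usually non-significant
    level-2 association, and a significantly negative popularity slope.
    """

    n_students: int = ref.N_STUDENTS
    n_classrooms: int = ref.N_CLASSROOMS
    out_degree_dist: np.ndarray = field(default_factory=_default_out_degree_dist)
    reciprocity_target: float = 35.6  # mean % of named friends naming back
    within_class_prob: float = 0.9
    brushing_dist: np.ndarray = field(default_factory=_default_brushing_dist)
    assortativity: float = 0.8
    popularity_coupling: float = 0.35
    seed: "int | None" = None

    def __post_init__(self) -> None:
        self.out_degree_dist = np.asarray(self.out_degree_dist, dtype=float)
        self.brushing_dist = np.asarray(self.brushing_dist, dtype=float)
        if self.out_degree_dist.size != MAX_NAMED_FRIENDS + 1:
            raise ValueError("out_degree_dist must cover degrees 0..5")
        if self.brushing_dist.size != 4:
            raise ValueError("brushing_dist must cover levels 1..4")
        for dist in (self.out_degree_dist, self.brushing_dist):
            if (dist < 0).any() or not np.isclose(dist.sum(), 1.0):
                raise ValueError("distributions must be nonnegative and sum to 1")
        for strength in (self.assortativity, self.popularity_coupling):
            if not 0.0 <= strength <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")
        if not 0.0 <= self.within_class_prob <= 1.0:
            raise ValueError("within_class_prob must lie in [0, 1]")
        if self.n_classrooms > self.n_students or self.n_classrooms < 1:
            raise ValueError("need 1 <= n_classrooms <= n_students")


def _classroom_labels(spec: CohortSpec) -> np.ndarray:
    sizes = np.full(spec.n_classrooms, spec.n_students // spec.n_classrooms)
    sizes[: spec.n_students % spec.n_classrooms] += 1
    return np.repeat(np.arange(1, spec.n_classrooms + 1), sizes)


def _pick(rng: np.random.Generator, pool: np.ndarray) -> int:
    return int(pool[rng.integers(pool.size)])


def generate_network(
    spec: CohortSpec, rng: "np.random.Generator | None" = None
) -> FriendshipMatrix:
    """Sample a classroom-structured friendship network.

    Out-degrees are drawn from ``spec.out_degree_dist``; a fraction of the
    out-stubs fixed by ``reciprocity_target`` is consumed by mutual dyads
    laid down first; remaining stubs become one-way edges that avoid
    creating extra reciprocity, each edge joining classmates with
    probability ``within_class_prob``.  Largest feasible classrooms are
    required: a classroom must offer enough eligible partners for the cap.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_students
    classroom = _classroom_labels(spec)
    smallest = np.unique(classroom, return_counts=True)[1].min() if n else 0
    if smallest <= MAX_NAMED_FRIENDS:
        raise NetworkError("classrooms too small for the friend cap")
    degrees = rng.choice(MAX_NAMED_FRIENDS + 1, size=n, p=spec.out_degree_dist)
    adj = np.zeros((n, n), dtype=np.uint8)
    capacity = degrees.astype(np.int64).copy()

    # Phase 1 - mutual dyads. Students with out-degree 0 never reciprocate,
    # so the per-student mean mutuality (isolates counted as 0%) is the
    # edge-level fraction shrunk by the share of positive-degree students;
    # inflate the dyad budget accordingly.
    total_stubs = int(capacity.sum())
    n_positive = int((degrees > 0).sum())
    scale = n / n_positive if n_positive else 0.0
    n_dyads = int(round(spec.reciprocity_target / 100.0 * scale * total_stubs / 2))
    attempts = 0
    placed = 0
    while placed < n_dyads and attempts < 60 * max(n_dyads, 1):
        attempts += 1
        open_students = np.flatnonzero(capacity > 0)
        if open_students.size < 2:
            break
        a = _pick(rng, open_students)
        same = classroom == classroom[a]
        if rng.random() >= spec.within_class_prob:
            same = ~same
        eligible = (capacity > 0) & same & (adj[a] == 0) & (adj[:, a] == 0)
        eligible[a] = False
        pool = np.flatnonzero(eligible)
        if pool.size == 0:
            continue
        b = _pick(rng, pool)
        adj[a, b] = adj[b, a] = 1
        capacity[a] -= 1
        capacity[b] -= 1
        placed += 1

    # Phase 2 - one-way edges for the remaining stubs, avoiding accidental
    # reciprocation so realized mutuality stays at the phase-1 level.
    for i in rng.permutation(n):
        while capacity[i] > 0:
            placed_edge = False
            for relax in range(3):
                same = classroom == classroom[i]
                if relax == 0 and rng.random() >= spec.within_class_prob:
                    same = ~same
                if relax == 2:
                    same = np.ones(n, dtype=bool)
                eligible = same & (adj[i] == 0)
                if relax == 0:
                    eligible &= adj[:, i] == 0
                eligible[i] = False
                pool = np.flatnonzero(eligible)
                if pool.size:
                    adj[i, _pick(rng, pool)] = 1
                    capacity[i] -= 1
                    placed_edge = True
                    break
            if not placed_edge:
                raise NetworkError("cohort spec infeasible: no eligible friend")
    return FriendshipMatrix(adj, classroom)


def _exact_level_counts(dist: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of dist * n to integer counts summing n."""
    raw = dist * n
    counts = np.floor(raw).astype(np.int64)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_behavior(
    network: FriendshipMatrix,
    spec: CohortSpec,
    rng: "np.random.Generator | None" = None,
) -> "tuple[BehaviorVector, pd.DataFrame]":
    """Draw brushing scores (and SES covariates) coupled to the network.

    The level counts are the largest-remainder rounding of
    ``brushing_dist * N`` and are preserved exactly: the coupling only
    reassigns the fixed score multiset between students.  A latent
    propensity is built per student — ``assortativity`` weights a smooth
    network field (each student's Gaussian draw blended with her named
    friends' draws, so adjacent students share latent mass),
    ``popularity_coupling`` weights standardized in-degree with a negative
    sign (higher in-degree → better, i.e. lower, score), and the residual
    weight is independent noise.  Scores are then assigned by latent rank,
    which conserves the marginal counts exactly at any strengths.  SES
    economy/education scores are independent ordinal 1–5 draws.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = network.n_students
    counts = _exact_level_counts(spec.brushing_dist, n)
    multiset = np.repeat(np.arange(1, 5), counts)

    a, c = spec.assortativity, spec.popularity_coupling
    if a == 0 and c == 0:
        scores = rng.permutation(multiset)
    else:
        def z(x: np.ndarray) -> np.ndarray:
            sd = x.std()
            return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

        g = rng.normal(size=n)
        adjf = network.adj.astype(float)
        deg = adjf.sum(axis=1)
        friend_mean = (adjf @ g) / np.maximum(deg, 1)
        friend_mean[deg == 0] = 0.0
        field = z(g + friend_mean)  # shared terms correlate adjacent students
        indeg_z = z(network.in_degree().astype(float))
        residual = np.sqrt(max(1.0 - a**2 - c**2, 0.05))
        latent = a * field - c * indeg_z + residual * rng.normal(size=n)
        order = np.argsort(latent)  # lowest latent -> best (lowest) score
        scores = np.empty(n, dtype=np.int64)
        scores[order] = np.sort(multiset)

    ses = pd.DataFrame(
        {
            "econ": rng.integers(1, 6, size=n),
            "edu": rng.integers(1, 6, size=n),
        }
    )
    return BehaviorVector(scores, round_label="round1"), ses


def generate_cohort(
    spec: CohortSpec, rng: "np.random.Generator | None" = None
) -> "tuple[SimulationState, pd.DataFrame]":
    """Network + behaviour as a week-0 simulation state, plus SES table."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    network = generate_network(spec, rng)
    behavior, ses = generate_behavior(network, spec, rng)
    return SimulationState(network, behavior, week=0), ses


def emulate_study_pair(
    spec: CohortSpec,
    u: float = ref.U_DYNAMIC,
    p: float = ref.P_REWIRE,
    weeks: int = ref.FOLLOWUP_WEEKS,
    rng: "np.random.Generator | None" = None,
) -> "tuple[SimulationState, SimulationState]":
    """A paired two-round fixture: round 1 generated, round 2 simulated.

    Round 2 is the round-1 cohort stepped through the calibrated dynamic
    model (default u = 0.023, p = 0.2, 22 weeks), giving a pair whose
    network turnover D, mean-score change and correlation-length change
    can be compared to the empirical directions (D in the hundreds, mean
    score falls, correlation length grows).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    round1, _ = generate_cohort(spec, rng)
    params = SimulationParams(u=u, p=p, horizon_weeks=weeks, ensemble_size=1)
    trajectory = run(round1, params, rng)
    round2 = trajectory[-1]
    round2.behavior.round_label = "round2"
    return round1, round2
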