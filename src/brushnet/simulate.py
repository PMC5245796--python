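"""Weekly agent-based models of brushing-behaviour diffusion.

Two model variants share one update rule for behaviour and differ in
whether the friendship network itself moves:

* **static** (``p = 0``): each week every student independently decides,
  with probability ``u``, to move her brushing score one level toward the
  mean score of the friends she named; the network never changes.
* **dynamic** (``p > 0``): additionally, each week every student with at
  least one named friend decides with probability ``p`` to drop one named
  friend at random and befriend a random student at directed distance
  exactly 2 from her, keeping her out-degree constant.

Behaviour updates are synchronous — every student compares herself to last
week's scores — which makes a week's outcome independent of student
ordering.  Rewiring is applied student-by-student in id order within the
week (each girl sees the network as already rewired by lower-id students),
behaviour first, rewiring second.  All randomness flows through a single
`numpy` Generator per run, consumed in fixed student-id order, so a run is
bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .behavior import BehaviorVector
from .network import FriendshipMatrix


class SimulationError(ValueError):
    """Raised for invalid simulation parameters or states."""


@dataclass
class SimulationParams:
    """Weekly-tick model parameters.

    ``u``/``p`` are per-student weekly probabilities of a behaviour change
    and of a friendship rewiring; ``p = 0`` gives the static-network model.
    """

    u: float
    p: float = 0.0
    horizon_weeks: int = 22
    ensemble_size: int = 100
    seed: "int | None" = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0 or not 0.0 <= self.p <= 1.0:
            raise SimulationError("u and p must lie in [0, 1]")
        if self.horizon_weeks < 1:
            raise SimulationError("horizon must be at least one week")
        if self.ensemble_size < 1:
            raise SimulationError("ensemble size must be at least 1")

    @property
    def is_static(self) -> bool:
        return self.p == 0.0


@dataclass
class SimulationState:
    """Network plus behaviour at one week."""

    network: FriendshipMatrix
    behavior: BehaviorVector
    week: int = 0

    def __post_init__(self) -> None:
        if len(self.behavior) != self.network.n_students:
            raise SimulationError("behavior vector does not align with network")

    def copy(self) -> "SimulationState":
        return SimulationState(self.network.copy(), self.behavior.copy(), self.week)


def behavior_update(
    state: SimulationState, u: float, rng: np.random.Generator
) -> BehaviorVector:
    """One synchronous week of behaviour change.

    Each student with at least one named friend moves, with probability
    ``u``, one level toward the (unrounded) mean score of her friends:
    down a level if she scores above the mean, up if below, nowhere on an
    exact tie.  Isolated students never change.  Comparisons use integer
    arithmetic (``sum - score * degree``) so ties are exact.
    """
    adj = state.network.adj
    scores = state.behavior.scores
    deg = adj.sum(axis=1).astype(np.int64)
    friend_sum = adj.astype(np.int64) @ scores
    direction = np.sign(friend_sum - scores * deg)
    draws = rng.random(scores.size)
    move = (draws < u) & (deg > 0) & (direction != 0)
    return BehaviorVector(
        scores + np.where(move, direction, 0), state.behavior.round_label
    )


def rewire_update(
    state: SimulationState, p: float, rng: np.random.Generator
) -> FriendshipMatrix:
    """One week of friendship rewiring (out-degree conserving).

    For each student with out-degree >= 1, with probability ``p``: remove
    one uniformly chosen out-edge, then add an out-edge to a uniformly
    chosen student at directed distance exactly 2 in the post-removal
    network, excluding herself and her remaining friends.  If no candidate
    exists the removal is reverted and her ties are untouched that week.
    """
    adj = state.network.adj.copy()
    n = adj.shape[0]
    decide = rng.random(n)
    # per-student draws are consumed in ascending id order for replicability
    for i in np.flatnonzero(decide < p):
        out = np.flatnonzero(adj[i])
        if out.size == 0:
            continue
        dropped = out[rng.integers(out.size)]
        adj[i, dropped] = 0
        remaining = np.flatnonzero(adj[i])
        if remaining.size == 0:
            adj[i, dropped] = 1
            continue
        candidates = adj[remaining].any(axis=0)
        candidates[i] = False
        candidates[remaining] = False
        pool = np.flatnonzero(candidates)
        if pool.size == 0:
            adj[i, dropped] = 1
        else:
            adj[i, pool[rng.integers(pool.size)]] = 1
    return FriendshipMatrix(adj, state.network.classroom)


def iterate(
    initial_state: SimulationState,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Iterator[SimulationState]:
    """Yield the state at weeks 0..horizon (behaviour step, then rewiring)."""
    state = initial_state
    yield state
    for week in range(1, params.horizon_weeks + 1):
        behavior = behavior_update(state, params.u, rng)
        state = SimulationState(state.network, behavior, week)
        if params.p > 0:
            network = rewire_update(state, params.p, rng)
            state = SimulationState(network, behavior, week)
        yield state


def run(
    initial_state: SimulationState,
    params: SimulationParams,
    rng: "np.random.Generator | None" = None,
) -> list[SimulationState]:
    """Full trajectory (length ``horizon + 1`` including week 0).

    Reproducible from ``(initial_state, params.seed)``; pass an explicit
    ``rng`` to chain several runs off one stream.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return [s.copy() for s in iterate(initial_state, params, rng)]


#: A statistic hook maps a SimulationState to one number.
StatisticHook = Callable[[SimulationState], float]


def count_at_level(level: int = 1) -> StatisticHook:
    """Hook: number of students at the given brushing level."""

    def hook(state: SimulationState) -> float:
        return float((state.behavior.scores == level).sum())

    return hook


def mean_score_hook(state: SimulationState) -> float:
    return float(state.behavior.scores.mean())


def difference_from(reference: FriendshipMatrix) -> StatisticHook:
    """Hook: turnover D between the reference network and the current one."""
    from .network import matrix_difference

    def hook(state: SimulationState) -> float:
        return float(matrix_difference(reference, state.network))

    return hook


@dataclass
class EnsembleResult:
    """Per-week ensemble means and standard errors of hooked statistics."""

    weeks: np.ndarray
    mean: pd.DataFrame  # index: week, columns: statistic names
    sem: pd.DataFrame
    ensemble_size: int


def replicate_rngs(seed: "int | None", n: int) -> list[np.random.Generator]:
    """Independent child generators derived from one master seed."""
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in seq.spawn(n)]


def run_ensemble(
    initial_state: SimulationState,
    params: SimulationParams,
    hooks: "dict[str, StatisticHook]",
) -> EnsembleResult:
    """Average hooked statistics per week over independent replicates.

    Replicate seeds are spawned from ``params.seed``, so the whole ensemble
    is reproducible and replicates stay independent.
    """
    n_rep, horizon = params.ensemble_size, params.horizon_weeks
    values = {name: np.empty((n_rep, horizon + 1)) for name in hooks}
    for r, rng in enumerate(replicate_rngs(params.seed, n_rep)):
        for state in iterate(initial_state, params, rng):
            for name, hook in hooks.items():
                values[name][r, state.week] = hook(state)
    weeks = np.arange(horizon + 1)
    mean = pd.DataFrame({k: v.mean(axis=0) for k, v in values.items()}, index=weeks)
    sem = pd.DataFrame(
        {k: v.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.zeros(horizon + 1)
         for k, v in values.items()},
        index=weeks,
    )
    mean.index.name = sem.index.name = "week"
    return EnsembleResult(weeks=weeks, mean=mean, sem=sem, ensemble_size=n_rep)


def final_states(
    initial_state: SimulationState, params: SimulationParams
) -> list[SimulationState]:
    """Final week's state of each replicate (cheap form of an ensemble)."""
    finals = []
    for rng in replicate_rngs(params.seed, params.ensemble_size):
        state = initial_state
        for state in iterate(initial_state, params, rng):
            pass
        finals.append(state.copy())
    return finals
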