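"""Grid-search calibration of (u, p) and the training-scenario experiments.

Calibration mirrors the study design: the two free weekly probabilities
are fitted one at a time against two empirical-style targets measured at
the follow-up assessment.  The rewiring probability ``p`` is fitted first,
against the observed network turnover ``D`` between the two rounds; the
behaviour-change probability ``u`` is then fitted against the follow-up
cross-correlation curve CC_i.  Both objectives are evaluated on
ensemble-averaged simulations from the round-1 state.

The scenario experiments compare three week-0 interventions — no training,
training ``n`` random students, training the ``n`` most popular
(highest in-degree) students — by the ensemble-mean weekly count of
students at the best brushing level (score 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorVector, CorrelationCurve, correlation_curve
from .network import FriendshipMatrix, matrix_difference
from .simulate import (
    SimulationParams,
    SimulationState,
    count_at_level,
    final_states,
    iterate,
    replicate_rngs,
)


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs."""


@dataclass
class CalibrationTarget:
    """Follow-up targets the model is fitted against."""

    target_curve: "CorrelationCurve | None" = None
    target_d: "float | None" = None
    followup_weeks: int = 22

    def __post_init__(self) -> None:
        if self.followup_weeks < 1:
            raise CalibrationError("followup_weeks must be >= 1")
        if self.target_d is not None and self.target_d < 0:
            raise CalibrationError("target D must be nonnegative")


@dataclass
class CalibrationResult:
    """Best grid point plus the full objective profile."""

    best: float
    grid: np.ndarray
    objective: np.ndarray

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.grid, "objective": self.objective})


def weeks_per_event(probability: float) -> int:
    """Mean waiting time, in whole weeks, of a weekly-probability event.

    The reciprocal of a weekly probability is the expected number of weeks
    between events for one student (u = 0.02 → one behaviour change every
    50 weeks; p = 0.2 → one rewiring every 5 weeks).
    """
    if probability <= 0:
        raise CalibrationError("probability must be positive")
    return int(round(1.0 / probability))


def _mean_final_d(
    initial: SimulationState, params: SimulationParams
) -> float:
    reference = initial.network
    finals = final_states(initial, params)
    return float(
        np.mean([matrix_difference(reference, s.network) for s in finals])
    )


def calibrate_p(
    initial: SimulationState,
    target: CalibrationTarget,
    u_fixed: float,
    p_grid: np.ndarray,
    ensemble_size: int = 100,
    seed: "int | None" = None,
) -> CalibrationResult:
    """Fit the weekly rewiring probability against network turnover D.

    For each grid value the dynamic model runs ``followup_weeks`` and the
    ensemble-mean D between the initial and final networks is compared to
    ``target.target_d``; the absolute difference is minimised, ties broken
    toward smaller p.
    """
    p_grid = np.sort(np.asarray(p_grid, dtype=float))
    if p_grid.size == 0:
        raise CalibrationError("p grid must be nonempty")
    if target.target_d is None:
        raise CalibrationError("target_d is required to calibrate p")
    objective = np.empty(p_grid.size)
    for k, p in enumerate(p_grid):
        params = SimulationParams(
            u=u_fixed,
            p=float(p),
            horizon_weeks=target.followup_weeks,
            ensemble_size=ensemble_size,
            seed=seed,
        )
        objective[k] = abs(_mean_final_d(initial, params) - target.target_d)
    return CalibrationResult(
        best=float(p_grid[int(np.argmin(objective))]),
        grid=p_grid,
        objective=objective,
    )


def ensemble_curve(
    initial: SimulationState,
    params: SimulationParams,
    max_level: int = 4,
    average: str = "curves",
) -> CorrelationCurve:
    """Ensemble-mean follow-up correlation curve (normalized mode).

    ``average="curves"`` (default) averages per-replicate Pearson curves
    level-wise, skipping undefined replicates; ``average="vectors"``
    averages the final V0 and V_i vectors across replicates first and
    correlates the averages — both orders are exposed because reported
    curves could have been produced either way.
    """
    finals = final_states(initial, params)
    if average == "curves":
        stacked = np.vstack(
            [
                correlation_curve(s.network, s.behavior, max_level).values
                for s in finals
            ]
        )
        n_def = np.vstack(
            [
                correlation_curve(s.network, s.behavior, max_level).n_defined
                for s in finals
            ]
        )
        with np.errstate(invalid="ignore"):
            values = np.nanmean(stacked, axis=0)
        return CorrelationCurve(
            levels=np.arange(1, max_level + 1),
            values=values,
            n_defined=n_def.mean(axis=0).round().astype(np.int64),
        )
    if average != "vectors":
        raise CalibrationError(f"unknown averaging order {average!r}")
    from .behavior import cross_correlation, friend_average_vector
    from .network import level_masks

    v0_stack, vi_stack = [], []
    for s in finals:
        masks = level_masks(s.network, max_level)
        v0_stack.append(s.behavior.scores.astype(float))
        vi_stack.append(
            np.vstack(
                [
                    friend_average_vector(s.network, s.behavior, lvl, masks=masks)
                    for lvl in range(1, max_level + 1)
                ]
            )
        )
    v0_mean = np.mean(v0_stack, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN entries
        vi_mean = np.nanmean(np.stack(vi_stack), axis=0)
    values = np.full(max_level, np.nan)
    n_def = np.zeros(max_level, dtype=np.int64)
    for idx in range(max_level):
        defined = ~np.isnan(vi_mean[idx])
        n_def[idx] = int(defined.sum())
        try:
            values[idx] = cross_correlation(v0_mean, vi_mean[idx])
        except Exception:
            pass
    return CorrelationCurve(
        levels=np.arange(1, max_level + 1), values=values, n_defined=n_def
    )


def calibrate_u(
    initial: SimulationState,
    target: CalibrationTarget,
    p_fixed: float,
    u_grid: np.ndarray,
    ensemble_size: int = 100,
    max_level: int = 4,
    seed: "int | None" = None,
    average: str = "curves",
) -> CalibrationResult:
    """Fit the weekly behaviour-change probability against the CC curve.

    For each grid value the model runs ``followup_weeks`` and the
    ensemble-mean normalized correlation curve is compared to the target
    curve by the sum of squared differences over levels defined in both;
    ties broken toward smaller u.
    """
    u_grid = np.sort(np.asarray(u_grid, dtype=float))
    if u_grid.size == 0:
        raise CalibrationError("u grid must be nonempty")
    if target.target_curve is None:
        raise CalibrationError("target_curve is required to calibrate u")
    tgt = target.target_curve.values
    objective = np.empty(u_grid.size)
    for k, u in enumerate(u_grid):
        params = SimulationParams(
            u=float(u),
            p=p_fixed,
            horizon_weeks=target.followup_weeks,
            ensemble_size=ensemble_size,
            seed=seed,
        )
        curve = ensemble_curve(initial, params, max_level=max_level, average=average)
        m = min(tgt.size, curve.values.size)
        common = ~(np.isnan(tgt[:m]) | np.isnan(curve.values[:m]))
        if not common.any():
            raise CalibrationError("no commonly defined correlation levels")
        objective[k] = float(((curve.values[:m] - tgt[:m])[common] ** 2).sum())
    return CalibrationResult(
        best=float(u_grid[int(np.argmin(objective))]),
        grid=u_grid,
        objective=objective,
    )


SCENARIO_NAMES = ("no_training", "random_training", "popular_training")


@dataclass
class ScenarioSpec:
    """A week-0 training intervention."""

    name: str = "no_training"
    n_trained: int = 10
    trained_level: int = 1

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise CalibrationError(f"unknown scenario {self.name!r}")
        if self.n_trained < 0:
            raise CalibrationError("n_trained must be nonnegative")
        if self.trained_level not in (1, 2, 3, 4):
            raise CalibrationError("trained_level must be a brushing level 1-4")


def select_trained(
    state: SimulationState, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Student ids receiving training under a scenario.

    ``no_training`` selects nobody; ``random_training`` samples uniformly
    without replacement; ``popular_training`` takes the ``n_trained``
    highest in-degree students, breaking ties at the cutoff by a seeded
    uniform draw.
    """
    n = state.network.n_students
    if spec.n_trained > n:
        raise CalibrationError("cannot train more students than the cohort has")
    if spec.name == "no_training" or spec.n_trained == 0:
        return np.empty(0, dtype=np.int64)
    if spec.name == "random_training":
        return rng.choice(n, size=spec.n_trained, replace=False)
    indeg = state.network.in_degree()
    jitter = rng.random(n)  # tie-break at the popularity cutoff
    order = np.lexsort((jitter, -indeg))
    return np.sort(order[: spec.n_trained])


@dataclass
class ScenarioResult:
    """Ensemble-mean weekly count of students at the best brushing level."""

    spec: ScenarioSpec
    weeks: np.ndarray
    mean_count_level1: np.ndarray
    sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": self.weeks,
                "scenario": self.spec.name,
                "mean_count_level1": self.mean_count_level1,
                "sem": self.sem,
            }
        )


def run_scenario(
    initial: SimulationState,
    spec: ScenarioSpec,
    params: SimulationParams,
) -> ScenarioResult:
    """Ensemble of the dynamic model under a training scenario.

    The selected students are set to ``trained_level`` at week 0, then the
    model runs for the horizon; the hooked statistic is the count of
    students at level 1.  The random-training set is redrawn per
    replicate; the popularity-selected set is fixed across replicates
    (it depends only on the initial network).
    """
    n_rep = params.ensemble_size
    horizon = params.horizon_weeks
    rngs = replicate_rngs(params.seed, n_rep + 1)
    selector_rng, rngs = rngs[0], rngs[1:]
    popular_set = (
        select_trained(initial, spec, selector_rng)
        if spec.name == "popular_training"
        else None
    )
    hook = count_at_level(1)
    counts = np.empty((n_rep, horizon + 1))
    for r, rng in enumerate(rngs):
        if spec.name == "random_training":
            trained = select_trained(initial, spec, rng)
        elif spec.name == "popular_training":
            trained = popular_set
        else:
            trained = np.empty(0, dtype=np.int64)
        state = initial.copy()
        state.behavior.scores[trained] = spec.trained_level
        for s in iterate(state, params, rng):
            counts[r, s.week] = hook(s)
    mean = counts.mean(axis=0)
    sem = (
        counts.std(axis=0, ddof=1) / np.sqrt(n_rep)
        if n_rep > 1
        else np.zeros(horizon + 1)
    )
    return ScenarioResult(
        spec=spec, weeks=np.arange(horizon + 1), mean_count_level1=mean, sem=sem
    )


def plateau_gain(
    scenario: ScenarioResult, baseline: ScenarioResult, window: int = 10
) -> float:
    """Mean indicator gain over the last ``window`` weeks vs a baseline."""
    return float(
        np.mean(
            scenario.mean_count_level1[-window:]
            - baseline.mean_count_level1[-window:]
        )
    )
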