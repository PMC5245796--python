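"""Brushing-behaviour summaries and network autocorrelation statistics.

Each student carries an ordinal brushing score V0 in {1, 2, 3, 4} (lower is
better).  For a friendship level *i*, V_i(j) is the mean score of the
students at directed distance exactly *i* from student *j*; CC_i is the
association between V0 and V_i across students.  The *correlation length*
is the deepest level up to which that association stays significant — the
paper-of-record quantity that grows as behaviour diffuses through the
network.

The printed definition of CC_i is the plain inner product of V0 and V_i,
but a raw inner product of 1–4 scores is scale-dominated, so the default
``mode="normalized"`` uses the Pearson product-moment correlation of the
defined pairs; ``mode="raw"`` keeps the literal sum for strict replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import FriendshipMatrix, level_masks

BRUSHING_LEVELS = (1, 2, 3, 4)


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


class UndefinedResult(StatsError):
    """A statistic has no defined value on the given data."""


class FitFailure(StatsError):
    """An ordinal-association fit could not be estimated."""


@dataclass
class BehaviorVector:
    """Per-student ordinal brushing score (1 best .. 4 never) at one round."""

    scores: np.ndarray
    round_label: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise StatsError("scores must be a non-empty 1-d vector")
        if not np.isin(self.scores, BRUSHING_LEVELS).all():
            raise StatsError("brushing scores must lie in {1, 2, 3, 4}")

    def __len__(self) -> int:
        return self.scores.size

    def copy(self) -> "BehaviorVector":
        return BehaviorVector(self.scores.copy(), self.round_label)


@dataclass
class FrequencyTable:
    """Counts/percentages per brushing level plus the mean score."""

    table: pd.DataFrame  # index: level 1..4; columns: count, percent
    mean: float


def frequency_table(v: BehaviorVector) -> FrequencyTable:
    """Frequency analysis of the four brushing levels.

    Counts always sum to N and the mean lies in [1, 4]; the mean falls as
    the cohort brushes more (1 is the best level).
    """
    n = len(v)
    counts = pd.Series(v.scores).value_counts().reindex(BRUSHING_LEVELS, fill_value=0)
    table = pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / n}
    ).rename_axis("level")
    return FrequencyTable(table=table, mean=float(v.scores.mean()))


def friend_average_vector(
    network: FriendshipMatrix,
    v0: BehaviorVector,
    level: int,
    *,
    masks: "list[np.ndarray] | None" = None,
) -> np.ndarray:
    """Mean score of each student's level-``level`` friends (V_i).

    Entries are NaN for students with no friend at that exact distance
    (isolates at every level); downstream statistics exclude them pairwise.
    ``masks`` may carry precomputed level masks to amortise the distance
    pass across levels.
    """
    if level < 1:
        raise StatsError("friendship level must be a positive integer")
    if len(v0) != network.n_students:
        raise StatsError("behavior vector does not align with the network")
    mask = level_masks(network, level)[-1] if masks is None else masks[level - 1]
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vi = (mask @ v0.scores.astype(float)) / counts
    vi[counts == 0] = np.nan
    return vi


def cross_correlation(
    v0: BehaviorVector | np.ndarray,
    vi: np.ndarray,
    mode: str = "normalized",
) -> float:
    """Association CC_i between own scores and level-i friend averages.

    ``raw``: literal sum over students of V0(j) * V_i(j), NaN entries
    skipped.  ``normalized``: Pearson correlation of the defined pairs
    (needs >= 3 pairs and variance in both vectors).
    """
    x = np.asarray(v0.scores if isinstance(v0, BehaviorVector) else v0, dtype=float)
    y = np.asarray(vi, dtype=float)
    if x.shape != y.shape:
        raise StatsError("vectors must align on the same students")
    ok = ~(np.isnan(x) | np.isnan(y))
    if mode == "raw":
        return float(np.sum(x[ok] * y[ok]))
    if mode != "normalized":
        raise StatsError(f"unknown mode {mode!r}")
    if ok.sum() < 3:
        raise UndefinedResult("fewer than 3 defined pairs")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedResult("zero variance in a vector")
    return float(np.corrcoef(xs, ys)[0, 1])


@dataclass
class CorrelationCurve:
    """CC_i for friendship levels 1..L (NaN where undefined)."""

    levels: np.ndarray
    values: np.ndarray
    n_defined: np.ndarray
    mode: str = "normalized"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"level": self.levels, "cc": self.values, "n_defined": self.n_defined}
        )


def correlation_curve(
    network: FriendshipMatrix,
    v0: BehaviorVector,
    max_level: int = 4,
    mode: str = "normalized",
) -> CorrelationCurve:
    """CC_i over levels 1..max_level, with per-level defined-pair counts.

    Undefined levels (too few defined pairs, or no variance) are reported
    as NaN rather than dropped, so curves stay aligned across cohorts.
    """
    if max_level < 1:
        raise StatsError("max_level must be a positive integer")
    masks = level_masks(network, max_level)
    values = np.full(max_level, np.nan)
    n_def = np.zeros(max_level, dtype=np.int64)
    for idx in range(max_level):
        vi = friend_average_vector(network, v0, idx + 1, masks=masks)
        n_def[idx] = int((~np.isnan(vi)).sum())
        try:
            values[idx] = cross_correlation(v0, vi, mode=mode)
        except UndefinedResult:
            pass
    return CorrelationCurve(
        levels=np.arange(1, max_level + 1), values=values, n_defined=n_def, mode=mode
    )


def _permuted_curves(
    masks: list[np.ndarray], scores: np.ndarray, perm_matrix: np.ndarray
) -> np.ndarray:
    """Pearson CC per level (rows) for each permuted score column."""
    n_perm = perm_matrix.shape[1]
    out = np.full((len(masks), n_perm), np.nan)
    for idx, mask in enumerate(masks):
        counts = mask.sum(axis=1)
        defined = counts > 0
        if defined.sum() < 3:
            continue
        vi = (mask[defined].astype(float) @ perm_matrix) / counts[defined, None]
        v0 = perm_matrix[defined]
        v0c = v0 - v0.mean(axis=0)
        vic = vi - vi.mean(axis=0)
        denom = np.sqrt((v0c**2).sum(axis=0) * (vic**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[idx] = (v0c * vic).sum(axis=0) / denom
    return out


def correlation_length(
    network: FriendshipMatrix,
    v0: BehaviorVector,
    alpha: float = 0.05,
    n_perm: int = 999,
    max_level: int = 4,
    rng: "np.random.Generator | int | None" = None,
) -> int:
    """Deepest friendship level with unbroken significant association.

    Returns the largest ``i`` such that the normalized CC_m is significant
    at ``alpha`` for every ``m <= i``, judged by a two-sided permutation
    test that shuffles the score vector across students (``n_perm``
    permutations); 0 if even the direct-friend association is not
    significant.  No multiple-testing correction is applied across levels.
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    masks = level_masks(network, max_level)
    scores = v0.scores.astype(float)
    observed = _permuted_curves(masks, scores, scores[:, None])[:, 0]
    perms = np.column_stack([rng.permutation(scores) for _ in range(n_perm)])
    null = _permuted_curves(masks, scores, perms)
    length = 0
    for idx in range(max_level):
        if np.isnan(observed[idx]):
            break
        exceed = np.abs(null[idx]) >= np.abs(observed[idx]) - 1e-12
        p = (1 + np.nansum(exceed)) / (n_perm + 1)
        if p > alpha:
            break
        length = idx + 1
    return length


@dataclass
class OrdinalAssociation:
    """Cumulative-logit (proportional-odds) fit summary."""

    coef: pd.DataFrame  # index: predictor; columns: estimate, std_err, pvalue
    thresholds: np.ndarray  # the 3 cut-points between the 4 levels
    n_obs: int
    converged: bool


def ordinal_association(
    outcome: BehaviorVector,
    predictors: pd.DataFrame | dict | np.ndarray,
    min_cases: int = 30,
) -> OrdinalAssociation:
    """Proportional-odds model of the 4-level brushing score on covariates.

    A negative slope means higher predictor values go with better (lower)
    brushing scores — e.g. the popularity effect, where well-named students
    brush more.  Rows with missing values are dropped; at least
    ``min_cases`` complete cases and nonzero predictor variance are
    required.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if isinstance(predictors, dict):
        exog = pd.DataFrame(predictors)
    elif isinstance(predictors, pd.DataFrame):
        exog = predictors.copy()
    else:
        exog = pd.DataFrame({"x": np.asarray(predictors)})
    if len(exog) != len(outcome):
        raise StatsError("predictors must align with the outcome vector")
    endog = pd.Series(outcome.scores, index=exog.index, name="brushing")
    keep = exog.notna().all(axis=1)
    exog, endog = exog.loc[keep], endog.loc[keep]
    if len(endog) < min_cases:
        raise FitFailure(f"only {len(endog)} complete cases (need {min_cases})")
    variances = exog.var(axis=0)
    if (variances == 0).any():
        dead = list(variances.index[variances == 0])
        raise FitFailure(f"zero-variance predictor(s): {dead}")
    if endog.nunique() < 2:
        raise FitFailure("outcome has a single observed level")

    model = OrderedModel(
        endog.astype("category").cat.as_ordered(), exog, distr="logit"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="bfgs", disp=False, maxiter=200)
        except Exception as exc:  # separation / singular Hessian
            raise FitFailure(f"ordinal fit failed: {exc}") from exc
    k = exog.shape[1]
    if not np.all(np.isfinite(res.bse[:k])) or np.any(res.bse[:k] > 50):
        raise FitFailure(
            "separation suspected: slope standard error diverged "
            f"(bse={np.asarray(res.bse[:k]).round(2)})"
        )
    coef = pd.DataFrame(
        {
            "estimate": res.params[:k],
            "std_err": res.bse[:k],
            "pvalue": res.pvalues[:k],
        },
        index=exog.columns,
    )
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    return OrdinalAssociation(
        coef=coef,
        thresholds=np.asarray(thresholds),
        n_obs=int(len(endog)),
        converged=bool(res.mle_retvals.get("converged", True)),
    )
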