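"""Directed friendship networks of a school cohort.

The basic object is a binary directed adjacency matrix over N students:
entry ``x[i, j] == 1`` iff student *i* listed student *j* among her (up to
five) close friends.  "Friends" therefore always means *out*-neighbours —
the students a girl named herself — and every distance notion below follows
out-edges.  Level-*n* friends are the students at directed shortest-path
distance exactly *n*: level 1 are the named friends, level 2 the friends of
friends not already named, and so on.

The module also provides the degree and mutuality summaries used to
characterise such cohorts, and the turnover metric ``D`` — the count of
adjacency entries that differ between two assessments of the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

#: Questionnaire cap: a student may list at most five close friends.
MAX_NAMED_FRIENDS = 5


class NetworkError(ValueError):
    """Raised for structurally invalid friendship networks or arguments."""


@dataclass
class FriendshipMatrix:
    """Binary directed adjacency over a cohort of students.

    Parameters
    ----------
    adj
        ``(N, N)`` array of 0/1 indicators; ``adj[i, j] == 1`` iff student
        ``i`` named student ``j``.  The diagonal must be zero and every row
        sum (out-degree) at most :data:`MAX_NAMED_FRIENDS`.
    classroom
        Optional per-student classroom label (``1..K``).  Defaults to a
        single classroom.
    """

    adj: np.ndarray
    classroom: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj)
        if self.adj.ndim != 2 or self.adj.shape[0] != self.adj.shape[1]:
            raise NetworkError("adjacency must be a square matrix")
        if not np.isin(self.adj, (0, 1)).all():
            raise NetworkError("adjacency entries must be exactly 0 or 1")
        self.adj = self.adj.astype(np.uint8)
        if np.diagonal(self.adj).any():
            raise NetworkError("self-friendship (nonzero diagonal) is not allowed")
        if (self.adj.sum(axis=1) > MAX_NAMED_FRIENDS).any():
            raise NetworkError(
                f"out-degree exceeds the questionnaire cap of {MAX_NAMED_FRIENDS}"
            )
        if self.classroom is None:
            self.classroom = np.ones(self.n_students, dtype=np.int64)
        else:
            self.classroom = np.asarray(self.classroom, dtype=np.int64)
            if self.classroom.shape != (self.n_students,):
                raise NetworkError("classroom labels must align with students")

    @property
    def n_students(self) -> int:
        return self.adj.shape[0]

    def out_degree(self) -> np.ndarray:
        """Row sums: how many friends each student named."""
        return self.adj.sum(axis=1).astype(np.int64)

    def in_degree(self) -> np.ndarray:
        """Column sums: how many students named her (sociometric popularity)."""
        return self.adj.sum(axis=0).astype(np.int64)

    def n_edges(self) -> int:
        return int(self.adj.sum())

    def copy(self) -> "FriendshipMatrix":
        return FriendshipMatrix(self.adj.copy(), self.classroom.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FriendshipMatrix):
            return NotImplemented
        return self.adj.shape == other.adj.shape and np.array_equal(
            self.adj, other.adj
        )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: "list[tuple[int, int]] | np.ndarray",
        n_students: int,
        classroom: np.ndarray | None = None,
    ) -> "FriendshipMatrix":
        """Build from an iterable of ``(namer, named)`` index pairs."""
        adj = np.zeros((n_students, n_students), dtype=np.uint8)
        for i, j in edges:
            adj[i, j] = 1
        return cls(adj, classroom)

    def to_networkx(self):
        """Directed graph view (for GraphML export / visualisation)."""
        import networkx as nx

        g = nx.from_numpy_array(self.adj, create_using=nx.DiGraph)
        nx.set_node_attributes(
            g, {i: int(c) for i, c in enumerate(self.classroom)}, "classroom"
        )
        return g


@dataclass
class LevelNMatrix:
    """Indicator of ordered pairs at directed distance exactly ``level``."""

    level: int
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)


def distance_matrix(network: FriendshipMatrix) -> np.ndarray:
    """All-pairs directed shortest-path length; ``inf`` where unreachable."""
    sparse = csr_array(network.adj)
    return shortest_path(sparse, method="D", unweighted=True, directed=True)


def level_n_matrix(
    network: FriendshipMatrix, n: int, *, raw: bool = False
) -> LevelNMatrix:
    """Level-*n* friendship matrix.

    By default entry ``(i, j)`` is 1 iff the shortest directed path from
    ``i`` to ``j`` has length exactly ``n``, so the levels partition the
    reachable ordered pairs by distance.  With ``raw=True`` the literal
    binarized *n*-th boolean power of the adjacency matrix is returned
    instead (walks of length ``n``, closer pairs included), with the
    diagonal zeroed.
    """
    if n < 1:
        raise NetworkError("friendship level n must be a positive integer")
    if raw:
        power = network.adj.astype(bool)
        step = network.adj.astype(bool)
        for _ in range(n - 1):
            power = power @ step
        entries = power.astype(np.uint8)
        np.fill_diagonal(entries, 0)
        return LevelNMatrix(n, entries)
    dist = distance_matrix(network)
    entries = (dist == n).astype(np.uint8)
    np.fill_diagonal(entries, 0)
    return LevelNMatrix(n, entries)


def level_masks(network: FriendshipMatrix, max_level: int) -> list[np.ndarray]:
    """Boolean masks for levels ``1..max_level`` from one distance pass."""
    if max_level < 1:
        raise NetworkError("max_level must be a positive integer")
    dist = distance_matrix(network)
    return [dist == lvl for lvl in range(1, max_level + 1)]


def matrix_difference(x: FriendshipMatrix, y: FriendshipMatrix) -> int:
    """Network turnover ``D``: count of ordered pairs whose entry differs.

    ``D = sum_ij |y_ij - x_ij|`` — symmetric, zero iff the matrices are
    identical, at most ``N * (N - 1)``.
    """
    if x.adj.shape != y.adj.shape:
        raise NetworkError("matrices must cover the same student set")
    return int(np.abs(y.adj.astype(np.int64) - x.adj.astype(np.int64)).sum())


@dataclass
class DegreeStats:
    out_degree: np.ndarray
    in_degree: np.ndarray
    out_degree_counts: pd.Series
    in_degree_counts: pd.Series
    mean_out_degree: float
    n_edges: int


def degree_stats(network: FriendshipMatrix) -> DegreeStats:
    """Per-student out/in-degrees and their distributions.

    Out-degree is the number of friends a student named; in-degree the
    number of students who named *her* — the cohort's popularity measure.
    """
    out = network.out_degree()
    inn = network.in_degree()
    out_counts = pd.Series(out).value_counts().sort_index()
    in_counts = pd.Series(inn).value_counts().sort_index()
    return DegreeStats(
        out_degree=out,
        in_degree=inn,
        out_degree_counts=out_counts,
        in_degree_counts=in_counts,
        mean_out_degree=float(out.mean()),
        n_edges=int(out.sum()),
    )


@dataclass
class MutualityStats:
    percent: np.ndarray  # per-student % of named friends who named her back
    mean_percent: float


def mutuality(network: FriendshipMatrix) -> MutualityStats:
    """Per-student mutual-friendship percentage and its cohort mean.

    For a student with out-degree > 0 the percentage is 100 times the
    fraction of her named friends who also named her back; students who
    named nobody score 0% and stay in the mean (isolates are never dropped).
    """
    adj = network.adj
    mutual = (adj & adj.T).sum(axis=1)
    out = network.out_degree()
    pct = np.zeros(network.n_students, dtype=float)
    pos = out > 0
    pct[pos] = 100.0 * mutual[pos] / out[pos]
    return MutualityStats(percent=pct, mean_percent=float(pct.mean()))


def reachable_pair_count(network: FriendshipMatrix) -> int:
    """Number of ordered pairs ``i != j`` with a directed path i→j."""
    dist = distance_matrix(network)
    np.fill_diagonal(dist, np.inf)
    return int(np.isfinite(dist).sum())
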