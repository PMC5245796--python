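"""Plain-text I/O for cohorts.

Two CSV files describe a cohort: an edge list (``source,target`` — one
directed "named as friend" edge per row, integer student ids) and a node
attribute table (``id,classroom,brushing_r1,brushing_r2,econ,edu``; the
round-2 and SES columns may be empty).  Ids are arbitrary integers; they
are mapped to matrix positions by sorted order and written back unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorVector
from .network import FriendshipMatrix, NetworkError
from .simulate import SimulationState

ATTRIBUTE_COLUMNS = ["id", "classroom", "brushing_r1", "brushing_r2", "econ", "edu"]


def load_cohort(
    network_csv: "str | Path", attributes_csv: "str | Path"
) -> "tuple[FriendshipMatrix, pd.DataFrame]":
    """Read the edge-list and attribute CSVs into a validated cohort.

    The attribute table defines the student set; every edge endpoint must
    appear in it.  Returns the network and the attribute table indexed by
    matrix position (original ids kept in the ``id`` column).
    """
    attrs = pd.read_csv(attributes_csv)
    if attrs.empty:
        raise NetworkError(f"{attributes_csv}: attribute table is empty")
    missing = {"id", "classroom", "brushing_r1"} - set(attrs.columns)
    if missing:
        raise NetworkError(f"{attributes_csv}: missing columns {sorted(missing)}")
    if attrs["id"].duplicated().any():
        raise NetworkError(f"{attributes_csv}: duplicate student ids")
    attrs = attrs.sort_values("id").reset_index(drop=True)
    position = {sid: k for k, sid in enumerate(attrs["id"])}

    edges = pd.read_csv(network_csv)
    if not {"source", "target"} <= set(edges.columns):
        raise NetworkError(f"{network_csv}: expected columns source,target")
    n = len(attrs)
    adj = np.zeros((n, n), dtype=np.uint8)
    for row, (src, dst) in enumerate(zip(edges["source"], edges["target"]), start=2):
        if src not in position or dst not in position:
            raise NetworkError(
                f"{network_csv}:{row}: edge ({src},{dst}) references unknown id"
            )
        adj[position[src], position[dst]] = 1
    network = FriendshipMatrix(adj, attrs["classroom"].to_numpy())
    return network, attrs


def load_state(
    network_csv: "str | Path",
    attributes_csv: "str | Path",
    round_column: str = "brushing_r1",
) -> SimulationState:
    """Cohort CSVs as a week-0 simulation state."""
    network, attrs = load_cohort(network_csv, attributes_csv)
    if round_column not in attrs.columns or attrs[round_column].isna().any():
        raise NetworkError(f"attribute column {round_column!r} missing or incomplete")
    scores = attrs[round_column].astype(int).to_numpy()
    return SimulationState(network, BehaviorVector(scores, round_column), week=0)


def save_cohort(
    network: FriendshipMatrix,
    network_csv: "str | Path",
    attributes_csv: "str | Path | None" = None,
    behavior_r1: "BehaviorVector | None" = None,
    behavior_r2: "BehaviorVector | None" = None,
    ses: "pd.DataFrame | None" = None,
    ids: "np.ndarray | None" = None,
) -> None:
    """Write a cohort back to the edge-list / attribute CSV pair."""
    n = network.n_students
    ids = np.arange(n) if ids is None else np.asarray(ids)
    src, dst = np.nonzero(network.adj)
    pd.DataFrame({"source": ids[src], "target": ids[dst]}).to_csv(
        network_csv, index=False
    )
    if attributes_csv is None:
        return
    attrs = pd.DataFrame({"id": ids, "classroom": network.classroom})
    attrs["brushing_r1"] = behavior_r1.scores if behavior_r1 is not None else pd.NA
    attrs["brushing_r2"] = behavior_r2.scores if behavior_r2 is not None else pd.NA
    if ses is not None:
        attrs["econ"] = ses["econ"].to_numpy()
        attrs["edu"] = ses["edu"].to_numpy()
    else:
        attrs["econ"] = pd.NA
        attrs["edu"] = pd.NA
    attrs.to_csv(attributes_csv, index=False)


def export_graphml(network: FriendshipMatrix, path: "str | Path") -> None:
    """GraphML export for external visualisation tools."""
    import networkx as nx

    nx.write_graphml(network.to_networkx(), path)
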