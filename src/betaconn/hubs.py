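"""Hub identification and node-role classification.

For each nodal measure, values are averaged across participants and the
nodes ranked (1 = largest).  Nodes in the top 5% (rank <= floor(0.05 n);
13 of 263) are hubs.  A node hub by flow coefficient acts as a local
bridge, hub by betweenness centrality as a global bridge and hub by
participation coefficient as a connector.  A paired sign-flip
permutation test compares every other node against the target node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import _signflip_null

__all__ = [
    "HubRoleReport",
    "rank_nodes",
    "identify_hubs",
    "hub_cutoff",
    "classify_roles",
    "target_vs_nodes_permutation",
    "ROLE_BY_METRIC",
]

ROLE_BY_METRIC = {
    "flow": "local_bridge",
    "betweenness": "global_bridge",
    "participation": "connector",
}


@dataclass
class HubRoleReport:
    """Per condition x metric rank tables plus the target node's roles."""

    rank_tables: dict[tuple[str, str], pd.DataFrame]  # (condition, metric)
    target_node: int
    target_ranks: pd.DataFrame  # index: condition, columns: metrics
    roles: dict[str, set[str]]  # condition -> role set
    hub_fraction: float = 0.05
    nodewise_p: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def role_matrix(self) -> pd.DataFrame:
        """Condition x role boolean matrix (Fig.-2E-style summary)."""
        roles = ["local_bridge", "global_bridge", "connector"]
        return pd.DataFrame(
            [[r in self.roles[c] for r in roles] for c in self.roles],
            index=list(self.roles),
            columns=roles,
        )


def rank_nodes(tables: list[pd.DataFrame], metric: str) -> pd.DataFrame:
    """Group-mean of one nodal metric and the descending rank per node.

    ``tables`` holds one nodal-metrics frame per participant (shared node
    index).  Ranks are 1 = largest mean; exact ties are ordered by node
    id (deterministic) and flagged.
    """
    if not tables:
        raise ValueError("no participant tables supplied")
    index = tables[0].index
    cols = []
    for t in tables:
        if metric not in t.columns:
            raise ValueError(f"metric {metric!r} missing from a participant table")
        if not t.index.equals(index):
            raise ValueError("participants do not share a node set")
        cols.append(t[metric].to_numpy(dtype=float))
    mean = np.mean(cols, axis=0)
    # stable sort on (-mean, node position): ties keep node-id order
    order = np.lexsort((np.arange(mean.size), -mean))
    rank = np.empty(mean.size, dtype=int)
    rank[order] = np.arange(1, mean.size + 1)
    sorted_means = np.sort(mean)
    tied = np.isin(mean, sorted_means[:-1][np.diff(sorted_means) == 0])
    return pd.DataFrame(
        {"mean": mean, "rank": rank, "tied": tied}, index=index
    )


def hub_cutoff(n_nodes: int, fraction: float = 0.05) -> int:
    """Hub rank cutoff: floor(fraction * n); 13 for 263 nodes at 5%."""
    return math.floor(fraction * n_nodes)


def identify_hubs(ranks: pd.DataFrame, fraction: float = 0.05) -> pd.Series:
    """Boolean hub flag per node: rank <= floor(fraction * n).

    Ties straddling the cutoff are reported (warning column upstream is
    the ``tied`` flag), never silently resolved differently.
    """
    n = len(ranks)
    if n < 20:
        raise ValueError("hub identification needs at least 20 nodes")
    cutoff = hub_cutoff(n, fraction)
    return ranks["rank"] <= cutoff


def classify_roles(
    metric_tables: dict[str, list[pd.DataFrame]],
    target_node: int,
    fraction: float = 0.05,
    conditions: list[str] | None = None,
) -> HubRoleReport:
    """Build the hub/role report for the target node across conditions.

    ``metric_tables`` maps condition -> list of per-participant nodal
    metric frames.  Roles: local_bridge iff hub by flow, global_bridge
    iff hub by betweenness, connector iff hub by participation.
    """
    conditions = conditions or list(metric_tables)
    rank_tables: dict[tuple[str, str], pd.DataFrame] = {}
    roles: dict[str, set[str]] = {}
    target_rows = {}
    for cond in conditions:
        tables = metric_tables[cond]
        role_set: set[str] = set()
        ranks_row = {}
        for metric, role in ROLE_BY_METRIC.items():
            ranks = rank_nodes(tables, metric)
            hubs = identify_hubs(ranks, fraction)
            rank_tables[(cond, metric)] = ranks.assign(hub=hubs)
            r = int(ranks["rank"].iloc[target_node])
            ranks_row[metric] = r
            if bool(hubs.iloc[target_node]):
                role_set.add(role)
        roles[cond] = role_set
        target_rows[cond] = ranks_row
    target_ranks = pd.DataFrame(target_rows).T
    return HubRoleReport(
        rank_tables=rank_tables,
        target_node=target_node,
        target_ranks=target_ranks,
        roles=roles,
        hub_fraction=fraction,
    )


def target_vs_nodes_permutation(
    values: np.ndarray,
    target_node: int,
    n_perm: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """One-sided paired permutation p-values: is each node lower than the
    target?

    ``values`` is participants x nodes for one metric and condition.  For
    each other node the statistic is the mean within-participant
    difference (target - node); the null flips difference signs
    (exhaustive for <= 12 participants, Monte-Carlo otherwise).  Small p
    means the node's values are significantly lower than the target's.
    Uncorrected, as a descriptive nodewise map; the target's own entry is
    NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("values must be a participants x nodes matrix")
    n_sub, n_nodes = x.shape
    exhaustive = n_sub <= 12
    p = np.full(n_nodes, np.nan)
    for j in range(n_nodes):
        if j == target_node:
            continue
        diff = x[:, target_node] - x[:, j]
        obs = diff.mean()
        null, exh = _signflip_null(diff, n_perm if not exhaustive else 2**n_sub, seed + j)
        count = int((null >= obs - 1e-12).sum())
        p[j] = count / null.size if exh else (1 + count) / (1 + n_perm)
    return p
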