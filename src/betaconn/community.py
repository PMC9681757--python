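"""Community detection: Louvain modularity optimization, consensus
partitioning, partition similarity (NMI) and sub-network labeling.

The pipeline runs Louvain (gamma = 1) many times per network, builds the
node-pair agreement matrix of the resulting partitions, thresholds it at
tau and re-clusters it (weighted modularity) until every run returns the
same partition — the consensus partition.  Participant-level consensus
partitions are pooled the same way into one representative partition per
condition, which is then labeled against a reference atlas partition by
maximal Jaccard overlap.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .construction import BinaryNetwork

__all__ = [
    "Partition",
    "modularity_q",
    "louvain",
    "louvain_ensemble",
    "consensus_partition",
    "group_representative",
    "nmi",
    "label_subnetworks",
]


@dataclass
class Partition:
    """A node -> community assignment with its modularity value."""

    assignment: np.ndarray
    q: float = np.nan
    level: str = "participant"
    participant: str = ""
    condition: str = ""
    degenerate: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.assignment = _canonical(np.asarray(self.assignment, dtype=int))

    @property
    def n_nodes(self) -> int:
        return self.assignment.size

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0


def _canonical(assignment: np.ndarray) -> np.ndarray:
    """Relabel community ids contiguously from 0 in order of first node."""
    out = np.empty_like(assignment)
    mapping: dict[int, int] = {}
    for i, c in enumerate(assignment):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def _weights_of(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(network, BinaryNetwork):
        return network.a.astype(float)
    w = np.asarray(network, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("network must be square")
    return w


def modularity_q(
    network: BinaryNetwork | np.ndarray,
    assignment: np.ndarray,
    gamma: float = 1.0,
) -> float:
    """Newman modularity with resolution gamma.

    q = (1/2m) * sum_ij [w_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j)
    where k are (weighted) degrees and 2m the total weight.
    """
    w = _weights_of(network)
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != w.shape[0]:
        raise ValueError("assignment must cover all nodes")
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an edgeless network")
    labels = np.unique(assignment)
    onehot = (assignment[:, None] == labels[None, :]).astype(float)
    e_c = np.einsum("ic,ij,jc->c", onehot, w, onehot)  # 2x internal weight
    a_c = onehot.T @ k
    return float((e_c.sum() - gamma * (a_c**2).sum() / two_m) / two_m)


def _ig_weighted(w: np.ndarray) -> tuple[ig.Graph, list[float]]:
    iu, ju = np.nonzero(np.triu(w, k=1))
    weights = w[iu, ju].tolist()
    g = ig.Graph(n=w.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))
    return g, weights


def louvain(
    network: BinaryNetwork | np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
) -> Partition:
    """One Louvain run (greedy multi-level modularity optimization).

    The randomized node visitation order is driven by ``seed``; the
    returned ``q`` is recomputed from the assignment with
    :func:`modularity_q`.
    """
    w = _weights_of(network)
    if w.sum() == 0:
        raise ValueError("cannot run Louvain on an edgeless network")
    g, weights = _ig_weighted(w)
    random.seed(seed)
    clust = g.community_multilevel(
        weights=weights if weights else None, resolution=gamma
    )
    assignment = np.asarray(clust.membership, dtype=int)
    return Partition(
        assignment=assignment, q=modularity_q(w, assignment, gamma=gamma)
    )


def louvain_ensemble(
    network: BinaryNetwork | np.ndarray,
    gamma: float = 1.0,
    n_runs: int = 1000,
    seed: int = 0,
) -> list[Partition]:
    """``n_runs`` Louvain runs with seeds ``seed + 0 .. seed + n_runs - 1``."""
    return [louvain(network, gamma=gamma, seed=seed + i) for i in range(n_runs)]


def agreement_matrix(partitions: list[Partition]) -> np.ndarray:
    """D_ij = fraction of partitions placing nodes i and j together."""
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    n = partitions[0].n_nodes
    d = np.zeros((n, n))
    for p in partitions:
        if p.n_nodes != n:
            raise ValueError("partitions must share the same node set")
        a = p.assignment
        d += (a[:, None] == a[None, :]).astype(float)
    d /= len(partitions)
    np.fill_diagonal(d, 0.0)
    return d


def _all_identical(partitions: list[Partition]) -> bool:
    first = partitions[0].assignment
    return all(np.array_equal(p.assignment, first) for p in partitions[1:])


def consensus_partition(
    partitions: list[Partition],
    tau: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
    gamma: float = 1.0,
    max_cycles: int = 50,
    base: BinaryNetwork | np.ndarray | None = None,
) -> Partition:
    """Consensus over an ensemble of partitions (agreement-matrix method).

    The agreement matrix is thresholded at ``tau``, re-clustered by
    ``n_iter`` weighted Louvain runs, and the cycle repeats on the new
    ensemble until all runs agree.  If ``base`` is given, the returned
    ``q`` is the modularity of the consensus assignment on that network;
    otherwise it is the weighted modularity on the final agreement graph.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions for consensus")
    current = partitions

    def _finalize(assignment: np.ndarray, fallback_w: np.ndarray | None,
                  degenerate: bool = False) -> Partition:
        if base is not None:
            q = modularity_q(base, assignment, gamma=gamma)
        elif fallback_w is not None and fallback_w.sum() > 0:
            q = modularity_q(fallback_w, assignment, gamma=gamma)
        else:
            q = np.nan
        return Partition(assignment=assignment, q=q, degenerate=degenerate)

    for _ in range(max_cycles):
        if _all_identical(current):
            return _finalize(current[0].assignment.copy(), None)
        d = agreement_matrix(current)
        d[d < tau] = 0.0
        if d.sum() == 0:
            warnings.warn(
                "agreement matrix is empty after thresholding; "
                "returning the all-singleton partition"
            )
            n = current[0].n_nodes
            return _finalize(np.arange(n), None, degenerate=True)
        current = [
            louvain(d, gamma=gamma, seed=seed + i) for i in range(n_iter)
        ]
        if _all_identical(current):
            return _finalize(current[0].assignment.copy(), d)
        seed += n_iter
    raise RuntimeError(
        f"consensus partitioning did not converge within {max_cycles} cycles "
        f"(tau={tau}, n_iter={n_iter})"
    )


def group_representative(
    participant_partitions: list[Partition],
    tau: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
    gamma: float = 1.0,
    max_cycles: int = 50,
) -> Partition:
    """Consensus across participants' consensus partitions (one condition)."""
    rep = consensus_partition(
        participant_partitions,
        tau=tau,
        n_iter=n_iter,
        seed=seed,
        gamma=gamma,
        max_cycles=max_cycles,
    )
    rep.level = "group"
    if rep.degenerate:
        warnings.warn(
            "group representative partition is degenerate (no agreement "
            "between participants)"
        )
    return rep


def nmi(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Normalized mutual information, 2 I / (H1 + H2), in [0, 1].

    Conventions for zero entropy: two identical trivial partitions score
    1; a single-community partition against anything else scores 0.
    """
    a1 = p1.assignment if isinstance(p1, Partition) else np.asarray(p1, dtype=int)
    a2 = p2.assignment if isinstance(p2, Partition) else np.asarray(p2, dtype=int)
    if a1.shape != a2.shape:
        raise ValueError("partitions must cover the same node set")
    h1_zero = np.unique(a1).size == 1
    h2_zero = np.unique(a2).size == 1
    if h1_zero and h2_zero:
        return 1.0
    if h1_zero or h2_zero:
        return 0.0
    return float(
        normalized_mutual_info_score(a1, a2, average_method="arithmetic")
    )


def label_subnetworks(
    partition: Partition,
    reference: dict[int, str] | pd.Series,
    target_node: int | None = None,
) -> tuple[dict[int, str], pd.DataFrame]:
    """Label detected communities by maximal Jaccard overlap with a
    reference partition (e.g. canonical resting-state sub-networks).

    ``reference`` maps node index -> network label and must cover at
    least 80% of nodes.  Ties are broken by larger overlap count, then
    lexicographic label.  Communities with no overlap get "unassigned".
    Returns (community -> label, overlap table); the overlap table has
    one row per community x reference label with jaccard and counts, and
    flags the community containing ``target_node`` if given.
    """
    ref = pd.Series(reference)
    n = partition.n_nodes
    covered = ref.index[(ref.index >= 0) & (ref.index < n)]
    if len(covered) < 0.8 * n:
        raise ValueError("reference partition must cover at least 80% of nodes")
    labels = sorted(set(ref.values))
    ref_sets = {lab: set(ref.index[ref.values == lab]) for lab in labels}
    mapping: dict[int, str] = {}
    rows = []
    target_comm = (
        int(partition.assignment[target_node]) if target_node is not None else None
    )
    for c in range(partition.n_communities):
        members = set(np.flatnonzero(partition.assignment == c))
        best: tuple[float, int, str] | None = None
        for lab in labels:  # sorted: first max wins ties -> lexicographic
            inter = len(members & ref_sets[lab])
            union = len(members | ref_sets[lab])
            jac = inter / union if union else 0.0
            rows.append(
                {
                    "community": c,
                    "reference": lab,
                    "jaccard": jac,
                    "overlap": inter,
                    "community_size": len(members),
                    "contains_target": c == target_comm,
                }
            )
            if inter == 0:
                continue
            if best is None or (jac, inter) > (best[0], best[1]):
                best = (jac, inter, lab)
        mapping[c] = best[2] if best is not None else "unassigned"
    table = pd.DataFrame(rows)
    return mapping, table
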