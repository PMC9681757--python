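"""Network construction from trial-wise beta series.

Edges are Fisher-z-transformed Spearman rank correlations of the two
regions' beta series across trials.  Weighted matrices are binarized by
proportional thresholding (keep the top d% strongest edges), and the
density range for the analysis is chosen from largest-connected-component
behaviour across the whole cohort of networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

__all__ = [
    "BetaSeriesSet",
    "WeightedNetwork",
    "BinaryNetwork",
    "DensityRange",
    "beta_correlation",
    "proportional_threshold",
    "edge_count_at_density",
    "lcc_size",
    "select_density_range",
]

# |rho| = 1 is clipped below 1 so the Fisher z transform stays finite
_RHO_CLIP = 1.0 - 1e-12


@dataclass
class BetaSeriesSet:
    """Trial-wise beta estimates for one participant in one condition.

    ``values`` is a trials x nodes matrix; ``node_ids`` fixes the node
    order shared by every set in a cohort.
    """

    values: np.ndarray
    participant: str
    condition: str
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("beta series must be a 2-D trials x nodes matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 trials to correlate beta series")
        if not np.isfinite(self.values).all():
            raise ValueError("beta series contain non-finite values")
        if not self.node_ids:
            self.node_ids = [f"n{i:03d}" for i in range(self.values.shape[1])]
        if len(self.node_ids) != self.values.shape[1]:
            raise ValueError("node_ids length does not match number of columns")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightedNetwork:
    """Symmetric Fisher-z Spearman correlation matrix with zero diagonal."""

    w: np.ndarray
    participant: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.isfinite(self.w).all():
            raise ValueError("weight matrix must be finite")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a target edge density (%)."""

    a: np.ndarray
    density: float
    participant: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.dtype != np.int8:
            self.a = self.a.astype(np.int8)
        if (self.a != self.a.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diag(self.a).any():
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2


@dataclass
class DensityRange:
    d_low: float
    d_high: float
    step: float = 1.0
    fractions: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d_low > self.d_high:
            raise ValueError("d_low must not exceed d_high")

    @property
    def densities(self) -> list[float]:
        out = []
        d = self.d_low
        while d <= self.d_high + 1e-9:
            out.append(round(d, 10))
            d += self.step
        return out


def beta_correlation(b: BetaSeriesSet) -> WeightedNetwork:
    """Fisher-z Spearman correlation network of a beta-series set.

    Trials are rank-transformed per node (ties get average ranks) and the
    Pearson correlation of the ranks — i.e. the Spearman correlation — is
    Fisher-z transformed.  Correlations of magnitude 1 are clipped just
    below 1 so atanh stays finite.  The diagonal is set to zero.
    """
    x = b.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = ", ".join(b.node_ids[i] for i in bad)
        raise ValueError(f"constant beta series for node(s): {names}")
    ranks = np.apply_along_axis(rankdata, 0, x)
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -_RHO_CLIP, _RHO_CLIP)
    w = np.arctanh(rho)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    return WeightedNetwork(w=w, participant=b.participant, condition=b.condition)


def edge_count_at_density(n_nodes: int, density: float) -> int:
    """Number of edges kept at ``density`` % — round-half-up of d% of pairs."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(density / 100.0 * n_pairs + 0.5))


def proportional_threshold(
    wn: WeightedNetwork, density: float, ranking: str = "signed"
) -> BinaryNetwork:
    """Binarize by keeping the d% strongest edges.

    ``ranking='signed'`` ranks edges by signed weight (most positive
    first); ``'absolute'`` ranks by magnitude.  Ties are broken by
    lexicographic (i, j) order so the edge set is deterministic.
    """
    if not 0 < density < 100:
        raise ValueError("density must be in (0, 100)")
    n = wn.n_nodes
    m = edge_count_at_density(n, density)
    iu, ju = np.triu_indices(n, k=1)
    vals = wn.w[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    elif ranking != "signed":
        raise ValueError("ranking must be 'signed' or 'absolute'")
    # lexsort: last key is primary -> sort by (-w, i, j)
    order = np.lexsort((ju, iu, -vals))[:m]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[order], ju[order]] = 1
    a |= a.T
    return BinaryNetwork(
        a=a, density=density, participant=wn.participant, condition=wn.condition
    )


def lcc_size(bn: BinaryNetwork) -> int:
    """Size (node count) of the largest connected component."""
    n_comp, labels = connected_components(
        sp.csr_matrix(bn.a), directed=False, return_labels=True
    )
    return int(np.bincount(labels).max())


def select_density_range(
    networks: list[WeightedNetwork],
    candidate_densities: list[float],
    full_fraction: float = 0.90,
    step: float = 1.0,
    ranking: str = "signed",
) -> DensityRange:
    """Choose the analysis density range from LCC behaviour.

    ``d_low`` is the sparsest density at which at least ``full_fraction``
    of all participant x condition networks are fully connected
    (LCC size == n); ``d_high`` is the sparsest density at which every
    network is fully connected.  The per-density full-connectivity
    fractions are reported alongside.
    """
    if not networks:
        raise ValueError("no networks supplied")
    cand = sorted(candidate_densities)
    fractions: dict[float, float] = {}
    d_low = None
    d_high = None
    for d in cand:
        full = 0
        for wn in networks:
            bn = proportional_threshold(wn, d, ranking=ranking)
            if lcc_size(bn) == bn.n_nodes:
                full += 1
        frac = full / len(networks)
        fractions[d] = frac
        if d_low is None and frac >= full_fraction:
            d_low = d
        if d_high is None and frac == 1.0:
            d_high = d
        if d_low is not None and d_high is not None:
            break
    if d_low is None or d_high is None:
        raise ValueError(
            "no candidate density satisfies the connectivity criterion; "
            f"full-connectivity fractions: {fractions}"
        )
    return DensityRange(d_low=d_low, d_high=d_high, step=step, fractions=fractions)
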