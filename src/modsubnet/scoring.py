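"""Subnetwork scoring: edge weights, activity, class relevance, modularity, score.

The subnetwork score trades off two quantities:

* class relevance ``R`` — the absolute Spearman correlation between subnetwork
  activity (mean member expression per sample) and sample age, so ``R`` is high
  when aggregate activity rises or falls monotonically with age;
* topological modularity ``M`` — a weighted local community fitness,
  ``M = W_in / (W_in + W_out)**2``, where ``W_in`` is the member-internal edge
  weight counted once per endpoint (each internal edge contributes ``2 w``) and
  ``W_out`` the weight of boundary edges, so the denominator is exactly the
  total strength of the member nodes.

The combined score is ``S = R + beta * M``; ``beta = 0`` recovers purely
relevance-driven ("regular") subnetwork scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionDataset

__all__ = [
    "Subnetwork",
    "edge_weight",
    "weight_network",
    "subnetwork_activity",
    "class_relevance",
    "internal_external_weight",
    "modularity",
    "subnetwork_score",
    "BETA_PRESETS",
    "R_THRESHOLD_PRESETS",
]

#: modularity coefficients defining the modular presets m1..m5
BETA_PRESETS: tuple[float, ...] = (50.0, 100.0, 250.0, 500.0, 1000.0)
#: per-step relevance-gain thresholds defining the regular presets r1..r5
R_THRESHOLD_PRESETS: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2)


@dataclass
class Subnetwork:
    """A connected gene set grown from a seed, with its score decomposition.

    ``members`` preserves growth order (seed first). ``history`` records
    ``(R, M, S)`` after every growth step, seed included.
    """

    seed: str
    members: tuple[str, ...]
    activity: np.ndarray
    relevance: float
    modularity: float
    score: float
    beta: float
    mode: str = "modular"
    r_threshold: float | None = None
    internal_weight: float = 0.0
    external_weight: float = 0.0
    history: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member")
        if not np.isclose(self.score, self.relevance + self.beta * self.modularity):
            raise ValueError("score is not R + beta * M")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


def edge_weight(zi: np.ndarray, zj: np.ndarray) -> float:
    """Co-expression weight of an edge: |Spearman correlation| of its endpoints.

    Average ranks are used for ties, so the weight is invariant under monotone
    transforms of either expression vector and always lies in [0, 1].
    """
    zi = np.asarray(zi, dtype=float)
    zj = np.asarray(zj, dtype=float)
    if zi.shape != zj.shape or zi.ndim != 1:
        raise ValueError("expression vectors must be 1-D with equal length")
    if zi.size < 3:
        raise ValueError("need at least 3 samples for a rank correlation")
    if np.ptp(zi) == 0 or np.ptp(zj) == 0:
        raise ValueError("constant expression vector; filter before weighting")
    rho = stats.spearmanr(zi, zj).statistic
    return float(abs(rho))


def weight_network(g: nx.Graph, d: ExpressionDataset) -> nx.Graph:
    """Assign every edge the |Spearman| co-expression weight of its endpoints.

    Topology is unchanged; any pre-existing weights are replaced. Vectorized:
    gene rows are rank-transformed once, then each edge weight is the Pearson
    correlation of the two rank rows.
    """
    missing = [n for n in g.nodes if n not in d.values.index]
    if missing:
        raise ValueError(f"network genes without expression data: {missing[:5]}")
    nodes = list(g.nodes)
    arr = d.values.loc[nodes].to_numpy(dtype=float)
    if np.any(np.ptp(arr, axis=1) == 0):
        bad = [n for n, p in zip(nodes, np.ptp(arr, axis=1)) if p == 0]
        raise ValueError(f"constant expression for genes: {bad[:5]}")
    ranks = stats.rankdata(arr, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    ranks /= np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    idx = {n: i for i, n in enumerate(nodes)}
    g2 = nx.Graph()
    g2.add_nodes_from(nodes)
    edges = list(g.edges)
    if edges:
        ia = np.fromiter((idx[a] for a, _ in edges), dtype=int, count=len(edges))
        ib = np.fromiter((idx[b] for _, b in edges), dtype=int, count=len(edges))
        w = np.abs(np.einsum("ij,ij->i", ranks[ia], ranks[ib]))
        w = np.clip(w, 0.0, 1.0)
        g2.add_weighted_edges_from(
            (a, b, float(wi)) for (a, b), wi in zip(edges, w)
        )
    return g2


def subnetwork_activity(members, d: ExpressionDataset) -> np.ndarray:
    """Per-sample activity: unweighted mean of the member genes' expression rows."""
    members = list(members)
    if not members:
        raise ValueError("members must be non-empty")
    unknown = [m for m in members if m not in d.values.index]
    if unknown:
        raise ValueError(f"members absent from dataset: {unknown}")
    return d.values.loc[members].to_numpy(dtype=float).mean(axis=0)


def class_relevance(a: np.ndarray, c: np.ndarray) -> float:
    """Class relevance R = |Spearman(a, c)| between activity and age.

    Ages tie heavily by design (replicate samples per age); average ranks are
    used. A constant activity vector carries no age signal and yields R = 0
    with a warning rather than an error.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    if a.shape != c.shape or a.ndim != 1:
        raise ValueError("activity and ages must be 1-D with equal length")
    if np.unique(c).size < 2:
        raise ValueError("ages must take at least 2 distinct values")
    if np.ptp(a) == 0:
        warnings.warn("constant activity vector; class relevance set to 0")
        return 0.0
    rho = stats.spearmanr(a, c).statistic
    return float(abs(rho))


def internal_external_weight(members, g: nx.Graph) -> tuple[float, float]:
    """(W_in, W_out) for a member set: internal strength and boundary weight.

    Each internal edge contributes ``2 w`` to W_in (once per endpoint), so
    ``W_in + W_out`` equals the summed strength of the member nodes.
    """
    mem = set(members)
    unknown = mem - set(g.nodes)
    if unknown:
        raise ValueError(f"members absent from network: {sorted(unknown)[:5]}")
    w_in = 0.0
    w_out = 0.0
    for m in mem:
        for nbr, data in g[m].items():
            w = data.get("weight", 1.0)
            if nbr in mem:
                w_in += w  # visited from both endpoints -> counted twice total
            else:
                w_out += w
    return w_in, w_out


def modularity(members, g: nx.Graph) -> float:
    """Weighted local modularity M = W_in / (W_in + W_out)**2.

    Zero for singletons and for isolated member sets (zero total strength).
    Whenever the total member strength is at least 1, M is bounded by 1.
    """
    w_in, w_out = internal_external_weight(members, g)
    tot = w_in + w_out
    if tot <= 0.0:
        return 0.0
    return w_in / tot**2


def subnetwork_score(R: float, M: float, beta: float) -> float:
    """Combined score S = R + beta * M."""
    if not 0.0 <= R <= 1.0 + 1e-12:
        raise ValueError("R must lie in [0, 1]")
    if M < 0.0:
        raise ValueError("M must be non-negative")
    if beta < 0.0:
        raise ValueError("beta must be non-negative")
    return R + beta * M
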