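"""Permutation significance of subnetworks: self-contained and competitive tests.

Two complementary null models are used:

* self-contained — ages are shuffled over samples and the full seed-wise search
  repeated; each seed's true score is ranked against the scores the same seed
  attains under permuted ages. This destroys the age-expression link while
  keeping the co-expression weights intact.
* competitive — gene labels are shuffled over network positions ("artificial
  interactomes"), edge weights recomputed, and the search repeated; each true
  score is ranked against the pooled scores of all subnetworks from all
  artificial interactomes.

Empirical p-values are add-one estimates, p = (1 + #{null >= true}) / (1 + n),
so they are never zero and a true score beating all 1,000 age permutations
attains p = 1/1001 < 0.001. A subnetwork is significant when it passes both
tests at their respective thresholds (defaults 0.001 and 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .scoring import Subnetwork
from .search import GrowthEngine, remove_redundant

__all__ = [
    "SignificanceResult",
    "self_contained_test",
    "randomize_interactome",
    "competitive_test",
    "significance_table",
    "select_significant",
]


@dataclass
class SignificanceResult:
    """Per-seed outcome of both permutation tests."""

    seed: str
    true_score: float
    self_p: float
    competitive_p: float
    n_perm: int
    n_interactomes: int
    significant: bool


def _scores(subs: list[Subnetwork]) -> np.ndarray:
    return np.fromiter((s.score for s in subs), dtype=float, count=len(subs))


def self_contained_test(
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
    engine: GrowthEngine | None = None,
    true_subs: list[Subnetwork] | None = None,
) -> pd.Series:
    """Age-permutation p-value per seed (index: seed gene id).

    For each of ``n_perm`` shuffles of the age vector the full all-seed search
    is re-run; p for seed s is the add-one fraction of permutations whose
    score from s ties or beats the true score from s.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = engine if engine is not None else GrowthEngine(g, d)
    kw = dict(mode=mode, beta=beta, r_threshold=r_threshold)
    if true_subs is None:
        true_subs = eng.grow_all(**kw)
    true = _scores(true_subs)
    seed_idx = np.fromiter(
        (eng.index[s.seed] for s in true_subs), dtype=np.intp, count=len(true_subs)
    )
    rng = np.random.default_rng(rng_seed)
    ages0 = eng.ages.copy()
    exceed = np.zeros(len(true), dtype=np.int64)
    try:
        for _ in range(n_perm):
            eng.set_ages(rng.permutation(ages0))
            exceed += eng.grow_all_scores(**kw)[seed_idx] >= true
    finally:
        eng.set_ages(ages0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=[s.seed for s in true_subs], name="self_p")


def randomize_interactome(
    g, d: ExpressionDataset, rng_seed: int = 0, permutation: dict | None = None
) -> nx.Graph:
    """One artificial interactome: gene labels shuffled on a fixed topology.

    Node positions and edges are unchanged, so the degree sequence is exactly
    preserved; every edge weight is recomputed as the |Spearman| co-expression
    of its new flanking genes. ``permutation`` (old label -> new label) may be
    supplied explicitly, e.g. the identity for testing.
    """
    from .scoring import weight_network

    nodes = sorted(g.nodes)
    if permutation is None:
        rng = np.random.default_rng(rng_seed)
        shuffled = [nodes[i] for i in rng.permutation(len(nodes))]
        permutation = dict(zip(nodes, shuffled))
    g2 = nx.relabel_nodes(g, permutation, copy=True)
    return weight_network(g2, d)


def competitive_test(
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
    n_interactomes: int = 100,
    rng_seed: int = 0,
    engine: GrowthEngine | None = None,
    true_subs: list[Subnetwork] | None = None,
) -> pd.Series:
    """Artificial-interactome p-value per seed against one pooled score null."""
    if n_interactomes < 1:
        raise ValueError("n_interactomes must be >= 1")
    eng = engine if engine is not None else GrowthEngine(g, d)
    kw = dict(mode=mode, beta=beta, r_threshold=r_threshold)
    if true_subs is None:
        true_subs = eng.grow_all(**kw)
    true = _scores(true_subs)
    rng = np.random.default_rng(rng_seed)
    n = len(eng.nodes)
    pool: list[np.ndarray] = []
    try:
        for _ in range(n_interactomes):
            eng.permute_genes(rng.permutation(n))
            pool.append(eng.grow_all_scores(**kw))
    finally:
        eng.reset_genes()
    null = np.sort(np.concatenate(pool))
    # count of null >= true via searchsorted on the sorted pool
    n_ge = null.size - np.searchsorted(null, true, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return pd.Series(p, index=[s.seed for s in true_subs], name="competitive_p")


def significance_table(
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
    n_perm: int = 1000,
    n_interactomes: int = 100,
    rng_seed: int = 0,
    self_alpha: float = 0.001,
    comp_alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[Subnetwork]]:
    """Run both tests for every seed; returns (per-seed table, true subnetworks)."""
    if n_perm + 1 < 1.0 / self_alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach self_alpha={self_alpha}: minimum "
            f"attainable p is {1.0 / (n_perm + 1):.4g}"
        )
    eng = GrowthEngine(g, d)
    kw = dict(mode=mode, beta=beta, r_threshold=r_threshold)
    true_subs = eng.grow_all(**kw)
    self_p = self_contained_test(
        g, d, n_perm=n_perm, rng_seed=rng_seed, engine=eng, true_subs=true_subs, **kw
    )
    comp_p = competitive_test(
        g,
        d,
        n_interactomes=n_interactomes,
        rng_seed=rng_seed + 1,
        engine=eng,
        true_subs=true_subs,
        **kw,
    )
    table = pd.DataFrame(
        {
            "seed": [s.seed for s in true_subs],
            "size": [s.size for s in true_subs],
            "R": [s.relevance for s in true_subs],
            "M": [s.modularity for s in true_subs],
            "S": [s.score for s in true_subs],
            "self_p": self_p.to_numpy(),
            "competitive_p": comp_p.to_numpy(),
        }
    )
    table["significant"] = (table["self_p"] < self_alpha) & (
        table["competitive_p"] < comp_alpha
    )
    return table, true_subs


def select_significant(
    table: pd.DataFrame,
    subs: list[Subnetwork],
    self_alpha: float = 0.001,
    comp_alpha: float = 0.05,
    max_overlap: float = 0.25,
    min_size: int = 2,
) -> list[Subnetwork]:
    """Subnetworks passing both tests, reduced to a non-redundant set.

    Singletons are never reported (``min_size`` defaults to 2): a lone seed
    carries no subnetwork structure.
    """
    ok = set(
        table.loc[
            (table["self_p"] < self_alpha) & (table["competitive_p"] < comp_alpha),
            "seed",
        ]
    )
    passed = [s for s in subs if s.seed in ok and s.size >= min_size]
    return remove_redundant(passed, max_overlap=max_overlap)
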