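"""Greedy seed expansion of subnetworks and redundancy removal.

Growth starts from a seed gene and repeatedly adds the network neighbor of the
current member set that most increases the subnetwork score, subject to the
mode's constraints:

* ``modular`` — candidates must not decrease class relevance R or modularity M
  and must strictly increase S = R + beta * M; growth halts when no neighbor
  qualifies. When ``beta == 0`` the score reduces to S = R and the modularity
  constraint is dropped, recovering purely relevance-driven greedy growth.
* ``regular`` — candidates are restricted to nodes within graph distance 2 of
  the seed (computed once); the neighbor with the largest relevance gain is
  added provided the gain is at least ``r_threshold``; growth halts when no
  candidate qualifies or the pool is exhausted.

Ties in the greedy choice break toward the lexicographically smallest gene id,
making every search deterministic and serial/parallel runs bit-identical.
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .io import ExpressionDataset
from .scoring import Subnetwork

__all__ = [
    "GrowthEngine",
    "grow_subnetwork",
    "grow_all",
    "jaccard",
    "remove_redundant",
    "SCORE_EPS",
]

#: tolerance for score/relevance/modularity comparisons during growth.
#: Rank statistics take discrete values with gaps far above this, so deltas
#: smaller than SCORE_EPS are floating-point noise from re-deriving the same
#: quantity along two routes, not real changes.
SCORE_EPS = 1e-9


class GrowthEngine:
    """Precomputed arrays for fast repeated subnetwork growth on one network.

    Node order is the sorted gene-id order, so candidate indices coincide with
    lexicographic order and ``argmax`` tie-breaking is deterministic. The
    engine supports in-place age permutation (self-contained null) and gene
    relabeling with edge-weight recomputation (competitive null).
    """

    def __init__(self, g, d: ExpressionDataset):
        self.nodes: list[str] = sorted(g.nodes)
        if not self.nodes:
            raise ValueError("empty network")
        missing = [n for n in self.nodes if n not in d.values.index]
        if missing:
            raise ValueError(f"network genes without expression: {missing[:5]}")
        self.index = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self._Z0 = d.values.loc[self.nodes].to_numpy(dtype=float)
        self.n_samples = self._Z0.shape[1]

        # normalized rank rows, for O(1) edge-weight recomputation
        G = stats.rankdata(self._Z0, axis=1)
        G = G - G.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", G, G))
        nz = norms > 0
        G[nz] /= norms[nz, None]
        G[~nz] = 0.0
        self._G = G

        edges = sorted(
            (min(self.index[a], self.index[b]), max(self.index[a], self.index[b]), dat)
            for a, b, dat in g.edges(data=True)
        )
        m = len(edges)
        self._eu = np.fromiter((e[0] for e in edges), dtype=np.intp, count=m)
        self._ev = np.fromiter((e[1] for e in edges), dtype=np.intp, count=m)
        self._ew0 = np.fromiter(
            (float(e[2].get("weight", 1.0)) for e in edges), dtype=float, count=m
        )
        nbrs: list[list[int]] = [[] for _ in range(n)]
        eidx: list[list[int]] = [[] for _ in range(n)]
        for k in range(m):
            u, v = int(self._eu[k]), int(self._ev[k])
            nbrs[u].append(v)
            eidx[u].append(k)
            nbrs[v].append(u)
            eidx[v].append(k)
        self._nbrs = [np.asarray(a, dtype=np.intp) for a in nbrs]
        self._eidx = [np.asarray(a, dtype=np.intp) for a in eidx]

        self._perm = np.arange(n, dtype=np.intp)
        self._Z = self._Z0
        self._ew = self._ew0
        self._recompute_strength()
        self.set_ages(d.ages.to_numpy(dtype=float))

    # ----- state manipulation (nulls) -------------------------------------

    def set_ages(self, ages: np.ndarray) -> None:
        """Install an age vector (rank-transformed once for relevance)."""
        ages = np.asarray(ages, dtype=float)
        if ages.shape != (self.n_samples,):
            raise ValueError("ages length must match sample count")
        if np.unique(ages).size < 2:
            raise ValueError("ages must take at least 2 distinct values")
        c = stats.rankdata(ages)
        c = c - c.mean()
        self._c_unit = c / np.sqrt(c @ c)
        self.ages = ages

    def permute_genes(self, perm: np.ndarray) -> None:
        """Relabel genes on the fixed topology and recompute edge weights.

        ``perm[i]`` is the index of the gene now sitting on node position
        ``i``; weights become the |Spearman| of the new flanking genes.
        """
        perm = np.asarray(perm, dtype=np.intp)
        if sorted(perm.tolist()) != list(range(len(self.nodes))):
            raise ValueError("perm must be a permutation of node indices")
        self._perm = perm
        self._Z = self._Z0[perm]
        gu = self._G[perm[self._eu]]
        gv = self._G[perm[self._ev]]
        self._ew = np.clip(np.abs(np.einsum("ij,ij->i", gu, gv)), 0.0, 1.0)
        self._recompute_strength()

    def reset_genes(self) -> None:
        self.permute_genes(np.arange(len(self.nodes), dtype=np.intp))

    def _recompute_strength(self) -> None:
        n = len(self.nodes)
        s = np.zeros(n)
        np.add.at(s, self._eu, self._ew)
        np.add.at(s, self._ev, self._ew)
        self.strength = s

    # ----- scoring helpers -------------------------------------------------

    def _relevance_rows(self, acts: np.ndarray) -> np.ndarray:
        """|Spearman(activity, age)| per row; constant rows yield 0."""
        r = stats.rankdata(acts, axis=1)
        r = r - r.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", r, r))
        dots = r @ self._c_unit
        out = np.zeros(acts.shape[0])
        nz = norms > 0
        out[nz] = np.abs(dots[nz] / norms[nz])
        return np.minimum(out, 1.0)

    def _within_two(self, s: int) -> np.ndarray:
        mask = np.zeros(len(self.nodes), dtype=bool)
        mask[s] = True
        first = self._nbrs[s]
        mask[first] = True
        for v in first:
            mask[self._nbrs[v]] = True
        return mask

    # ----- growth ----------------------------------------------------------

    def grow(
        self,
        seed: int,
        mode: str = "modular",
        beta: float = 250.0,
        r_threshold: float = 0.05,
        score_only: bool = False,
    ):
        if mode not in ("modular", "regular"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "modular" and beta < 0:
            raise ValueError("beta must be non-negative")
        if mode == "regular" and r_threshold <= 0:
            raise ValueError("r_threshold must be positive")
        n = len(self.nodes)
        Z, ew, strength = self._Z, self._ew, self.strength

        in_mem = np.zeros(n, dtype=bool)
        in_mem[seed] = True
        members = [seed]
        sum_z = Z[seed].copy()
        n_links = np.zeros(n, dtype=np.int32)
        cand_w = np.zeros(n)
        n_links[self._nbrs[seed]] += 1
        cand_w[self._nbrs[seed]] += ew[self._eidx[seed]]
        w_in, w_out = 0.0, float(strength[seed])

        R = float(self._relevance_rows(sum_z[None, :])[0])
        M = 0.0
        eff_beta = beta if mode == "modular" else 0.0
        S = R + eff_beta * M
        history = [(R, M, S)]
        seed_constant = np.ptp(Z[seed]) == 0
        pool = self._within_two(seed) if mode == "regular" else None

        while not seed_constant:
            bmask = (n_links > 0) & ~in_mem
            if pool is not None:
                bmask &= pool
            cand = np.flatnonzero(bmask)
            if cand.size == 0:
                break
            dw = cand_w[cand]
            w_in_n = w_in + 2.0 * dw
            w_out_n = w_out + strength[cand] - 2.0 * dw
            tot = w_in_n + w_out_n
            with np.errstate(divide="ignore", invalid="ignore"):
                Mn = np.where(tot > 0, w_in_n / np.square(tot), 0.0)
            if mode == "modular" and beta > 0:
                # the modularity constraint is cheap; apply it before ranking
                keep = Mn >= M - SCORE_EPS
                if not keep.any():
                    break
                cand, dw = cand[keep], dw[keep]
                w_in_n, w_out_n, Mn = w_in_n[keep], w_out_n[keep], Mn[keep]
            k = len(members)
            acts = (sum_z + Z[cand]) / (k + 1)
            Rn = self._relevance_rows(acts)
            if mode == "modular":
                Sn = Rn + beta * Mn
                ok = (Rn >= R - SCORE_EPS) & (Sn > S + SCORE_EPS)
                crit = Sn
            else:
                Sn = Rn
                ok = (Rn - R) >= r_threshold - SCORE_EPS
                crit = Rn
            if not ok.any():
                break
            oki = np.flatnonzero(ok)
            # ties within SCORE_EPS of the maximum break toward the smallest id
            mx = crit[oki].max()
            pick = oki[int(np.argmax(crit[oki] >= mx - SCORE_EPS))]
            v = int(cand[pick])

            members.append(v)
            in_mem[v] = True
            sum_z += Z[v]
            w_in, w_out = float(w_in_n[pick]), float(w_out_n[pick])
            R, M, S = float(Rn[pick]), float(Mn[pick]), float(Sn[pick])
            n_links[self._nbrs[v]] += 1
            cand_w[self._nbrs[v]] += ew[self._eidx[v]]
            history.append((R, M, S))

        if score_only:
            return S
        names = tuple(self.nodes[self._perm_name(i)] for i in members)
        return Subnetwork(
            seed=names[0],
            members=names,
            activity=sum_z / len(members),
            relevance=R,
            modularity=M,
            score=S,
            beta=eff_beta,
            mode=mode,
            r_threshold=r_threshold if mode == "regular" else None,
            internal_weight=w_in,
            external_weight=w_out,
            history=history,
        )

    def _perm_name(self, i: int) -> int:
        """Gene index carried by node position *i* under the current relabeling."""
        return int(self._perm[i])

    def grow_by_name(self, seed: str, **kwargs) -> Subnetwork:
        if seed not in self.index:
            raise ValueError(f"seed {seed!r} not in network")
        return self.grow(self.index[seed], **kwargs)

    def grow_all(
        self,
        mode: str = "modular",
        beta: float = 250.0,
        r_threshold: float = 0.05,
        seeds=None,
        n_jobs: int = 1,
    ) -> list[Subnetwork]:
        """Grow one subnetwork per seed (default: every node, sorted order)."""
        if seeds is None:
            seed_idx = list(range(len(self.nodes)))
        else:
            seed_idx = [self.index[s] for s in seeds]
        if n_jobs == 1:
            return [self.grow(s, mode, beta, r_threshold) for s in seed_idx]
        return Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(self.grow)(s, mode, beta, r_threshold) for s in seed_idx
        )

    def grow_all_scores(
        self,
        mode: str = "modular",
        beta: float = 250.0,
        r_threshold: float = 0.05,
    ) -> np.ndarray:
        """Final score per seed, skipping Subnetwork construction (fast path)."""
        return np.fromiter(
            (
                self.grow(s, mode, beta, r_threshold, score_only=True)
                for s in range(len(self.nodes))
            ),
            dtype=float,
            count=len(self.nodes),
        )


def grow_subnetwork(
    seed: str,
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
) -> Subnetwork:
    """Grow a single subnetwork from *seed* on the weighted network *g*."""
    if seed not in g.nodes:
        raise ValueError(f"seed {seed!r} not in network")
    return GrowthEngine(g, d).grow_by_name(
        seed, mode=mode, beta=beta, r_threshold=r_threshold
    )


def grow_all(
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
    seeds=None,
    n_jobs: int = 1,
) -> list[Subnetwork]:
    """Grow one subnetwork per network node (or per listed seed)."""
    return GrowthEngine(g, d).grow_all(
        mode=mode, beta=beta, r_threshold=r_threshold, seeds=seeds, n_jobs=n_jobs
    )


def jaccard(a, b) -> float:
    """Jaccard index |a n b| / |a u b| between two non-empty gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return len(a & b) / len(a | b)


def remove_redundant(subs, max_overlap: float = 0.25) -> list[Subnetwork]:
    """Greedy redundancy filter over scored subnetworks.

    Processing in descending score order (ties by seed id), a subnetwork is
    kept iff its Jaccard overlap with every already-kept subnetwork does not
    exceed ``max_overlap`` (strictly-more-than-threshold overlaps are
    eliminated). The output preserves descending score order.
    """
    ordered = sorted(subs, key=lambda s: (-s.score, s.seed))
    kept: list[Subnetwork] = []
    for sub in ordered:
        if all(jaccard(sub.member_set, k.member_set) <= max_overlap for k in kept):
            kept.append(sub)
    return kept
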