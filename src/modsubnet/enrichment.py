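"""Gene-set enrichment of subnetworks and cross-study conservation statistics.

Over-representation is assessed with the upper-tail hypergeometric test
against the analyzable network universe (never the full genome), with
Benjamini-Hochberg control across the sets tested. A coverage filter can
additionally require a category to annotate a minimum fraction of the query
(e.g. at least 25% of a subnetwork's genes) before it is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .scoring import Subnetwork

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper",
    "bh_fdr",
    "enrich",
    "annotate_genes",
    "conservation",
]


@dataclass
class EnrichmentResult:
    """Per-gene-set over-representation outcome."""

    name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p: float
    q: float
    coverage: float
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.query_size):
            raise ValueError("overlap exceeds set or query size")
        if not (0.0 < self.p <= 1.0) or self.q < self.p - 1e-12:
            raise ValueError("invalid p/q values")


def hypergeom_upper(overlap: int, query: int, set_size: int, universe: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_size, query)."""
    if not (0 <= overlap <= min(query, set_size)):
        raise ValueError("overlap must lie in [0, min(query, set_size)]")
    if query > universe or set_size > universe:
        raise ValueError("query and set sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    sets: GeneSetCollection,
    universe,
    fdr_alpha: float = 0.05,
    min_coverage: float = 0.0,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of *query* in every gene set.

    A set is flagged significant iff its BH-adjusted q is below ``fdr_alpha``
    and it covers at least ``min_coverage`` of the query genes. Results are
    sorted by (q, p, name).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    names, pvals, rows = [], [], []
    for name in sets:
        members = set(sets[name]) & universe
        if not members:
            continue
        overlap = len(members & query)
        p = hypergeom_upper(overlap, len(query), len(members), len(universe))
        names.append(name)
        pvals.append(p)
        rows.append((name, len(members), overlap, p))
    qvals = bh_fdr(pvals)
    out = []
    for (name, set_size, overlap, p), q in zip(rows, qvals):
        coverage = overlap / len(query)
        out.append(
            EnrichmentResult(
                name=name,
                universe_size=len(universe),
                set_size=set_size,
                query_size=len(query),
                overlap=overlap,
                p=p,
                q=float(q),
                coverage=coverage,
                significant=bool(q < fdr_alpha and coverage >= min_coverage),
            )
        )
    out.sort(key=lambda r: (r.q, r.p, r.name))
    return out


def annotate_genes(
    target_genes,
    significant_subs: list[Subnetwork],
    sets: GeneSetCollection,
    universe,
    fdr_alpha: float = 0.05,
    min_coverage: float = 0.25,
) -> pd.DataFrame:
    """Transfer subnetwork enrichments to target genes (e.g. longevity genes).

    Each target gene appearing in at least one significant subnetwork receives
    the union of the categories that those subnetworks are significantly
    enriched for (q < ``fdr_alpha`` and coverage >= ``min_coverage``); its
    single most significant annotation (smallest p, ties broken by category
    name) is flagged ``best``. Genes in no subnetwork yield no rows.
    """
    targets = set(target_genes)
    records: dict[str, dict[str, tuple[float, float, str]]] = {}
    for sub in significant_subs:
        hits = targets & sub.member_set
        if not hits:
            continue
        results = enrich(
            sub.member_set, sets, universe, fdr_alpha=fdr_alpha, min_coverage=min_coverage
        )
        for res in results:
            if not res.significant:
                continue
            for gene in hits:
                prev = records.setdefault(gene, {}).get(res.name)
                if prev is None or (res.p, res.q) < (prev[0], prev[1]):
                    records[gene][res.name] = (res.p, res.q, sub.seed)
    rows = []
    for gene in sorted(records):
        annots = records[gene]
        best = min(annots, key=lambda n: (annots[n][0], n))
        for name in sorted(annots):
            p, q, seed = annots[name]
            rows.append(
                {
                    "gene": gene,
                    "category": name,
                    "p": p,
                    "q": q,
                    "source_seed": seed,
                    "best": name == best,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene", "category", "p", "q", "source_seed", "best"]
    )


def conservation(seeds_a, seeds_b, universe) -> tuple[float, float]:
    """Cross-study seed overlap: (Jaccard percentage, hypergeometric p).

    The overlap percentage is |a n b| / |a u b| * 100; its significance is the
    upper-tail hypergeometric probability of an intersection at least that
    large given the two set sizes and the shared universe.
    """
    a, b, universe = set(seeds_a), set(seeds_b), set(universe)
    if not (a <= universe and b <= universe):
        raise ValueError("seed sets must be subsets of the universe")
    if not a or not b:
        raise ValueError("seed sets must be non-empty")
    inter = len(a & b)
    pct = 100.0 * inter / len(a | b)
    p = hypergeom_upper(inter, len(a), len(b), len(universe))
    return pct, p
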