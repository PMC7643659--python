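"""Over-representation analysis and hub-gene selection.

Standard hypergeometric ORA: given a query gene list, a background universe
of N genes of which K belong to a set, and a query of n genes drawn from the
universe, the enrichment p is the upper tail P(X ≥ overlap) with
X ~ Hypergeometric(N, K, n), BH-corrected across the tested sets. The hub
gene is the highest-degree node of the interaction subgraph induced by the
query list.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EdgeList, GeneSetCollection, _clean_symbol


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float
    overlap_genes: tuple[str, ...]


@dataclass(frozen=True)
class HubResult:
    gene: str
    degree: int


def hypergeom_enrich(query, collection: GeneSetCollection,
                     universe) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a query list against every set in a collection.

    Sets and the query are intersected with the universe first; one result
    per set that intersects the universe, sorted by q then p then set id.
    """
    uni = {_clean_symbol(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_genes = {_clean_symbol(g) for g in query} & uni
    if not q_genes:
        raise ValueError("query is empty after intersection with the universe")
    n_uni, n_query = len(uni), len(q_genes)
    rows = []
    for set_id, (desc, members) in collection.sets.items():
        set_in_uni = {_clean_symbol(g) for g in members} & uni
        if not set_in_uni:
            continue
        overlap_genes = tuple(sorted(set_in_uni & q_genes))
        k = len(overlap_genes)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(set_in_uni), n_query))
        rows.append((set_id, desc, k, len(set_in_uni), overlap_genes, min(p, 1.0)))
    if not rows:
        return []
    qvals = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(set_id=sid, description=desc, overlap=k, set_size=ks,
                         query_size=n_query, universe_size=n_uni, p=p,
                         q=float(qv), overlap_genes=genes)
        for (sid, desc, k, ks, genes, p), qv in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.q, r.p, r.set_id))


def hub_gene(query, edges: EdgeList) -> list[HubResult]:
    """Rank query genes by degree in the induced interaction subgraph.

    Ties break alphabetically; the hub is the first entry. Genes with no
    induced edges are omitted; an empty ranking means the edge list does not
    touch the query at all.
    """
    q_genes = {_clean_symbol(g) for g in query}
    degree: dict[str, int] = {}
    for edge in edges.edges:
        a, b = tuple(edge)
        if a in q_genes and b in q_genes:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return [HubResult(gene=g, degree=d) for g, d in ranked]
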