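"""Term overrepresentation against an expressed-gene background via a
conditional hypergeometric walk over a term DAG.

Annotations obey the true-path rule (a gene annotated to a term is annotated
to all its ancestors), applied once at load time.  The walk visits terms
children-before-parents; when a parent is tested, genes annotated to its
already-significant children are removed from both the set count k and the
background count K, so a parent is only called when it carries signal beyond
its children.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["TermDAG", "TermResult", "hypergeom_tail", "conditional_walk",
           "set_background"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class TermDAG:
    """An acyclic is-a hierarchy with ancestor-propagated annotations."""

    graph: nx.DiGraph                       # edges child -> parent
    term_genes: dict                        # term -> frozenset of genes (propagated)
    names: dict = field(default_factory=dict)

    @classmethod
    def build(cls, edges: Iterable[tuple[str, str]],
              annotations: Mapping[str, Iterable[str]],
              names: Mapping[str, str] | None = None) -> "TermDAG":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for terms in annotations.values():
            g.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")
        term_genes: dict[str, set] = {t: set() for t in g.nodes}
        for gene, terms in annotations.items():
            for t in terms:
                if t not in term_genes:
                    raise ValueError(f"gene {gene!r} annotated to unknown term {t!r}")
                term_genes[t].add(gene)
                for anc in nx.descendants(g, t):  # child->parent edges: descendants = ancestors
                    term_genes[anc].add(gene)
        return cls(graph=g,
                   term_genes={t: frozenset(gs) for t, gs in term_genes.items()},
                   names=dict(names or {}))

    def children(self, term: str) -> list:
        return list(self.graph.predecessors(term))

    def topological_leaves_first(self) -> list:
        # child->parent edges, so a topological sort already puts children first
        return list(nx.topological_sort(self.graph))


@dataclass(frozen=True)
class TermResult:
    term: str
    k: int                # set genes with the term (after conditioning)
    K: int                # background genes with the term (after conditioning)
    n: int                # set size
    N: int                # background size
    p: float
    conditioned_on: tuple = ()
    q: float = np.nan


def conditional_walk(dag: TermDAG, gene_set: Iterable[str], background: Iterable[str],
                     alpha: float = 0.05, min_background_count: int = 3) -> list[TermResult]:
    """Conditional hypergeometric walk; returns results sorted by p.

    Terms with fewer than ``min_background_count`` background genes (after
    conditioning) are skipped as untestable.  Child significance for
    conditioning is judged at raw p < alpha; a BH q across tested terms is
    attached afterwards for reporting.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    n, N = len(gene_set), len(background)
    significant: dict[str, bool] = {}
    results = []
    for term in dag.topological_leaves_first():
        genes_t = dag.term_genes.get(term, frozenset()) & background
        removed: set = set()
        cond_children = []
        for child in dag.children(term):
            if significant.get(child):
                removed |= dag.term_genes[child] & background
                cond_children.append(child)
        eligible = genes_t - removed
        K = len(eligible)
        if K < min_background_count:
            log.debug("term %s skipped (K=%d after conditioning)", term, K)
            continue
        k = len(eligible & gene_set)
        p = hypergeom_tail(k, K, n, N)
        significant[term] = p < alpha
        results.append(TermResult(term=term, k=k, K=K, n=n, N=N, p=p,
                                  conditioned_on=tuple(sorted(cond_children))))
    if results:
        qs = bh_adjust([r.p for r in results])
        results = [TermResult(r.term, r.k, r.K, r.n, r.N, r.p, r.conditioned_on, float(q))
                   for r, q in zip(results, qs)]
    return sorted(results, key=lambda r: (r.p, r.term))


def set_background(expressed: Iterable[str], de_genes: Iterable[str]) -> set:
    """Background = expressed genes minus differentially expressed genes."""
    expressed, de_genes = set(expressed), set(de_genes)
    bg = expressed - de_genes
    if not bg:
        raise ValueError("background is empty: every expressed gene is differentially expressed")
    log.info("background: %d of %d expressed genes", len(bg), len(expressed))
    return bg
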