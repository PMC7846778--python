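"""Term enrichment over CGI-to-gene maps with Wang semantic similarity.

Terms live in a directed acyclic graph with typed child->parent edges
(``is_a``, ``part_of``). A CGI carries a term when any of its assigned
genes carries it (after closing gene annotations over ancestors).
Enrichment of a CGI subset against a CGI background is a one-sided
Fisher's exact test per term with BH correction; rarely annotated terms
(fewer than 10 background CGIs by default) are excluded before testing.

Redundant significant terms are collapsed with Wang's graph-based
semantic similarity: each term's ancestors receive S-values decaying by
an edge-type weight along the best path, and the similarity of two terms
is the sum of both S-values over common ancestors divided by the sum of
all S-values. Groups of mutually similar terms keep only the lowest-q
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .methylation import benjamini_hochberg

__all__ = [
    "TermGraph",
    "propagate_ancestors",
    "enrich_terms",
    "wang_similarity",
    "collapse_similar_terms",
    "DEFAULT_EDGE_WEIGHTS",
]

DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class TermGraph:
    """Directed acyclic ontology; edges point child -> parent."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        terms: Iterable[str] | None = None,
    ) -> "TermGraph":
        """Build from (child, parent, relation) triples."""
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for child, parent, relation in edges:
            g.add_edge(child, parent, relation=relation)
        tg = cls(graph=g)
        tg.validate()
        return tg

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TermGraph":
        """Build from a DataFrame with columns child, parent, relation."""
        return cls.from_edges(
            table[["child", "parent", "relation"]].itertuples(index=False, name=None)
        )

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` along parent edges, plus itself."""
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r}")
        return nx.descendants(self.graph, term) | {term}


def propagate_ancestors(
    assignments: Mapping[str, Iterable[str]], graph: TermGraph
) -> dict[str, frozenset[str]]:
    """Close each gene's direct term set over the parent relation.

    Idempotent; every ancestor is counted once (set semantics on DAGs).
    """
    closure_cache: dict[str, set[str]] = {}
    out = {}
    for gene, terms in assignments.items():
        full: set[str] = set()
        for t in terms:
            if t not in closure_cache:
                closure_cache[t] = graph.ancestors(t)
            full |= closure_cache[t]
        out[gene] = frozenset(full)
    return out


def _svalues(
    term: str, graph: TermGraph, weights: Mapping[str, float]
) -> dict[str, float]:
    """Wang S-values of a term's ancestor closure (max over paths)."""
    s = {term: 1.0}
    anc = graph.ancestors(term)
    sub = graph.graph.subgraph(anc)
    # process children before parents so each max is final when read
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(node, data=True):
            if child in s:
                w = weights.get(data.get("relation", "is_a"), 0.0)
                best = max(best, s[child] * w)
        s[node] = best
    return s


def wang_similarity(
    term_a: str,
    term_b: str,
    graph: TermGraph,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Wang semantic similarity of two ontology terms, in [0, 1].

    sim(a, b) = sum over common ancestors (incl. the terms themselves) of
    (S_a + S_b), divided by (SV(a) + SV(b)) where SV is each term's total
    S-value mass. Self-similarity is 1; symmetric by construction.
    """
    w = dict(DEFAULT_EDGE_WEIGHTS if weights is None else weights)
    sa = _svalues(term_a, graph, w)
    sb = _svalues(term_b, graph, w)
    common = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return float(num / den)


def enrich_terms(
    target_cgis: Iterable[str],
    background_cgis: Iterable[str],
    cgi_to_genes: Mapping[str, Iterable[str]],
    gene_to_terms: Mapping[str, Iterable[str]],
    graph: TermGraph | None = None,
    min_background: int = 10,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of a CGI subset vs background.

    Gene annotations are first closed over ancestors when ``graph`` is
    given. Terms carried by fewer than ``min_background`` background CGIs
    are excluded before testing; BH correction runs across the tested
    terms. ``significant`` flags q < ``fdr``.
    """
    background = list(dict.fromkeys(background_cgis))
    if not background:
        raise ValueError("background must be non-empty")
    target = set(target_cgis)
    if not target.issubset(set(background)):
        raise ValueError("target CGIs must be a subset of the background")

    if graph is not None:
        gene_to_terms = propagate_ancestors(
            {g: set(ts) for g, ts in gene_to_terms.items()}, graph
        )
    cgi_terms: dict[str, frozenset[str]] = {}
    for cgi in background:
        terms: set[str] = set()
        for gene in cgi_to_genes.get(cgi, ()):
            terms |= set(gene_to_terms.get(gene, ()))
        cgi_terms[cgi] = frozenset(terms)

    n_bg = len(background)
    n_tg = len(target)
    term_bg_counts: dict[str, int] = {}
    term_tg_counts: dict[str, int] = {}
    for cgi in background:
        in_target = cgi in target
        for t in cgi_terms[cgi]:
            term_bg_counts[t] = term_bg_counts.get(t, 0) + 1
            if in_target:
                term_tg_counts[t] = term_tg_counts.get(t, 0) + 1

    rows = []
    for term in sorted(term_bg_counts):
        k_bg = term_bg_counts[term]
        if k_bg < min_background:
            continue
        k_tg = term_tg_counts.get(term, 0)
        k_rest = k_bg - k_tg
        n_rest = n_bg - n_tg
        table = [[k_tg, n_tg - k_tg], [k_rest, n_rest - k_rest]]
        odds, p = fisher_exact(table, alternative="greater")
        rows.append((term, k_tg, n_tg, k_bg, n_bg, float(odds), float(p)))
    out = pd.DataFrame(
        rows,
        columns=["term", "k_target", "n_target", "k_background", "n_background",
                 "odds_ratio", "p"],
    )
    if len(out):
        out["q"] = benjamini_hochberg(out["p"])
    else:
        out["q"] = pd.Series(dtype=float)
    out["significant"] = out["q"] < fdr
    return out


def collapse_similar_terms(
    results: pd.DataFrame,
    graph: TermGraph,
    threshold: float = 0.7,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Keep one representative per group of semantically similar terms.

    Significant terms are visited in ascending q (ties broken by term id).
    Each unclaimed term seeds a group and is kept; any later unclaimed term
    with Wang similarity strictly above ``threshold`` to the seed joins the
    group and is dropped. Non-significant terms are never kept.

    Returns the input with a ``kept_after_collapse`` column.
    """
    out = results.copy()
    out["kept_after_collapse"] = False
    sig = out[out["significant"]].sort_values(["q", "term"])
    claimed: set[str] = set()
    kept: list[str] = []
    terms = sig["term"].tolist()
    for seed in terms:
        if seed in claimed:
            continue
        claimed.add(seed)
        kept.append(seed)
        for other in terms:
            if other in claimed:
                continue
            if wang_similarity(seed, other, graph, weights) > threshold:
                claimed.add(other)
    out.loc[out["term"].isin(kept), "kept_after_collapse"] = True
    return out
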