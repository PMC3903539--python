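"""Condition-specific gene-gene interaction networks and their reduction
to function-function networks.

A GGIN contains an edge for a gene pair iff (1) the pair is a known
protein-protein interaction and (2) the Pearson correlation of the two
genes' intensities across the condition's samples has p <= p0 (default
closed-form p from the t transform on n-2 degrees of freedom; a seeded
permutation p is available as an opt-in dialect). Per-node degree k and
clustering coefficient C (C = 0 when k < 2) feed the downstream trend
filter.

Enriched ontology terms are found with a conditional hypergeometric test
walked leaves-upward through the DAG: genes explained by an already
significant descendant are removed from both the term's gene set and the
universe before the parent is tested, so parents are only reported when
they add signal beyond their children.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, Ontology, PPINetwork

log = logging.getLogger(__name__)


@dataclass
class CondGraph:
    """Per-condition co-expression graph restricted to PPI pairs."""

    condition: str
    graph: nx.Graph  # edge attrs: r, p; node attrs: k, C

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def metrics(self, gene: str) -> tuple[int, float]:
        """(degree, clustering coefficient); (0, 0) for absent genes."""
        if gene not in self.graph:
            return 0, 0.0
        return self.graph.nodes[gene]["k"], self.graph.nodes[gene]["C"]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "r": d["r"], "p": d["p"]}
            for a, b, d in sorted(
                ((min(u, v), max(u, v), d) for u, v, d in self.graph.edges(data=True))
            )
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"gene": n, "k": self.graph.nodes[n]["k"], "C": self.graph.nodes[n]["C"]}
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows, columns=["gene", "k", "C"])


@dataclass
class FFN:
    """Function-function network: enriched terms with intra/inter edge counts."""

    condition: str
    term_genes: dict[str, set[str]]  # term -> genes of the term inside the GGIN
    intra_edges: dict[str, int] = field(default_factory=dict)
    inter_edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def intra_per_gene(self, term: str) -> float:
        n = len(self.term_genes.get(term, ()))
        return self.intra_edges.get(term, 0) / n if n else 0.0

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "term": t,
                "n_genes": len(self.term_genes[t]),
                "intra_edges": self.intra_edges.get(t, 0),
                "intra_per_gene": self.intra_per_gene(t),
            }
            for t in sorted(self.term_genes)
        ]
        return pd.DataFrame(rows, columns=["term", "n_genes", "intra_edges", "intra_per_gene"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"term_a": a, "term_b": b, "inter_edges": c}
            for (a, b), c in sorted(self.inter_edges.items())
        ]
        return pd.DataFrame(rows, columns=["term_a", "term_b", "inter_edges"])


def pearson_edge_stats(
    m: ExpressionMatrix,
    ppi: PPINetwork,
    condition: str,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson r and p for every PPI pair measurable in the condition.

    p defaults to the closed-form two-sided t transform
    t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; with
    ``n_perm > 0`` a seeded permutation p (sample shuffles of one gene)
    replaces it. Zero-variance genes cause their pairs to be skipped with a
    log notice.
    """
    samples = m.samples_for(condition)
    n = len(samples)
    if n < 4:
        raise ValueError(f"need >=4 samples in condition {condition!r}, got {n}")
    x = m.values[samples]
    present = set(x.index)
    pairs = [(a, b) for a, b in ppi.pairs() if a in present and b in present]
    if not pairs:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r", "p"])
    arr = x.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(x.index)}
    sd = arr.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        log.info("skipping pairs with %d zero-variance genes in %s", int(zero_var.sum()), condition)
    z = (arr - arr.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    ia = np.array([idx[a] for a, _ in pairs])
    ib = np.array([idx[b] for _, b in pairs])
    ok = ~(zero_var[ia] | zero_var[ib])
    r = (z[ia] * z[ib]).sum(axis=1) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    if n_perm > 0:
        if n_perm < 1000:
            raise ValueError("permutation p needs n_perm >= 1000")
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(pairs), dtype=np.int64)
        za, zb = z[ia], z[ib]
        for _ in range(n_perm):
            perm = rng.permutation(n)
            r_perm = (za[:, perm] * zb).sum(axis=1) / (n - 1)
            exceed += np.abs(r_perm) >= np.abs(r) - 1e-12
        p = (1 + exceed) / (1 + n_perm)
    else:
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
    out = pd.DataFrame(
        {
            "gene_a": [a for a, _ in pairs],
            "gene_b": [b for _, b in pairs],
            "r": r,
            "p": p,
        }
    )
    return out.loc[ok].reset_index(drop=True)


def build_ggin(edge_stats: pd.DataFrame, p0: float, condition: str = "") -> CondGraph:
    """Retain edges with p <= p0; nodes are endpoints of retained edges."""
    if not (0 < p0 <= 1):
        raise ValueError("p0 must be in (0, 1]")
    g = nx.Graph()
    kept = edge_stats.loc[edge_stats["p"] <= p0]
    for row in kept.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, r=float(row.r), p=float(row.p))
    if g.number_of_edges() == 0:
        log.warning("GGIN for %r is empty at p0=%g", condition, p0)
    cg = CondGraph(condition, g)
    node_metrics(cg)
    return cg


def node_metrics(g: CondGraph) -> pd.DataFrame:
    """Annotate and return per-node degree k and clustering coefficient C.

    C = 2 * (edges among neighbors) / (k * (k - 1)), defined as 0 when k < 2.
    """
    graph = g.graph
    for node in graph.nodes:
        k = graph.degree(node)
        if k < 2:
            c = 0.0
        else:
            neighbors = list(graph.neighbors(node))
            links = sum(
                1
                for i, u in enumerate(neighbors)
                for v in neighbors[i + 1 :]
                if graph.has_edge(u, v)
            )
            c = 2.0 * links / (k * (k - 1))
        graph.nodes[node]["k"] = k
        graph.nodes[node]["C"] = c
    return g.node_table()


def conditional_go_enrichment(
    genes: set[str],
    onto: Ontology,
    universe: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Conditional hypergeometric enrichment over the ontology DAG.

    Terms are tested leaves-upward (children before parents). For each term
    the gene sets of already-significant descendants are removed from both
    the term's annotated set and the universe, then the upper-tail
    hypergeometric probability P(X >= k) is computed. Rows with p < alpha
    are flagged significant; annotation is propagated up the DAG (a term's
    tested set includes descendants' genes).
    """
    if not genes <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    dag = onto.dag()
    rows = []
    significant: dict[str, set[str]] = {}  # term -> its (effective) gene set
    for term in nx.topological_sort(dag):  # child -> parent edges: leaves first
        if term not in onto.term_genes:
            log.warning("term %r not in ontology annotation; skipped", term)
            continue
        eff = onto.effective_genes(term)
        conditioned: set[str] = set()
        for desc in nx.ancestors(dag, term):  # descendants under child->parent
            if desc in significant:
                conditioned |= significant[desc]
        term_set = (eff - conditioned) & universe
        uni = universe - conditioned
        sel = genes & uni
        k = len(term_set & sel)
        big_n, big_k, n_draw = len(uni), len(term_set), len(sel)
        if big_k == 0 or n_draw == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n_draw))
        is_sig = p < alpha
        if is_sig:
            significant[term] = eff & universe
        rows.append(
            {
                "term": term,
                "p": p,
                "overlap": k,
                "term_size": big_k,
                "universe": big_n,
                "selected": n_draw,
                "significant": is_sig,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "p", "overlap", "term_size", "universe", "selected", "significant"]
    )
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def reduce_to_ffn(
    g: CondGraph, enriched_terms: list[str], onto: Ontology
) -> FFN:
    """Reduce a GGIN to a function-function network over enriched terms.

    Per term: its genes inside the GGIN (direct + descendant annotation)
    and the count of GGIN edges with both endpoints in the term. Per term
    pair: the count of GGIN edges with one endpoint exclusively in each
    term (genes shared by both terms contribute to intra counts only).
    """
    if not enriched_terms:
        raise ValueError("enriched term list is empty")
    nodes = g.nodes
    term_genes = {t: onto.effective_genes(t) & nodes for t in enriched_terms}
    ffn = FFN(g.condition, term_genes)
    edges = [(min(u, v), max(u, v)) for u, v in g.graph.edges]
    for t, gs in term_genes.items():
        ffn.intra_edges[t] = sum(1 for u, v in edges if u in gs and v in gs)
    terms = sorted(term_genes)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            only_a = term_genes[a] - term_genes[b]
            only_b = term_genes[b] - term_genes[a]
            count = sum(
                1
                for u, v in edges
                if (u in only_a and v in only_b) or (u in only_b and v in only_a)
            )
            if count:
                ffn.inter_edges[(a, b)] = count
    return ffn
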