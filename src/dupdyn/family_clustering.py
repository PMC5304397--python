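"""Similarity-hit filtering, graph construction and Markov clustering.

Gene families are defined operationally as clusters of a protein similarity
graph under the Markov Cluster (MCL) algorithm: the column-stochastic flow
matrix is alternately squared (expansion, simulating a random walk) and
raised elementwise to an inflation power (sharpening the walk) until it
converges to a sparse attractor pattern whose connected components are the
clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneFamily, ProteinRecord, SimilarityHit, split_species

__all__ = [
    "filter_hits",
    "build_graph",
    "mcl_cluster",
    "MCLResult",
    "summarize_families",
    "family_matrix",
    "group_specific_families",
    "lineage_specific_rate",
    "group_ages",
]

EDGE_WEIGHT_CAP = 200.0


def filter_hits(
    hits: Iterable[SimilarityHit],
    lengths: Mapping[str, int],
    max_evalue: float = 1e-5,
    min_coverage: float = 0.5,
) -> list[SimilarityHit]:
    """Keep hits with E-value strictly below ``max_evalue`` that align over at
    least ``min_coverage`` of the longer sequence of the pair; drop self-hits.
    """
    kept = []
    for h in hits:
        if h.is_self:
            continue
        for g in (h.query, h.subject):
            if g not in lengths:
                raise KeyError(f"no sequence length known for gene {g!r}")
        if h.evalue >= max_evalue:
            continue
        longest = max(lengths[h.query], lengths[h.subject])
        if h.aln_length / longest < min_coverage:
            continue
        kept.append(h)
    return kept


def _evalue_weight(evalue: float) -> float:
    if evalue <= 0.0:
        return EDGE_WEIGHT_CAP
    return min(EDGE_WEIGHT_CAP, -np.log10(evalue))


def build_graph(filtered_hits: Iterable[SimilarityHit]) -> nx.Graph:
    """Undirected similarity graph; edge weight = min(200, −log10 E-value),
    reciprocal hits merged by the larger weight."""
    g = nx.Graph()
    for h in filtered_hits:
        w = _evalue_weight(h.evalue)
        if w <= 0:
            continue
        if g.has_edge(h.query, h.subject):
            g[h.query][h.subject]["weight"] = max(g[h.query][h.subject]["weight"], w)
        else:
            g.add_edge(h.query, h.subject, weight=w)
    return g


@dataclass
class MCLResult:
    families: list[GeneFamily]
    converged: bool
    n_iterations: int


def _clusters_from_flow(M: np.ndarray, nodes: Sequence[str], eps: float) -> list[set[str]]:
    # attractors carry positive diagonal flow; each attractor row's support is
    # one cluster; overlapping attractor systems are merged so the result is a
    # strict partition
    n = len(nodes)
    attractors = [i for i in range(n) if M[i, i] > eps]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for a in attractors:
        support = np.nonzero(M[a] > eps)[0]
        for j in support:
            union(a, j)
    clusters: dict[int, set[str]] = {}
    assigned = set()
    for a in attractors:
        for j in np.nonzero(M[a] > eps)[0]:
            clusters.setdefault(find(a), set()).add(nodes[j])
            assigned.add(j)
    # nodes never reached by an attractor (numerically dried-out columns):
    # attach to the attractor with the largest flow from that column,
    # ties broken by lexicographic node id via ordered iteration
    for j in range(n):
        if j in assigned:
            continue
        col = M[:, j]
        best = int(np.argmax(col))
        if col[best] > 0 and attractors:
            clusters.setdefault(find(best), set()).add(nodes[j])
        else:
            clusters.setdefault(j, set()).add(nodes[j])
    return [clusters[k] for k in sorted(clusters)]


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.1,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    convergence_tol: float = 1e-6,
    self_loop_weight: float | None = None,
) -> MCLResult:
    """Cluster a similarity graph with the Markov Cluster algorithm.

    Nodes are ordered lexicographically so the result is deterministic and
    invariant to input ordering.  Matrix entries below ``prune_threshold``
    are zeroed after each inflation (with column renormalisation), an
    approximation to the mcl binary's pruning schemes.

    Self-loops default to each node's maximum incident edge weight (the mcl
    convention); a fixed scalar can be supplied instead.  Unit loops on a
    heavily weighted clique make the flow matrix collapse to the identity,
    splitting genuine families, so the max-weight default matters.

    Returns an :class:`MCLResult`; ``converged`` is False when ``max_iter``
    was exhausted, in which case the current clustering is still returned.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u}, {v})")
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    if self_loop_weight is None:
        loops = A.max(axis=1)
        loops[loops == 0.0] = 1.0
    else:
        loops = np.full(n, float(self_loop_weight))
    np.fill_diagonal(A, loops)

    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        M_new = M @ M                      # expansion
        np.power(M_new, inflation, out=M_new)  # inflation
        M_new[M_new < prune_threshold] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M_new /= colsum
        diff = np.abs(M_new - M).max()
        M = M_new
        if diff < convergence_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge after {max_iter} iterations", RuntimeWarning
        )
    clusters = _clusters_from_flow(M, nodes, eps=convergence_tol)
    clusters.sort(key=lambda c: min(c))
    families = [
        GeneFamily(
            family_id=f"F{i + 1:06d}",
            members=frozenset((split_species(g)[0], g) for g in cluster),
        )
        for i, cluster in enumerate(clusters)
    ]
    # partition contract: disjoint and covering
    total = sum(len(f) for f in families)
    assert total == n, "MCL output is not a partition (size mismatch)"
    return MCLResult(families=families, converged=converged, n_iterations=it)


# ---------------------------------------------------------------------------
# Family summaries

def family_matrix(families: Sequence[GeneFamily], species: Sequence[str] | None = None) -> pd.DataFrame:
    """Family × species copy-number matrix."""
    if species is None:
        species = sorted({sp for f in families for sp, _ in f.members})
    data = {
        f.family_id: [f.species_count(sp) for sp in species] for f in families
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(species))


def summarize_families(
    families: Sequence[GeneFamily],
    proteomes: Mapping[str, Sequence[ProteinRecord]] | Mapping[str, int],
) -> pd.DataFrame:
    """Per-species counts of single-copy, multi-copy and unclustered genes.

    A gene is multi-copy for its species iff its family holds ≥ 2 members of
    that species.  Unclustered = proteome genes absent from every family
    (``proteomes`` may map species -> records or species -> gene count).
    """
    rows = {}
    for sp, prot in proteomes.items():
        size = prot if isinstance(prot, int) else len(prot)
        single = multi = clustered = 0
        for fam in families:
            c = fam.species_count(sp)
            clustered += c
            if c >= 2:
                multi += c
            elif c == 1:
                single += 1
        if clustered > size:
            raise ValueError(
                f"{sp}: {clustered} clustered genes exceed proteome size {size}"
            )
        unclustered = size - clustered
        rows[sp] = {
            "single_copy": single + unclustered,
            "multi_copy": multi,
            "unclustered": unclustered,
            "proteome_size": size,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_specific_families(
    families: Sequence[GeneFamily], group: set[str]
) -> list[GeneFamily]:
    """Families with at least one member inside ``group`` and none outside."""
    out = []
    for fam in families:
        present = fam.species_set()
        if present and present <= set(group):
            out.append(fam)
    return out


# ---------------------------------------------------------------------------
# Lineage-specific accumulation rate

def group_ages(tree: dendropy.Tree, group: set[str]) -> tuple[float, float]:
    """(stem length, crown age) of a monophyletic group of leaf taxa.

    Crown age is the depth of the group MRCA (max root-to-leaf distance below
    it); for a single-species group the crown age is 0 and the stem is the
    terminal branch length.  Raises ValueError if the group is not
    monophyletic.
    """
    labels = set(group)
    taxa = [t for t in tree.taxon_namespace if t.label in labels]
    if len(taxa) != len(labels):
        missing = labels - {t.label for t in taxa}
        raise ValueError(f"species not in tree: {sorted(missing)}")
    if len(taxa) == 1:
        leaf = tree.find_node_with_taxon_label(taxa[0].label)
        return float(leaf.edge.length or 0.0), 0.0
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
    if clade_leaves != labels:
        raise ValueError(
            f"group {sorted(labels)} is not monophyletic "
            f"(MRCA clade also contains {sorted(clade_leaves - labels)})"
        )
    stem = float(mrca.edge.length or 0.0)

    def depth(node) -> float:
        if node.is_leaf():
            return 0.0
        return max(
            (child.edge.length or 0.0) + depth(child)
            for child in node.child_nodes()
        )

    return stem, depth(mrca)


def lineage_specific_rate(
    n_group_specific: int, tree: dendropy.Tree, group: set[str]
) -> float:
    """Group-specific gene accumulation rate per relative-time unit:
    count / (stem length + crown age) of the group."""
    stem, crown = group_ages(tree, group)
    total = stem + crown
    if total <= 0:
        raise ValueError("stem + crown age is zero; rate undefined")
    return n_group_specific / total
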