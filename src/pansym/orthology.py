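"""Ortholog family inference: k-mer similarity graph + Markov clustering.

All-vs-all protein similarity is scored as the Jaccard index of k-mer sets,
with a containment coverage (shared k-mers over the shorter sequence's k-mer
count) acting as the match-length cut-off. Edges passing both thresholds
feed a Markov clustering (MCL): alternating expansion (random-walk matrix
self-composition) and inflation (entrywise power with column
renormalization) until the walk matrix stabilizes, after which the attractor
structure yields a hard partition of genes into ortholog families. Genes
with no qualifying edge are reported separately as singletons.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .records import GeneRecord, GenomeCollection

__all__ = [
    "OrthologFamily", "kmer_similarity", "build_similarity_graph",
    "mcl_cluster", "cluster_consistency", "duplication_level",
]


@dataclass(frozen=True)
class OrthologFamily:
    """A cluster of genes across strains; members are (strain, gene_id)."""

    family_id: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.family_id} has no members")

    def strains(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.members)

    def copies_in(self, strain: str) -> int:
        return sum(1 for s, _ in self.members if s == strain)

    def __len__(self) -> int:
        return len(self.members)


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_similarity(seq_a: str, seq_b: str, k: int) -> float:
    """Jaccard index of the two sequences' k-mer sets (symmetric, in [0,1])."""
    ka, kb = _kmer_set(seq_a, k), _kmer_set(seq_b, k)
    return len(ka & kb) / len(ka | kb)


def build_similarity_graph(genomes: GenomeCollection | list[GeneRecord],
                           k: int = 3, min_score: float = 0.5,
                           min_coverage: float = 0.70) -> nx.Graph:
    """All-vs-all k-mer similarity graph over all genes.

    An edge is kept iff Jaccard score >= ``min_score`` and the containment
    coverage (shared k-mers / k-mer count of the shorter sequence) >=
    ``min_coverage``. Every gene is a node (label ``strain|gene_id``), so
    genes without qualifying matches appear as isolated nodes.
    """
    genes = genomes.genes if isinstance(genomes, GenomeCollection) else genomes
    if not genes:
        raise ValueError("empty genome set")
    graph = nx.Graph()
    sets: list[frozenset[str]] = []
    for g in genes:
        graph.add_node(g.label, strain=g.strain, gene_id=g.gene_id)
        sets.append(_kmer_set(g.sequence, k))
    for i in range(len(genes)):
        si = sets[i]
        for j in range(i + 1, len(genes)):
            sj = sets[j]
            shared = len(si & sj)
            if not shared:
                continue
            score = shared / (len(si) + len(sj) - shared)
            coverage = shared / min(len(si), len(sj))
            if score >= min_score and coverage >= min_coverage:
                graph.add_edge(genes[i].label, genes[j].label,
                               score=score, coverage=coverage)
    return graph


def _mcl_component(nodes: list[str], graph: nx.Graph, inflation: float,
                   max_iter: int, tol: float) -> tuple[list[list[str]], bool]:
    """Run MCL on one connected component; returns (clusters, converged)."""
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    w = np.zeros((m, m))
    for u, v, data in graph.subgraph(nodes).edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = data["score"]
    # self-loops at each node's maximum incident weight (MCL regularization)
    np.fill_diagonal(w, w.max(axis=1))
    mat = w / w.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = mat @ mat
        inflated = np.power(expanded, inflation)
        inflated /= inflated.sum(axis=0, keepdims=True)
        diff = float(np.abs(inflated - mat).max())
        mat = inflated
        if diff < tol:
            converged = True
            break
    # Attractors are rows retaining mass on the diagonal; attractors that
    # still attract each other form one attractor system (one cluster seed).
    eps = 1e-8
    attractors = [i for i in range(m) if mat[i, i] > eps]
    if not attractors:  # not converged enough to form attractors
        attractors = [int(np.argmax(np.diag(mat)))]
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    aset = set(attractors)
    for i in attractors:
        for i2 in attractors:
            if i2 > i and (mat[i, i2] > eps or mat[i2, i] > eps):
                union(i, i2)
    systems = sorted({find(i) for i in attractors})
    members: dict[int, list[int]] = {s: [] for s in systems}
    for j in range(m):
        pulls = sorted({find(i) for i in aset if mat[i, j] > eps})
        if not pulls:
            top = int(np.argmax(mat[:, j]))
            pulls = [find(top)] if top in aset else [find(owner_of(top, mat,
                                                                   aset))]
        if len(pulls) == 1:
            members[pulls[0]].append(j)
        else:
            # equally attracted node joins the system holding the
            # lexicographically smallest member id (determinism)
            members[min(pulls, key=lambda s: nodes[s])].append(j)
    clusters = [sorted(nodes[j] for j in cols)
                for s, cols in sorted(members.items()) if cols]
    return clusters, converged


def owner_of(row: int, mat: np.ndarray, aset: set[int]) -> int:
    """Fallback attractor for a row that is itself not an attractor."""
    order = np.argsort(-mat[:, row])
    for i in order:
        if int(i) in aset:
            return int(i)
    return int(order[0])


def mcl_cluster(graph: nx.Graph, inflation: float = 1.5, max_iter: int = 200,
                convergence_tol: float = 1e-6,
                ) -> tuple[list[OrthologFamily], list[tuple[str, str]]]:
    """Markov clustering of the similarity graph.

    Returns (families of size >= 2, singletons); the two exactly tile the
    input node set. Non-convergence within ``max_iter`` emits a warning and
    returns the current hard clustering.
    """
    if inflation <= 0:
        raise ValueError("inflation must be positive")
    singleton_nodes: list[str] = []
    clusters: list[list[str]] = []
    all_converged = True
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            singleton_nodes.append(nodes[0])
            continue
        comp_clusters, converged = _mcl_component(
            nodes, graph, inflation, max_iter, convergence_tol)
        all_converged = all_converged and converged
        for c in comp_clusters:
            if len(c) == 1:
                singleton_nodes.append(c[0])
            else:
                clusters.append(c)
    if not all_converged:
        warnings.warn("MCL did not converge within max_iter; returning the "
                      "current hard clustering", RuntimeWarning)

    def split(label: str) -> tuple[str, str]:
        strain, gene_id = label.split("|", 1)
        return strain, gene_id

    clusters.sort(key=lambda c: c[0])
    families = [OrthologFamily(family_id=f"OG{i+1:05d}",
                               members=tuple(split(n) for n in c))
                for i, c in enumerate(clusters)]
    singletons = sorted(split(n) for n in singleton_nodes)
    return families, singletons


def cluster_consistency(families: list[OrthologFamily],
                        annotations: dict[tuple[str, str], str],
                        ) -> dict[str, float | None]:
    """Per-family COG homogeneity: fraction of annotated members sharing the
    modal category. Families with no annotated member map to ``None``
    (not assessable)."""
    report: dict[str, float | None] = {}
    for fam in families:
        labels = [annotations[m] for m in fam.members if m in annotations]
        if not labels:
            report[fam.family_id] = None
            continue
        _, modal_count = Counter(labels).most_common(1)[0]
        report[fam.family_id] = modal_count / len(labels)
    return report


def duplication_level(families: list[OrthologFamily], strain: str,
                      beyond_first: bool = False) -> float:
    """Percentage of the strain's genes lying in families with >= 2 members
    from that strain.

    ``families`` must cover the strain's full gene set (clustered families
    plus its singleton families). With ``beyond_first`` only the extra
    copies beyond the first per family are counted as duplicated.
    """
    total = 0
    duplicated = 0
    for fam in families:
        copies = fam.copies_in(strain)
        total += copies
        if copies >= 2:
            duplicated += (copies - 1) if beyond_first else copies
    if total == 0:
        raise ValueError(f"strain {strain!r} has no genes in the family set")
    return 100.0 * duplicated / total
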