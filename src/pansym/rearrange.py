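"""Signed gene-order rearrangement analysis.

Single-copy-core gene orders are encoded as signed permutations (sign =
strand relative to a reference strain). Pairwise dissimilarity comes in two
flavours: the breakpoint count (non-conserved oriented adjacencies) and the
exact minimal reversal distance of Hannenhalli and Pevzner, computed on the
breakpoint graph as

    d = (n + 1) - c + h + f

where c counts alternating cycles, h counts hurdles (unoriented components
whose span is not interleaved with another unoriented component) and f
flags a fortress (an odd number of hurdles, all of them superhurdles).
A greedy most-parsimonious-reversal search yields sorting scenarios, median
genomes and a minimal-rearrangement tree in the style of MGR, plus synteny
run tables for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .records import GeneRecord
from .orthology import OrthologFamily

__all__ = [
    "SignedGenomeOrder", "BreakpointGraphSummary", "encode_orders",
    "breakpoint_distance", "reversal_distance", "sorting_scenario",
    "mgr_tree", "synteny_pairs", "apply_reversal",
]


@dataclass(frozen=True)
class SignedGenomeOrder:
    """A strain's single-copy-core order as a signed permutation."""

    strain: str
    order: tuple[int, ...]
    shape: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "circular"):
            raise ValueError(f"invalid shape {self.shape!r}")
        seen = {abs(v) for v in self.order}
        if 0 in seen or len(seen) != len(self.order):
            raise ValueError(f"{self.strain}: order is not a signed "
                             "permutation (repeated or zero ids)")

    @property
    def n(self) -> int:
        return len(self.order)

    def gene_set(self) -> frozenset[int]:
        return frozenset(abs(v) for v in self.order)


@dataclass(frozen=True)
class BreakpointGraphSummary:
    n: int
    b: int  # breakpoints
    c: int  # alternating cycles
    h: int  # hurdles
    fortress: bool


def apply_reversal(order: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse segment [i..j] (1-based inclusive positions), flipping signs."""
    if not (1 <= i <= j <= len(order)):
        raise ValueError(f"invalid segment ({i},{j}) for n={len(order)}")
    a = i - 1
    return order[:a] + tuple(-x for x in reversed(order[a:j])) + order[j:]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def canonical_linear(order: SignedGenomeOrder) -> SignedGenomeOrder:
    """Canonicalize a circular order: rotate/reflect so gene 1 comes first
    with positive sign, then treat as linear."""
    if order.shape == "linear":
        return order
    seq = list(order.order)
    pos = next(k for k, v in enumerate(seq) if abs(v) == 1)
    seq = seq[pos:] + seq[:pos]
    if seq[0] < 0:
        seq = [-v for v in reversed(seq)]
        seq = seq[-1:] + seq[:-1]
    return SignedGenomeOrder(strain=order.strain, order=tuple(seq),
                             shape="linear")


def encode_orders(genes: list[GeneRecord], scc_families: list[OrthologFamily],
                  reference_strain: str, shape: str = "linear",
                  ) -> dict[str, SignedGenomeOrder]:
    """Encode each strain's single-copy-core gene order as a signed
    permutation, renumbered so the reference strain is the identity.

    Genes are ordered by (contig, start); a gene's sign is + iff its strand
    matches the reference strain's strand for the same family.
    """
    member_of: dict[tuple[str, str], str] = {}
    strains: set[str] = set()
    for fam in scc_families:
        for m in fam.members:
            member_of[m] = fam.family_id
            strains.add(m[0])
    if reference_strain not in strains:
        raise KeyError(f"reference strain {reference_strain!r} not in the "
                       "single-copy core")

    per_strain: dict[str, list[GeneRecord]] = {s: [] for s in strains}
    for g in genes:
        if g.key in member_of:
            per_strain[g.strain].append(g)

    n_fam = len(scc_families)
    for s, recs in per_strain.items():
        fams = [member_of[g.key] for g in recs]
        if len(recs) != n_fam or len(set(fams)) != n_fam:
            raise ValueError(f"strain {s}: expected exactly one gene per "
                             f"single-copy-core family ({n_fam}), found "
                             f"{len(recs)} genes over {len(set(fams))} families")

    ref_sorted = sorted(per_strain[reference_strain],
                        key=lambda g: (g.contig, g.start))
    fam_rank = {member_of[g.key]: idx + 1 for idx, g in enumerate(ref_sorted)}
    ref_strand = {member_of[g.key]: g.strand for g in ref_sorted}

    out: dict[str, SignedGenomeOrder] = {}
    for s, recs in per_strain.items():
        ordered = sorted(recs, key=lambda g: (g.contig, g.start))
        signed = []
        for g in ordered:
            fam = member_of[g.key]
            sign = 1 if g.strand == ref_strand[fam] else -1
            signed.append(sign * fam_rank[fam])
        out[s] = SignedGenomeOrder(strain=s, order=tuple(signed), shape=shape)
    return out


def _relative_to(a: SignedGenomeOrder, b: SignedGenomeOrder) -> tuple[int, ...]:
    """Relabel so that b becomes the identity; returns a in b's frame."""
    if a.gene_set() != b.gene_set():
        raise ValueError("orders are over different gene sets")
    if a.shape != b.shape:
        raise ValueError("orders have different shapes")
    if a.shape == "circular":
        a, b = canonical_linear(a), canonical_linear(b)
    mapping = {abs(v): (idx + 1, 1 if v > 0 else -1)
               for idx, v in enumerate(b.order)}
    out = []
    for v in a.order:
        rank, sign = mapping[abs(v)]
        out.append(rank * sign * (1 if v > 0 else -1))
    return tuple(out)


# ---------------------------------------------------------------------------
# breakpoint distance
# ---------------------------------------------------------------------------

def _adjacencies(order: tuple[int, ...]) -> set[tuple[int, int]]:
    """Oriented adjacencies with linear end caps 0 and n+1, canonicalized so
    (x, y) and (-y, -x) coincide."""
    n = len(order)
    seq = (0,) + order + (n + 1,)
    adj = set()
    for x, y in zip(seq, seq[1:]):
        adj.add((x, y) if (x, y) <= (-y, -x) else (-y, -x))
    return adj


def breakpoint_distance(a: SignedGenomeOrder, b: SignedGenomeOrder) -> int:
    """Number of adjacencies of one order (end caps included) not conserved
    with orientation in the other; symmetric."""
    rel = _relative_to(a, b)
    ident = tuple(range(1, len(rel) + 1))
    return len(_adjacencies(rel) - _adjacencies(ident))


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner reversal distance
# ---------------------------------------------------------------------------

def _hp_summary(perm: tuple[int, ...]) -> BreakpointGraphSummary:
    """Breakpoint-graph summary of a signed permutation vs the identity."""
    n = len(perm)
    # vertex encoding: +x -> (2x-1, 2x); -x -> (2x, 2x-1); frame 0 .. 2n+1
    seq = [0]
    for v in perm:
        x = abs(v)
        seq.extend((2 * x - 1, 2 * x) if v > 0 else (2 * x, 2 * x - 1))
    seq.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(seq)}

    # gray (desire) edges: (2i, 2i+1) for i = 0..n; black (reality) edges
    # join positions (2k, 2k+1)
    gray = [(2 * i, 2 * i + 1) for i in range(n + 1)]

    # cycle decomposition: follow alternating black/gray edges
    cycle_of: dict[int, int] = {}
    cycle_edges: list[list[int]] = []  # gray-edge indices per cycle
    cycle_id = 0
    visited: set[int] = set()
    black_partner = {}
    for k in range(n + 1):
        u, v = seq[2 * k], seq[2 * k + 1]
        black_partner[u] = v
        black_partner[v] = u
    gray_partner = {}
    for u, v in gray:
        gray_partner[u] = v
        gray_partner[v] = u
    gray_index = {}
    for gi, (u, v) in enumerate(gray):
        gray_index[u] = gi
        gray_index[v] = gi

    for start in seq:
        if start in visited:
            continue
        edges_here: list[int] = []
        cur = start
        while cur not in visited:
            visited.add(cur)
            nxt = black_partner[cur]
            visited.add(nxt)
            edges_here.append(gray_index[nxt])
            cur = gray_partner[nxt]
        for gi in edges_here:
            cycle_of[gi] = cycle_id
        cycle_edges.append(edges_here)
        cycle_id += 1
    c = cycle_id

    b = sum(1 for u, v in gray if abs(pos[u] - pos[v]) != 1)

    # oriented gray edge: endpoints at positions of equal parity
    oriented_edge = [abs(pos[u] % 2 - pos[v] % 2) == 0 for u, v in gray]
    trivial_cycle = [len(cycle_edges[ci]) == 1 and
                     abs(pos[gray[cycle_edges[ci][0]][0]] -
                         pos[gray[cycle_edges[ci][0]][1]]) == 1
                     for ci in range(c)]
    cycle_oriented = [any(oriented_edge[gi] for gi in cycle_edges[ci])
                      for ci in range(c)]

    # components: union cycles whose gray edges interleave as chords
    parent = list(range(c))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    spans = []
    for gi, (u, v) in enumerate(gray):
        lo, hi = sorted((pos[u], pos[v]))
        spans.append((lo, hi, cycle_of[gi]))
    for (l1, h1, c1), (l2, h2, c2) in combinations(spans, 2):
        if c1 == c2:
            continue
        if (l1 < l2 < h1 < h2) or (l2 < l1 < h2 < h1):
            union(c1, c2)

    comp_cycles: dict[int, list[int]] = {}
    for ci in range(c):
        comp_cycles.setdefault(find(ci), []).append(ci)

    unoriented_comps = set()
    for root, cycles in comp_cycles.items():
        if all(trivial_cycle[ci] for ci in cycles):
            continue  # adjacency-only component, not a real component
        if not any(cycle_oriented[ci] for ci in cycles):
            unoriented_comps.add(root)

    h = 0
    fortress = False
    if unoriented_comps:
        # scan frame positions; record the unoriented component of each
        # position (via the cycle its vertex lies on), squashing repeats on a
        # circle: a component whose occupied stretch is uninterrupted by any
        # other unoriented component appears exactly once -> hurdle
        comp_at: list[int] = []
        vertex_cycle: dict[int, int] = {}
        for ci in range(c):
            for gi in cycle_edges[ci]:
                u, v = gray[gi]
                vertex_cycle[u] = ci
                vertex_cycle[v] = ci
        for p in range(len(seq)):
            ci = vertex_cycle[seq[p]]
            root = find(ci)
            if root in unoriented_comps:
                comp_at.append(root)
        squashed: list[int] = []
        for comp in comp_at:
            if not squashed or squashed[-1] != comp:
                squashed.append(comp)
        if len(squashed) > 1 and squashed[0] == squashed[-1]:
            squashed.pop()  # circular squash
        occurrences: dict[int, int] = {}
        for comp in squashed:
            occurrences[comp] = occurrences.get(comp, 0) + 1
        hurdles = [comp for comp, k in occurrences.items() if k == 1]
        h = len(hurdles)
        if h % 2 == 1 and h > 1 and len(occurrences) > h:
            m = len(squashed)
            super_flags = []
            for comp in hurdles:
                i = squashed.index(comp)
                before = squashed[(i - 1) % m]
                after = squashed[(i + 1) % m]
                is_super = (m >= 3 and before == after and
                            occurrences.get(before, 0) == 2)
                super_flags.append(is_super)
            fortress = all(super_flags)
    return BreakpointGraphSummary(n=n, b=b, c=c, h=h, fortress=fortress)


def reversal_distance(a: SignedGenomeOrder, b: SignedGenomeOrder,
                      ) -> tuple[int, BreakpointGraphSummary]:
    """Exact minimal number of signed reversals transforming one order into
    the other (symmetric; 0 iff equal)."""
    rel = _relative_to(a, b)
    summary = _hp_summary(rel)
    d = (summary.n + 1) - summary.c + summary.h + (1 if summary.fortress else 0)
    return d, summary


def _perm_distance(perm: tuple[int, ...]) -> int:
    s = _hp_summary(perm)
    return (s.n + 1) - s.c + s.h + (1 if s.fortress else 0)


def sorting_scenario(a: SignedGenomeOrder, b: SignedGenomeOrder,
                     ) -> list[tuple[int, int]]:
    """An optimal reversal list (1-based inclusive segments, applied left to
    right to ``a``) realizing the reversal distance."""
    rel = _relative_to(a, b)
    scenario: list[tuple[int, int]] = []
    current = rel
    d = _perm_distance(current)
    n = len(rel)
    while d > 0:
        found = False
        for i in range(1, n + 1):
            for j in range(i, n + 1):
                cand = apply_reversal(current, i, j)
                if _perm_distance(cand) == d - 1:
                    scenario.append((i, j))
                    current = cand
                    d -= 1
                    found = True
                    break
            if found:
                break
        if not found:  # cannot happen for a correct distance
            raise RuntimeError("no distance-reducing reversal found")
    return scenario


# ---------------------------------------------------------------------------
# MGR-style tree
# ---------------------------------------------------------------------------

@dataclass
class MgrResult:
    newick: str
    internal_orders: dict[str, SignedGenomeOrder]
    edge_distances: dict[tuple[str, str], int]
    total_distance: int
    converged: bool


def _breakpoint_boundaries(perm: tuple[int, ...],
                           target: tuple[int, ...]) -> set[int]:
    """Boundary indices k (cut between positions k and k+1, 0..n) that are
    breakpoints of ``perm`` relative to ``target``."""
    rel = _compose(perm, target)
    n = len(rel)
    seq = (0,) + rel + (n + 1,)
    return {k for k in range(n + 1) if seq[k + 1] - seq[k] != 1}


def _greedy_median(targets: list[tuple[int, ...]], start: tuple[int, ...],
                   max_moves: int = 200) -> tuple[tuple[int, ...], bool]:
    """Hill-climb a median: apply the reversal maximally decreasing the sum
    of reversal distances to the targets; ties broken by smallest (start,
    end) segment.

    Candidate reversals are restricted to segments whose two cut points are
    both breakpoints relative to the same target — reversals cutting only
    conserved adjacencies cannot move the median closer to anything.
    """
    current = start

    def total(perm: tuple[int, ...]) -> int:
        return sum(_perm_distance(_compose(perm, t)) for t in targets)

    best = total(current)
    for _ in range(max_moves):
        candidates: set[tuple[int, int]] = set()
        for t in targets:
            cuts = sorted(_breakpoint_boundaries(current, t))
            for a_i, left in enumerate(cuts):
                for right in cuts[a_i + 1:]:
                    candidates.add((left + 1, right))
        best_move = None
        best_score = best
        for i, j in sorted(candidates):
            cand = apply_reversal(current, i, j)
            score = total(cand)
            if score < best_score:
                best_score = score
                best_move = (i, j)
        if best_move is None:
            return current, True
        current = apply_reversal(current, *best_move)
        best = best_score
    return current, False


def _compose(perm: tuple[int, ...], frame: tuple[int, ...]) -> tuple[int, ...]:
    """Express ``perm`` relative to ``frame`` (both over 1..n)."""
    mapping = {abs(v): (idx + 1, 1 if v > 0 else -1)
               for idx, v in enumerate(frame)}
    return tuple(mapping[abs(v)][0] * mapping[abs(v)][1] *
                 (1 if v > 0 else -1) for v in perm)


def mgr_tree(orders: list[SignedGenomeOrder],
             topology: str | None = None,
             max_rounds: int = 10) -> MgrResult:
    """Minimal-rearrangement tree via iterated greedy medians.

    With three genomes this reduces to a single median (star) problem. With
    more, a fixed or NJ-derived unrooted binary topology is steinerized:
    each internal node's order is repeatedly replaced by the greedy median
    of its three neighbours until the total edge distance stops improving.
    Edge lengths are exact pairwise reversal distances.
    """
    if len(orders) < 3:
        raise ValueError("need at least 3 genomes")
    names = [o.strain for o in orders]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain names")
    gene_sets = {o.gene_set() for o in orders}
    if len(gene_sets) != 1:
        raise ValueError("orders are over different gene sets")
    shape = orders[0].shape
    lin = {o.strain: canonical_linear(o) if shape == "circular" else o
           for o in orders}
    by_name = {s: o.order for s, o in lin.items()}

    # --- tree structure: (internal node -> neighbour names) ---------------
    if len(orders) == 3:
        internals = {"M1": list(names)}
        edges = [("M1", nm) for nm in names]
        newick = f"({names[0]},{names[1]},{names[2]})M1;"
    else:
        internals, edges, newick = _unrooted_topology(orders, topology)

    # --- initialize internal nodes at their closest leaf -------------------
    orders_now: dict[str, tuple[int, ...]] = dict(by_name)
    for node, neigh in internals.items():
        leaves = [nm for nm in neigh if nm in by_name]
        seed_leaf = leaves[0] if leaves else names[0]
        orders_now[node] = by_name[seed_leaf]

    def edge_dist(u: str, v: str) -> int:
        return _perm_distance(_compose(orders_now[u], orders_now[v]))

    def tree_total() -> int:
        return sum(edge_dist(u, v) for u, v in edges)

    converged = True
    prev = tree_total()
    for _ in range(max_rounds):
        improved = False
        for node in sorted(internals):
            targets = [orders_now[nm] for nm in internals[node]]
            start_candidates = targets + [orders_now[node]]
            best_start = min(
                start_candidates,
                key=lambda s: sum(_perm_distance(_compose(s, t))
                                  for t in targets))
            median, ok = _greedy_median(targets, best_start)
            converged = converged and ok
            orders_now[node] = median
        now = tree_total()
        if now < prev:
            improved = True
            prev = now
        if not improved:
            break

    internal_orders = {
        node: SignedGenomeOrder(strain=node, order=orders_now[node],
                                shape="linear")
        for node in internals}
    edge_distances = {(u, v): edge_dist(u, v) for u, v in edges}
    return MgrResult(newick=newick, internal_orders=internal_orders,
                     edge_distances=edge_distances,
                     total_distance=sum(edge_distances.values()),
                     converged=converged)


def _unrooted_topology(orders: list[SignedGenomeOrder],
                       topology: str | None,
                       ) -> tuple[dict[str, list[str]],
                                  list[tuple[str, str]], str]:
    """Unrooted binary topology over the leaves, from Newick or NJ on the
    reversal-distance matrix."""
    names = [o.strain for o in orders]
    if topology is None:
        import numpy as np
        from skbio import DistanceMatrix
        from skbio.tree import nj as _nj
        k = len(orders)
        d = np.zeros((k, k), dtype=float)
        for i in range(k):
            for j in range(i + 1, k):
                d[i, j] = d[j, i] = reversal_distance(orders[i], orders[j])[0]
        tree = _nj(DistanceMatrix(d, ids=names))
    else:
        from io import StringIO
        from skbio import TreeNode
        tree = TreeNode.read(StringIO(topology))
    tree = tree.unrooted_copy() if hasattr(tree, "unrooted_copy") else tree
    internals: dict[str, list[str]] = {}
    edges: list[tuple[str, str]] = []
    counter = 0
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        if node.name is None or not str(node.name).strip() \
                or node.name in names:
            counter += 1
            node.name = f"M{counter}"
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            continue
        neigh = [c.name for c in node.children]
        if node.parent is not None:
            neigh.append(node.parent.name)
        internals[node.name] = neigh
        for c in node.children:
            edges.append((node.name, c.name))
    # degree-2 root (rooted newick input): splice it out
    for node, neigh in list(internals.items()):
        if len(neigh) == 2:
            a, b = neigh
            edges = [e for e in edges if node not in e]
            edges.append((a, b))
            internals.pop(node)
            for other in internals:
                internals[other] = [b if x == node and other == a else
                                    a if x == node and other == b else x
                                    for x in internals[other]]
    newick = str(tree).strip()
    return internals, edges, newick


# ---------------------------------------------------------------------------
# synteny runs
# ---------------------------------------------------------------------------

def synteny_pairs(a: SignedGenomeOrder, b: SignedGenomeOrder) -> pd.DataFrame:
    """Maximal runs of consecutive genes conserved in order and relative
    orientation between two genomes.

    Returns a table with 1-based inclusive coordinates (start_a, end_a,
    start_b, end_b, orientation), suitable for synteny plotting.
    """
    rel = _relative_to(a, b)  # b's frame: b is the identity
    n = len(rel)
    runs: list[tuple[int, int, int, int, str]] = []
    i = 0
    while i < n:
        j = i
        if rel[i] > 0:
            while (j + 1 < n and rel[j + 1] > 0 and
                   rel[j + 1] == rel[j] + 1):
                j += 1
            orientation = "+"
            start_b, end_b = rel[i], rel[j]
        else:
            while (j + 1 < n and rel[j + 1] < 0 and
                   rel[j + 1] == rel[j] + 1):
                j += 1
            orientation = "-"
            start_b, end_b = -rel[i], -rel[j]
        runs.append((i + 1, j + 1, start_b, end_b, orientation))
        i = j + 1
    return pd.DataFrame(runs, columns=["start_a", "end_a", "start_b",
                                       "end_b", "orientation"])
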