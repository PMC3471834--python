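"""Single-copy-core phylogeny: supermatrix, distances, NJ, bootstrap.

Families with exactly one member in every strain (the single-copy core) are
concatenated into an aligned protein supermatrix. Pairwise distances are
Poisson-corrected amino-acid distances d = -ln(1 - p), trees are built by
neighbor joining (exact on additive matrices), rooted on an outgroup when
one is given, and split support is estimated by bootstrap resampling of
supermatrix columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .orthology import OrthologFamily

__all__ = ["Supermatrix", "single_copy_core", "concatenate",
           "poisson_distance", "distance_matrix", "nj_tree",
           "bootstrap_support", "tree_splits"]


@dataclass
class Supermatrix:
    """Concatenated aligned residue columns for an ordered taxon set."""

    taxa: list[str]
    rows: list[str]  # one concatenated sequence per taxon
    family_boundaries: list[tuple[str, int, int]]  # (family, start, end), 0-based half-open

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def as_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(),
                             dtype=np.uint8).reshape(len(self.taxa), -1)

    def drop_ambiguous_columns(self) -> "Supermatrix":
        """Optional curation: drop columns containing any unknown residue."""
        arr = self.as_array()
        keep = ~(arr == ord("X")).any(axis=0)
        rows = ["".join(r[i] for i in range(len(r)) if keep[i])
                for r in self.rows]
        return Supermatrix(taxa=list(self.taxa), rows=rows,
                           family_boundaries=[])


def single_copy_core(families: list[OrthologFamily], strains: list[str],
                     require_outgroup: bool = False,
                     outgroup: str | None = None) -> list[OrthologFamily]:
    """Families with exactly one member in every strain (and the outgroup
    when required)."""
    required = list(strains)
    if require_outgroup:
        if outgroup is None:
            raise ValueError("require_outgroup set but no outgroup given")
        if outgroup not in required:
            required.append(outgroup)
    out = []
    for fam in families:
        if all(fam.copies_in(s) == 1 for s in required) and \
                len(fam) == len(required):
            out.append(fam)
    return out


def concatenate(family_sequences: dict[str, dict[str, str]],
                taxon_order: list[str]) -> Supermatrix:
    """Concatenate per-family taxon->sequence maps into a supermatrix.

    Sequences within a family must be equal length (inputs are gap-free and
    pre-aligned); families are concatenated in sorted family-id order.
    """
    rows = {t: [] for t in taxon_order}
    boundaries: list[tuple[str, int, int]] = []
    col = 0
    for fam_id in sorted(family_sequences):
        seqs = family_sequences[fam_id]
        missing = [t for t in taxon_order if t not in seqs]
        if missing:
            raise ValueError(f"family {fam_id} missing taxa {missing}")
        lengths = {len(seqs[t]) for t in taxon_order}
        if len(lengths) > 1:
            raise ValueError(f"family {fam_id} has unequal sequence lengths "
                             f"{sorted(lengths)}; inputs must be aligned")
        length = lengths.pop()
        for t in taxon_order:
            rows[t].append(seqs[t])
        boundaries.append((fam_id, col, col + length))
        col += length
    return Supermatrix(taxa=list(taxon_order),
                       rows=["".join(rows[t]) for t in taxon_order],
                       family_boundaries=boundaries)


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p), p = fraction of
    differing columns."""
    if len(row_a) != len(row_b):
        raise ValueError("rows of unequal length")
    if not row_a:
        raise ValueError("empty rows")
    p = sum(a != b for a, b in zip(row_a, row_b)) / len(row_a)
    if p >= 1.0:
        raise ValueError("saturated distance (all columns differ)")
    return -np.log(1.0 - p)


def distance_matrix(sm: Supermatrix) -> pd.DataFrame:
    """All pairwise Poisson-corrected distances of a supermatrix."""
    arr = sm.as_array()
    n = len(sm.taxa)
    d = np.zeros((n, n))
    cols = arr.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            p = np.count_nonzero(arr[i] != arr[j]) / cols
            if p >= 1.0:
                raise ValueError(f"saturated distance between {sm.taxa[i]} "
                                 f"and {sm.taxa[j]}")
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return pd.DataFrame(d, index=sm.taxa, columns=sm.taxa)


def nj_tree(dm: pd.DataFrame, outgroup: str | None = None) -> TreeNode:
    """Neighbor-joining tree; rooted at the midpoint of the outgroup's
    terminal edge when an outgroup is given."""
    arr = dm.values
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    if (arr < 0).any():
        raise ValueError("negative distances")
    sk_dm = DistanceMatrix(arr, ids=list(dm.index))
    tree = _skbio_nj(sk_dm)
    # NJ can emit tiny negative branch lengths from noise; clamp at zero
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    if outgroup is not None:
        tree = root_on_outgroup(tree, outgroup)
    return tree


def root_on_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root an unrooted NJ tree on the outgroup's terminal edge midpoint."""
    tips = {t.name for t in tree.tips()}
    if outgroup not in tips:
        raise KeyError(f"outgroup {outgroup!r} not among taxa")
    og = [t for t in tree.tips() if t.name == outgroup][0]
    length = og.length or 0.0
    rerooted = tree.root_at(og.parent, reset=True)
    og = [t for t in rerooted.tips() if t.name == outgroup][0]
    parent = og.parent
    parent.remove(og)
    og.length = length / 2.0
    rest = TreeNode(name=None, length=length / 2.0)
    for child in list(parent.children):
        parent.remove(child)
        rest.append(child)
    root = TreeNode(name="root")
    root.append(rest)
    root.append(og)
    return root


def tree_splits(tree: TreeNode, taxa: list[str] | None = None,
                ) -> set[frozenset[str]]:
    """Non-trivial splits as canonical tip-name bipartitions.

    Each internal edge's split is represented by the side not containing
    the alphabetically first taxon, so rooted and unrooted versions of the
    same topology compare equal.
    """
    if taxa is None:
        taxa = sorted(t.name for t in tree.tips())
    full = frozenset(taxa)
    ref = min(full)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(full) - 1:
            continue
        canon = full - side if ref in side else side
        if 1 < len(canon) < len(full) - 1:
            splits.add(canon)
    return splits


def bootstrap_support(sm: Supermatrix, n_replicates: int = 100,
                      seed: int = 0, outgroup: str | None = None,
                      ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Column-resampling bootstrap support for the splits of the full-data
    NJ tree, as percentages."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dm = distance_matrix(sm)
    tree = nj_tree(dm, outgroup=outgroup)
    ref_splits = tree_splits(tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    arr = sm.as_array()
    n_cols = arr.shape[1]
    n = len(sm.taxa)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = arr[:, idx]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = np.count_nonzero(rep[i] != rep[j]) / n_cols
                p = min(p, 1.0 - 1e-12)
                d[i, j] = d[j, i] = -np.log(1.0 - p)
        rep_tree = _skbio_nj(DistanceMatrix(d, ids=list(sm.taxa)))
        rep_splits = tree_splits(rep_tree, taxa=sm.taxa)
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    return tree, support
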