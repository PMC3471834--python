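"""COG functional-category profiles and their divergence analysis.

A profile is the vector of COG-category counts of a unit — a strain, the
core genome, the pan-genome, or a combined (consortium) profile. Relative
profiles divide by the unit's total COG-assigned CDSs. Divergence of an
endosymbiont from the free-living average is expressed per category in
percentage points, and classified on a six-level retained/reduced scale.
Kruskal–Wallis rank tests compare absolute profiles across units, and
two-way hierarchical clustering orders units and categories for heatmap
export.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import isfinite

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .orthology import OrthologFamily
from .records import GeneRecord

__all__ = [
    "CogProfileMatrix", "DivergenceTable", "RETENTION_LABELS",
    "strain_profiles", "family_profile", "relative_profile",
    "fls_divergence", "categorize_retention", "ratio_table",
    "kruskal_wallis", "combine_profiles", "hierarchical_cluster",
]

DEFAULT_CATEGORIES = list("JKLDVTMNUOCGEFHIPQRS")

RETENTION_LABELS = (
    "extremely_retained", "highly_retained", "moderately_retained",
    "moderately_reduced", "highly_reduced", "extremely_reduced",
)


@dataclass
class CogProfileMatrix:
    """Unit x category count matrix (integer counts of assigned CDSs)."""

    counts: pd.DataFrame  # rows = units, columns = COG letters

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def units(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class DivergenceTable:
    """Signed per-category deviations (percentage points) from the
    free-living average."""

    deltas: pd.DataFrame
    fls_set: tuple[str, ...]


def _tally(labels: list[str | None], categories: list[str]) -> dict[str, int]:
    row = {c: 0 for c in categories}
    for lab in labels:
        if lab is None:
            continue
        if lab not in row:
            raise ValueError(f"unknown COG category {lab!r}")
        row[lab] += 1
    return row


def strain_profiles(genes: list[GeneRecord],
                    categories: list[str] | None = None) -> CogProfileMatrix:
    """Tally assigned COG letters per strain; unassigned genes are excluded
    from counts and totals."""
    categories = categories or DEFAULT_CATEGORIES
    by_strain: dict[str, list[str | None]] = {}
    for g in genes:
        by_strain.setdefault(g.strain, []).append(g.cog)
    rows = {s: _tally(labs, categories) for s, labs in by_strain.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[categories]
    return CogProfileMatrix(counts=df.astype(int))


def family_profile(families: list[OrthologFamily],
                   annotations: dict[tuple[str, str], str],
                   unit_name: str,
                   categories: list[str] | None = None) -> CogProfileMatrix:
    """Tally a family set (e.g. core or pan-genome) as one unit, counting one
    modal member label per family; unannotated families are skipped."""
    categories = categories or DEFAULT_CATEGORIES
    labels: list[str | None] = []
    for fam in families:
        fam_labels = [annotations[m] for m in fam.members if m in annotations]
        if not fam_labels:
            continue
        counts = Counter(fam_labels)
        top = max(counts.values())
        # modal label; ties broken alphabetically for determinism
        labels.append(min(c for c, n in counts.items() if n == top))
    df = pd.DataFrame.from_dict({unit_name: _tally(labels, categories)},
                                orient="index")[categories]
    return CogProfileMatrix(counts=df.astype(int))


def stack_profiles(*matrices: CogProfileMatrix) -> CogProfileMatrix:
    """Concatenate profile matrices sharing the same category set."""
    dfs = [m.counts for m in matrices]
    for df in dfs[1:]:
        if list(df.columns) != list(dfs[0].columns):
            raise ValueError("category sets differ")
    joined = pd.concat(dfs, axis=0)
    if joined.index.duplicated().any():
        dup = joined.index[joined.index.duplicated()].tolist()
        raise ValueError(f"duplicate unit names {dup}")
    return CogProfileMatrix(counts=joined)


def relative_profile(matrix: CogProfileMatrix) -> pd.DataFrame:
    """Counts divided by each unit's total assigned CDSs; rows sum to 1."""
    totals = matrix.assigned_totals
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"units with zero assigned genes: {zero}")
    return matrix.counts.div(totals, axis=0)


def fls_divergence(relative: pd.DataFrame,
                   fls_set: list[str]) -> DivergenceTable:
    """Per-category difference from the mean free-living relative frequency,
    in percentage points."""
    if not fls_set:
        raise ValueError("empty free-living reference set")
    missing = set(fls_set) - set(relative.index)
    if missing:
        raise KeyError(f"free-living units not in matrix: {sorted(missing)}")
    fls_mean = relative.loc[list(fls_set)].mean(axis=0)
    deltas = 100.0 * (relative - fls_mean)
    return DivergenceTable(deltas=deltas, fls_set=tuple(fls_set))


def categorize_retention(delta: float) -> str:
    """Six-level retained/reduced call from a percentage-point deviation.

    Thresholds at 0, +/-2 and +/-5 points; boundary values go to the
    higher-magnitude class, and 0 counts as moderately reduced.
    """
    if not isfinite(delta):
        raise ValueError(f"non-finite delta {delta!r}")
    if delta >= 5:
        return "extremely_retained"
    if delta >= 2:
        return "highly_retained"
    if delta > 0:
        return "moderately_retained"
    if delta > -2:
        return "moderately_reduced"
    if delta > -5:
        return "highly_reduced"
    return "extremely_reduced"


def ratio_table(relative: pd.DataFrame, numerator_unit: str,
                denominator: str | list[str]) -> dict[str, float | None]:
    """Per-category ratio of relative frequencies.

    ``denominator`` is a unit name or a list of units averaged first (e.g.
    the free-living mean). Categories with zero denominator frequency map
    to ``None`` (undefined)."""
    num = relative.loc[numerator_unit]
    if isinstance(denominator, str):
        den = relative.loc[denominator]
    else:
        den = relative.loc[list(denominator)].mean(axis=0)
    out: dict[str, float | None] = {}
    for c in relative.columns:
        out[c] = float(num[c] / den[c]) if den[c] > 0 else None
    return out


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis rank-sum test with tie correction.

    Returns (H, df, p) with df = number of groups - 1. The degenerate
    all-tied case (tie-correction denominator 0) is defined as H = 0,
    p = 1: no evidence against the null.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} has zero observations")
    df = len(groups) - 1
    flat = {v for g in groups for v in g}
    if len(flat) == 1:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def combine_profiles(matrix: CogProfileMatrix, a: str, b: str,
                     name: str | None = None) -> CogProfileMatrix:
    """Append the category-wise sum of two units as a new unit (e.g. a
    host-sharing endosymbiont consortium)."""
    for u in (a, b):
        if u not in matrix.counts.index:
            raise KeyError(f"unknown unit {u!r}")
    name = name or f"{a}+{b}"
    if name in matrix.counts.index:
        raise ValueError(f"unit name {name!r} already present")
    combined = matrix.counts.loc[a] + matrix.counts.loc[b]
    df = pd.concat([matrix.counts, combined.to_frame(name).T])
    return CogProfileMatrix(counts=df.astype(int))


@dataclass
class ClusterResult:
    """Two-way agglomerative clustering of a profile matrix."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_labels: list[str]  # original (pre-clustering) label order
    col_labels: list[str]
    reordered: pd.DataFrame


def _leaf_order(z: np.ndarray, labels: list[str]) -> list[str]:
    order = hierarchy.leaves_list(z)
    return [labels[i] for i in order]


def _linkage_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def fmt(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return "(" + ",".join(fmt(c) for c in (node.left, node.right)) + ")"

    return fmt(tree) + ";"


def hierarchical_cluster(profile: pd.DataFrame, metric: str = "euclidean",
                         linkage: str = "complete") -> ClusterResult:
    """Agglomerative clustering over rows and columns of a relative or
    divergence profile matrix (heatmap ordering)."""
    if profile.shape[0] < 2:
        raise ValueError("need at least 2 units to cluster")
    row_z = hierarchy.linkage(pdist(profile.values, metric=metric),
                              method=linkage)
    row_order = _leaf_order(row_z, list(profile.index))
    if profile.shape[1] >= 2:
        col_z = hierarchy.linkage(pdist(profile.values.T, metric=metric),
                                  method=linkage)
        col_order = _leaf_order(col_z, list(profile.columns))
    else:  # a single category cannot be clustered
        col_z = np.empty((0, 4))
        col_order = list(profile.columns)
    reordered = profile.loc[row_order, col_order]
    return ClusterResult(row_order=row_order, col_order=col_order,
                         row_linkage=row_z, col_linkage=col_z,
                         row_labels=list(profile.index),
                         col_labels=list(profile.columns),
                         reordered=reordered)


def nearest_unit(profile: pd.DataFrame, unit: str,
                 metric: str = "euclidean") -> str:
    """The unit closest to ``unit`` in profile space (heatmap neighbour)."""
    d = pdist(profile.values, metric=metric)
    dm = pd.DataFrame(squareform(d), index=profile.index,
                      columns=profile.index)
    row = dm.loc[unit].drop(unit)
    return str(row.idxmin())


def cluster_newick(result: ClusterResult, axis: str = "row") -> str:
    """Newick-like nested string of a clustering axis."""
    if axis == "row":
        return _linkage_newick(result.row_linkage, result.row_labels)
    return _linkage_newick(result.col_linkage, result.col_labels)
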