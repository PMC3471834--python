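"""Pan-genome partitioning into strain-subset subspaces.

The pan-genome is the full family set — clustered ortholog families plus
per-gene singletons — and every family is assigned to exactly one subspace:
the subset of strains represented among its members (the data behind an
Euler diagram). The core is the full-strain-set subspace; strain-specific
families are the single-strain subspaces. Singletons are first-class
pan-genome members, so summary fractions use clustered + singleton counts
as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .orthology import OrthologFamily

__all__ = ["PanGenomePartition", "partition", "core_fraction",
           "subspace_fraction", "subspace_query", "strain_specific"]


@dataclass
class PanGenomePartition:
    """Family counts and memberships per non-empty strain subset."""

    strains: tuple[str, ...]
    subspace_counts: dict[frozenset[str], int] = field(default_factory=dict)
    subspace_members: dict[frozenset[str], list[str]] = field(
        default_factory=dict)

    @property
    def total_families(self) -> int:
        return sum(self.subspace_counts.values())

    @property
    def core_count(self) -> int:
        return self.subspace_counts.get(frozenset(self.strains), 0)

    def _check_strains(self, subset: frozenset[str]) -> None:
        unknown = subset - set(self.strains)
        if unknown:
            raise KeyError(f"unknown strains {sorted(unknown)}")

    def mask(self, subset: frozenset[str]) -> int:
        """Binary mask of a subset in canonical strain order (bit i = strain i)."""
        return sum(1 << i for i, s in enumerate(self.strains) if s in subset)

    def sorted_subsets(self) -> list[frozenset[str]]:
        return sorted(self.subspace_counts, key=self.mask)


def partition(families: list[OrthologFamily],
              singletons: list[tuple[str, str]],
              strains: list[str]) -> PanGenomePartition:
    """Assign every family (and singleton gene) to its strain-subset subspace."""
    known = set(strains)
    part = PanGenomePartition(strains=tuple(strains))

    def add(subset: frozenset[str], family_id: str) -> None:
        part.subspace_counts[subset] = part.subspace_counts.get(subset, 0) + 1
        part.subspace_members.setdefault(subset, []).append(family_id)

    for fam in families:
        subset = fam.strains()
        unknown = subset - known
        if unknown:
            raise KeyError(f"family {fam.family_id} contains unknown strains "
                           f"{sorted(unknown)}")
        add(subset, fam.family_id)
    for strain, gene_id in singletons:
        if strain not in known:
            raise KeyError(f"singleton {strain}|{gene_id} has unknown strain")
        add(frozenset([strain]), f"SINGLETON:{strain}|{gene_id}")
    return part


def core_fraction(part: PanGenomePartition) -> float:
    """Core families as a percentage of the pan-genome, to 2 decimals."""
    if part.total_families == 0:
        raise ValueError("empty partition")
    return round(100.0 * part.core_count / part.total_families, 2)


def subspace_fraction(part: PanGenomePartition, required: set[str]) -> float:
    """Percentage of families whose strain set contains all of ``required``."""
    if not required:
        raise ValueError("required strain set must be non-empty")
    req = frozenset(required)
    part._check_strains(req)
    if part.total_families == 0:
        raise ValueError("empty partition")
    count = sum(c for subset, c in part.subspace_counts.items()
                if req <= subset)
    return round(100.0 * count / part.total_families, 2)


def subspace_query(part: PanGenomePartition, include: set[str],
                   exclude: set[str]) -> list[str]:
    """Families present in every ``include`` strain and absent from every
    ``exclude`` strain."""
    if not include:
        raise ValueError("include set must be non-empty")
    inc, exc = frozenset(include), frozenset(exclude)
    if inc & exc:
        raise ValueError(f"include and exclude overlap: {sorted(inc & exc)}")
    part._check_strains(inc | exc)
    out: list[str] = []
    for subset in part.sorted_subsets():
        if inc <= subset and not (exc & subset):
            out.extend(part.subspace_members[subset])
    return out


def strain_specific(part: PanGenomePartition, strain: str) -> list[str]:
    """Families (including singletons) found in exactly this strain."""
    part._check_strains(frozenset([strain]))
    return list(part.subspace_members.get(frozenset([strain]), []))
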