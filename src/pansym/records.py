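"""Core domain records shared across the pipeline.

A genome here is a set of annotated protein-coding genes (CDSs): each gene
carries its strain, replicon coordinates, strand, an optional single-letter
COG functional category, and its amino-acid sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AA_ALPHABET + "X")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS.

    Coordinates are 1-based inclusive; strand is '+' or '-'; ``cog`` is a
    single COG category letter or ``None`` for unassigned genes.
    """

    strain: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cog: str | None
    sequence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.strain}|{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.strain}|{self.gene_id}: invalid strand {self.strand!r}"
            )
        if not self.sequence:
            raise ValueError(f"gene {self.strain}|{self.gene_id}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"gene {self.strain}|{self.gene_id}: invalid residues {sorted(bad)}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.strain, self.gene_id)

    @property
    def label(self) -> str:
        return f"{self.strain}|{self.gene_id}"


@dataclass
class GenomeCollection:
    """All genes of a strain set, in gene-table order."""

    strains: list[str]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for g in self.genes:
            if g.key in seen:
                raise ValueError(f"duplicate gene {g.label}")
            seen.add(g.key)

    def by_strain(self, strain: str) -> list[GeneRecord]:
        if strain not in self.strains:
            raise KeyError(f"unknown strain {strain!r}")
        return [g for g in self.genes if g.strain == strain]

    def gene_map(self) -> dict[tuple[str, str], GeneRecord]:
        return {g.key: g for g in self.genes}

    def annotations(self) -> dict[tuple[str, str], str]:
        """COG annotation map over assigned genes only."""
        return {g.key: g.cog for g in self.genes if g.cog is not None}

    def __len__(self) -> int:
        return len(self.genes)
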