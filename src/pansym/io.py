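"""Readers and writers for the interchange formats.

All tables are UTF-8, tab-separated, LF-terminated, with ``#`` comment
lines; coordinates are 1-based inclusive; strands are +/-; an unassigned
COG category is written as ``.``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import GeneRecord, GenomeCollection

GENE_TABLE_COLUMNS = ["strain", "gene_id", "contig", "start", "end",
                      "strand", "cog_category"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA id -> uppercased sequence, preserving input order."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_gene_table(path: str | Path,
                    sequences: dict[str, str] | None = None,
                    ) -> list[GeneRecord]:
    """Parse a gene table TSV into records; malformed rows error with their
    line number. ``sequences`` maps ``strain|gene_id`` to protein sequence
    (records get a placeholder residue if omitted)."""
    records: list[GeneRecord] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != GENE_TABLE_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: bad header {header}, expected "
                        f"{GENE_TABLE_COLUMNS}")
                continue
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(GENE_TABLE_COLUMNS)} fields, got "
                                 f"{len(fields)}")
            strain, gene_id, contig, start, end, strand, cog = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer "
                                 f"coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand "
                                 f"{strand!r}")
            if start_i < 1 or start_i > end_i:
                raise ValueError(f"{path}:{lineno}: invalid coordinates "
                                 f"{start_i}..{end_i}")
            label = f"{strain}|{gene_id}"
            seq = sequences.get(label, "X") if sequences else "X"
            records.append(GeneRecord(
                strain=strain, gene_id=gene_id, contig=contig,
                start=start_i, end=end_i, strand=strand,
                cog=None if cog in (".", "") else cog, sequence=seq))
    if header is None:
        raise ValueError(f"{path}: empty gene table (missing header)")
    return records


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            cog = g.cog if g.cog is not None else "."
            fh.write(f"{g.strain}\t{g.gene_id}\t{g.contig}\t{g.start}\t"
                     f"{g.end}\t{g.strand}\t{cog}\n")


def read_collection(directory: str | Path) -> GenomeCollection:
    """Read a fixture directory (per-strain FASTA + genes.tsv) back into a
    collection; inverse of :func:`pansym.synthdata.write_fixture`."""
    directory = Path(directory)
    sequences: dict[str, str] = {}
    fasta_strains: set[str] = set()
    for fasta in sorted(directory.glob("*.faa")):
        fasta_strains.add(fasta.stem)
        for label, seq in read_fasta(fasta).items():
            if label in sequences:
                raise ValueError(f"duplicate gene label {label}")
            sequences[label] = seq
    genes = read_gene_table(directory / "genes.tsv", sequences=sequences)
    # strain order follows first appearance in the gene table
    strains: list[str] = []
    for g in genes:
        if g.strain not in strains:
            strains.append(g.strain)
    unknown = set(strains) - fasta_strains
    if unknown:
        raise ValueError(f"gene table references strains without FASTA: "
                         f"{sorted(unknown)}")
    order = {s: i for i, s in enumerate(strains)}
    genes.sort(key=lambda g: (order[g.strain], g.start))
    return GenomeCollection(strains=strains, genes=genes)


def read_annotation(path: str | Path) -> dict[tuple[str, str], str]:
    """COG annotation TSV -> (strain, gene_id) -> category letter."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = ["strain", "gene_id", "cog_category"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: bad header {list(df.columns)}, "
                         f"expected {expected}")
    return {(r.strain, r.gene_id): r.cog_category
            for r in df.itertuples(index=False)}


def write_clusters(families, singletons, directory: str | Path) -> None:
    directory = Path(directory)
    with open(directory / "clusters.tsv", "w") as fh:
        fh.write("family_id\tstrain\tgene_id\n")
        for fam in families:
            for strain, gene_id in fam.members:
                fh.write(f"{fam.family_id}\t{strain}\t{gene_id}\n")
    with open(directory / "singletons.tsv", "w") as fh:
        fh.write("strain\tgene_id\n")
        for strain, gene_id in singletons:
            fh.write(f"{strain}\t{gene_id}\n")


def write_partition(part, directory: str | Path) -> None:
    directory = Path(directory)
    with open(directory / "subspaces.tsv", "w") as fh:
        fh.write("mask\tstrains\tcount\n")
        for subset in part.sorted_subsets():
            names = ",".join(s for s in part.strains if s in subset)
            fh.write(f"{part.mask(subset)}\t{names}\t"
                     f"{part.subspace_counts[subset]}\n")
    with open(directory / "subspace_members.tsv", "w") as fh:
        fh.write("mask\tfamily_id\n")
        for subset in part.sorted_subsets():
            for fam_id in part.subspace_members.get(subset, []):
                fh.write(f"{part.mask(subset)}\t{fam_id}\n")
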