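"""Synthetic clades of free-living and endosymbiotic bacterial genomes.

Generates a small clade (by default three free-living strains, two
endosymbionts and an outgroup) with known ground truth: ortholog families
with lifestyle-dependent presence/absence (a large shared core, an accessory
set shared by the free-living strains, strain-specific tails), single-letter
COG functional labels whose retention in endosymbionts is biased per
category, gap-free protein sequences evolved by per-branch Poisson
substitution, and single-copy-core gene orders shuffled by a recorded number
of signed inversions per branch.

The generator emulates the statistical structure of a five-strain clade in
which two lineages underwent genome reduction of very different depth: a
facultative endosymbiont retaining most of the ancestral core, and an
obligate one whose gene content has collapsed close to the core itself,
with one accelerated sequence branch and heavy gene-order scrambling on the
endosymbiotic branches while the free-living strains keep perfect synteny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .records import AA_ALPHABET, GeneRecord, GenomeCollection

COG_CATEGORIES = list("JKLDVTMNUOCGEFHIPQRS")

# A generic gammaproteobacterial COG-category composition (fractions of
# COG-assigned CDSs); sums to 1.
DEFAULT_COG_PROFILE: dict[str, float] = {
    "J": 0.06, "K": 0.07, "L": 0.06, "D": 0.01, "V": 0.015,
    "T": 0.05, "M": 0.06, "N": 0.03, "U": 0.015, "O": 0.04,
    "C": 0.06, "G": 0.08, "E": 0.09, "F": 0.02, "H": 0.04,
    "I": 0.03, "P": 0.06, "Q": 0.02, "R": 0.09, "S": 0.10,
}

# Per-category retention bias of an obligate endosymbiont relative to its
# free-living relatives: information processing (J), chaperones (O),
# nucleotide (F), coenzyme (H), envelope (M), replication (L), secretion (U)
# and cell cycle (D) enriched; regulation (K), signal transduction (T) and
# motility (N) heavily depleted.
OBLIGATE_RETENTION_MULTIPLIERS: dict[str, float] = {
    "J": 4.14, "O": 1.65, "F": 2.03, "H": 2.14, "M": 1.67, "L": 1.78,
    "U": 2.36, "D": 2.41, "I": 1.30, "V": 0.72, "Q": 0.58, "C": 0.78,
    "P": 0.74, "T": 0.36, "N": 0.40, "R": 0.62, "S": 0.50, "G": 0.57,
    "E": 0.52, "K": 0.27,
}


class TreeNode:
    """Minimal rooted tree node; ``length`` is the branch above the node."""

    def __init__(self, name: str, children: list["TreeNode"] | None = None,
                 length: float = 0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def preorder(self) -> list["TreeNode"]:
        out = [self]
        for c in self.children:
            out.extend(c.preorder())
        return out

    def newick(self, with_lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                s = node.name
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.name
            if with_lengths and node.length:
                s += f":{node.length:g}"
            return s

        return fmt(self) + ";"


def default_topology(fls: list[str], endos: list[str],
                     outgroup: str | None) -> TreeNode:
    """Fixed clade topology: ((endo1,endo2),fl1) vs (fl2,fl3), outgroup basal.

    Generalizes to other strain counts by caterpillar nesting.
    """
    def caterpillar(names: list[str], prefix: str) -> TreeNode:
        node = TreeNode(names[0])
        for i, nm in enumerate(names[1:], start=1):
            node = TreeNode(f"{prefix}{i}", [node, TreeNode(nm)])
        return node

    if endos:
        sym = caterpillar(endos, "SYM") if len(endos) > 1 else TreeNode(endos[0])
        if len(endos) == 2:
            sym.name = "SYM"
        ingroup = TreeNode("SYMFL", [sym, TreeNode(fls[0])])
        rest = fls[1:]
        if len(rest) == 1:
            ingroup = TreeNode("ING", [ingroup, TreeNode(rest[0])])
        elif len(rest) >= 2:
            flc = caterpillar(rest, "FLC")
            flc.name = "FLC"
            ingroup = TreeNode("ING", [ingroup, flc])
    else:
        ingroup = caterpillar(fls, "FLINT")
    if outgroup is not None:
        return TreeNode("ROOT", [ingroup, TreeNode(outgroup)])
    ingroup.name = "ROOT"
    return ingroup


@dataclass
class SimConfig:
    """Parameters of one synthetic clade.

    ``branch_subst_rates`` and ``branch_inversion_counts`` are keyed by node
    name (the branch above that node); names are the strain names plus the
    internal labels of :func:`default_topology` (SYM, SYMFL, FLC, ING).
    ``retention_fractions`` gives, per endosymbiont, the expected fraction of
    non-single-copy core families it keeps; keeping is biased per COG
    category by ``retention_multipliers``.
    """

    n_free_living: int = 3
    n_endosymbiont: int = 2
    include_outgroup: bool = True
    n_core_families: int = 300
    n_fls_accessory: int = 150
    strain_specific_counts: tuple[int, ...] | None = None
    n_single_copy_core: int = 60
    cog_base_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COG_PROFILE))
    retention_multipliers: dict[str, dict[str, float]] | None = None
    retention_fractions: tuple[float, ...] | None = None
    branch_subst_rates: dict[str, float] | None = None
    branch_inversion_counts: dict[str, int] | None = None
    protein_length: int = 100
    duplication_rate: float = 0.03
    unassigned_cog_rate: float = 0.10
    seed: int = 0

    # -- derived naming -----------------------------------------------------
    @property
    def fls_strains(self) -> list[str]:
        return [f"FL{i+1}" for i in range(self.n_free_living)]

    @property
    def endo_strains(self) -> list[str]:
        return [f"ES{i+1}" for i in range(self.n_endosymbiont)]

    @property
    def outgroup(self) -> str | None:
        return "OUT" if self.include_outgroup else None

    @property
    def clade_strains(self) -> list[str]:
        return self.fls_strains + self.endo_strains

    @property
    def all_strains(self) -> list[str]:
        return self.clade_strains + ([self.outgroup] if self.outgroup else [])

    def tree(self) -> TreeNode:
        return default_topology(self.fls_strains, self.endo_strains,
                                self.outgroup)

    def resolved(self) -> "SimConfig":
        """Fill derived defaults and validate; returns self."""
        if self.n_free_living < 1:
            raise ValueError("need at least one free-living strain")
        if self.strain_specific_counts is None:
            counts = [50] * self.n_free_living
            if self.n_endosymbiont:
                # facultative-like endosymbionts keep a specific tail, the
                # last (obligate-like) one is down to a single specific gene
                counts += [52] * (self.n_endosymbiont - 1) + [1]
            self.strain_specific_counts = tuple(counts)
        if self.retention_fractions is None:
            fr = [0.75] * max(0, self.n_endosymbiont - 1) + (
                [0.35] if self.n_endosymbiont else [])
            self.retention_fractions = tuple(fr)
        if self.retention_multipliers is None:
            mult: dict[str, dict[str, float]] = {}
            for i, s in enumerate(self.endo_strains):
                base = OBLIGATE_RETENTION_MULTIPLIERS
                if i < self.n_endosymbiont - 1:
                    mult[s] = {c: float(np.sqrt(v)) for c, v in base.items()}
                else:
                    mult[s] = dict(base)
            self.retention_multipliers = mult
        names = [n.name for n in self.tree().preorder()]
        if self.branch_subst_rates is None:
            rates = {n: 0.02 for n in names if n != "ROOT"}
            for s in self.endo_strains[:-1]:
                rates[s] = 0.03
            if self.endo_strains:
                rates[self.endo_strains[-1]] = 0.12  # accelerated branch
            if self.outgroup:
                rates[self.outgroup] = 0.08
            self.branch_subst_rates = rates
        if self.branch_inversion_counts is None:
            inv = {n: 0 for n in names if n != "ROOT"}
            # sparse-inversion regime: total applied inversions stay below
            # n_single_copy_core / 4 so the rearrangement signal remains
            # identifiable; scrambling is confined to endosymbiotic branches
            if self.n_endosymbiont >= 1:
                inv[self.endo_strains[0]] = 6
            if self.n_endosymbiont >= 2:
                inv[self.endo_strains[-1]] = 5
                inv["SYM"] = 3
            self.branch_inversion_counts = inv
        self.validate()
        return self

    def validate(self) -> None:
        total = sum(self.cog_base_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cog_base_profile sums to {total}, expected 1")
        for nm, v in [("n_free_living", self.n_free_living),
                      ("n_endosymbiont", self.n_endosymbiont),
                      ("n_core_families", self.n_core_families),
                      ("n_fls_accessory", self.n_fls_accessory),
                      ("n_single_copy_core", self.n_single_copy_core),
                      ("protein_length", self.protein_length)]:
            if v < 0:
                raise ValueError(f"{nm} must be non-negative, got {v}")
        if self.n_free_living < 1:
            raise ValueError("need at least one free-living strain")
        if self.n_single_copy_core > self.n_core_families:
            raise ValueError("n_single_copy_core exceeds n_core_families")
        if self.n_endosymbiont and self.n_single_copy_core < 1:
            raise ValueError(
                "an endosymbiont would retain zero single-copy-core genes")
        if len(self.strain_specific_counts) != len(self.clade_strains):
            raise ValueError("strain_specific_counts length must equal the "
                             "number of clade strains")
        if any(c < 0 for c in self.strain_specific_counts):
            raise ValueError("strain-specific counts must be non-negative")
        if len(self.retention_fractions) != self.n_endosymbiont:
            raise ValueError("one retention fraction per endosymbiont")
        for s in self.endo_strains:
            mult = self.retention_multipliers.get(s)
            if not mult or any(m <= 0 for m in mult.values()):
                raise ValueError(f"positive retention multipliers required "
                                 f"for {s}")
        names = {n.name for n in self.tree().preorder()} - {"ROOT"}
        for d, what in [(self.branch_subst_rates, "substitution rate"),
                        (self.branch_inversion_counts, "inversion count")]:
            missing = names - set(d)
            if missing:
                raise ValueError(f"missing {what} for branches {sorted(missing)}")
        if any(r < 0 for r in self.branch_subst_rates.values()):
            raise ValueError("substitution rates must be non-negative")
        if any(k < 0 for k in self.branch_inversion_counts.values()):
            raise ValueError("inversion counts must be non-negative")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated collection."""

    true_families: dict[str, list[tuple[str, str]]]
    true_tree: str
    applied_inversions: dict[str, list[tuple[int, int]]]
    true_category_deltas: dict[str, dict[str, float]]
    scc_families: list[str]
    leaf_orders: dict[str, list[int]]
    fls_strains: list[str]
    endo_strains: list[str]
    outgroup: str | None


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Poisson substitutions: each event replaces a uniform site with a
    uniform choice among the 19 alternative residues (multiple hits allowed)."""
    out = seq.copy()
    n_events = rng.poisson(rate * len(seq))
    for _ in range(n_events):
        pos = int(rng.integers(0, len(seq)))
        out[pos] = (out[pos] + rng.integers(1, 20)) % 20
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in seq)


def _apply_inversion(order: list[int], i: int, j: int) -> list[int]:
    """Reverse segment [i..j] (1-based inclusive) and flip its signs."""
    a = i - 1
    return order[:a] + [-x for x in reversed(order[a:j])] + order[j:]


def simulate_clade(config: SimConfig) -> tuple[GenomeCollection, TruthRecord]:
    """Simulate one clade; deterministic given ``config.seed``."""
    cfg = config.resolved()
    seed = cfg.seed
    rng_fam = np.random.default_rng([seed, 1])
    rng_seq = np.random.default_rng([seed, 2])
    rng_ord = np.random.default_rng([seed, 3])
    rng_tab = np.random.default_rng([seed, 4])
    rng_ret = np.random.default_rng([seed, 5])

    tree = cfg.tree()
    for node in tree.preorder():
        if node.name != "ROOT":
            node.length = cfg.branch_subst_rates[node.name]

    cats = list(cfg.cog_base_profile)
    probs = np.array([cfg.cog_base_profile[c] for c in cats])
    probs = probs / probs.sum()

    def sample_category() -> str | None:
        if rng_fam.random() < cfg.unassigned_cog_rate:
            return None
        return cats[rng_fam.choice(len(cats), p=probs)]

    # ---- family roster ----------------------------------------------------
    families: list[dict] = []  # family: {id, category, members: set of strains}
    fam_serial = 0

    def new_family(category: str | None, members: list[str], kind: str) -> dict:
        nonlocal fam_serial
        fam_serial += 1
        fam = {"id": f"F{fam_serial:05d}", "category": category,
               "members": list(members), "kind": kind}
        families.append(fam)
        return fam

    scc_ids: list[str] = []
    for _ in range(cfg.n_single_copy_core):
        fam = new_family(sample_category(), cfg.all_strains, "scc")
        scc_ids.append(fam["id"])

    # expected multiplier under the base profile, per endosymbiont, so that
    # the average keep probability equals the retention fraction
    mbar = {s: float(sum(cfg.cog_base_profile[c] *
                         cfg.retention_multipliers[s].get(c, 1.0)
                         for c in cats))
            for s in cfg.endo_strains}

    for _ in range(cfg.n_core_families - cfg.n_single_copy_core):
        cat = sample_category()
        members = list(cfg.fls_strains)
        if cfg.outgroup:
            members.append(cfg.outgroup)
        for frac, s in zip(cfg.retention_fractions, cfg.endo_strains):
            m = cfg.retention_multipliers[s].get(cat, 1.0) if cat else 1.0
            p = min(1.0, frac * m / mbar[s])
            if rng_ret.random() < p:
                members.append(s)
        new_family(cat, members, "core")

    for _ in range(cfg.n_fls_accessory):
        new_family(sample_category(), list(cfg.fls_strains), "fls_accessory")

    for strain, count in zip(cfg.clade_strains, cfg.strain_specific_counts):
        for _ in range(count):
            new_family(sample_category(), [strain], "specific")

    # ---- sequences --------------------------------------------------------
    leaf_names = {leaf.name for leaf in tree.leaves()}
    fam_seqs: dict[str, dict[str, np.ndarray]] = {}
    for fam in families:
        members = set(fam["members"])
        if fam["kind"] == "specific":
            strain = fam["members"][0]
            fam_seqs[fam["id"]] = {strain: _random_seq(rng_seq,
                                                       cfg.protein_length)}
            continue
        root = _random_seq(rng_seq, cfg.protein_length)
        seqs: dict[str, np.ndarray] = {}

        def walk(node: TreeNode, seq: np.ndarray) -> None:
            cur = seq if node.name == "ROOT" else _mutate(rng_seq, seq,
                                                          node.length)
            if node.is_leaf():
                if node.name in members:
                    seqs[node.name] = cur
            else:
                for child in node.children:
                    walk(child, cur)

        walk(tree, root)
        # members not on the tree (defensive; all strains are leaves)
        assert members <= leaf_names
        fam_seqs[fam["id"]] = seqs

    # ---- duplications (free-living strains, non-single-copy families) -----
    duplicates: dict[str, list[str]] = {s: [] for s in cfg.all_strains}
    for fam in families:
        if fam["kind"] not in ("core", "fls_accessory"):
            continue
        for s in cfg.fls_strains:
            if s in fam["members"] and rng_tab.random() < cfg.duplication_rate:
                duplicates[s].append(fam["id"])

    # ---- single-copy-core gene orders -------------------------------------
    n = cfg.n_single_copy_core
    applied: dict[str, list[tuple[int, int]]] = {}
    leaf_orders: dict[str, list[int]] = {}

    def walk_orders(node: TreeNode, order: list[int]) -> None:
        cur = list(order)
        if node.name != "ROOT":
            segs: list[tuple[int, int]] = []
            for _ in range(cfg.branch_inversion_counts[node.name]):
                i = int(rng_ord.integers(1, n + 1))
                j = int(rng_ord.integers(1, n + 1))
                i, j = min(i, j), max(i, j)
                segs.append((i, j))
                cur = _apply_inversion(cur, i, j)
            applied[node.name] = segs
        if node.is_leaf():
            leaf_orders[node.name] = cur
        else:
            for child in node.children:
                walk_orders(child, cur)

    if n > 0:
        walk_orders(tree, list(range(1, n + 1)))
    else:
        for leaf in tree.leaves():
            leaf_orders[leaf.name] = []
            applied[leaf.name] = []

    # ---- gene tables -------------------------------------------------------
    fam_by_id = {f["id"]: f for f in families}
    true_families: dict[str, list[tuple[str, str]]] = {f["id"]: []
                                                       for f in families}
    genes: list[GeneRecord] = []
    gene_nt = 3 * cfg.protein_length
    gap = 100

    # Shared (multi-strain) non-single-copy families anchor once to an
    # ancestral slot: they sit immediately after one single-copy-core gene
    # and ride along with it through inversions (physical linkage), so
    # their positions stay mutually consistent across strains. Families
    # private to one strain are interleaved at random slots instead.
    flip = {"+": "-", "-": "+"}
    anchored: dict[int, list[tuple[str, str]]] = {}  # scc rank -> satellites
    for fam in families:
        if fam["kind"] in ("core", "fls_accessory") and n > 0:
            anchor = int(rng_tab.integers(1, n + 1))
            strand = "+" if rng_tab.random() < 0.5 else "-"
            anchored.setdefault(anchor, []).append((fam["id"], strand))

    for strain in cfg.all_strains:
        entries: list[tuple[str, str, bool]] = []  # (family_id, strand, is_dup)
        member_fams = {f["id"] for f in families if strain in f["members"]}
        for v in leaf_orders[strain]:
            rank = abs(v)
            fam_id = scc_ids[rank - 1]
            sats = [(fid, st) for fid, st in anchored.get(rank, [])
                    if fid in member_fams]
            if v > 0:
                entries.append((fam_id, "+", False))
                entries.extend((fid, st, False) for fid, st in sats)
            else:
                entries.extend((fid, flip[st], False)
                               for fid, st in reversed(sats))
                entries.append((fam_id, "-", False))
        extras: list[tuple[str, str, bool]] = []
        if n == 0:  # no backbone: everything is interleaved at random
            for fam in families:
                if fam["kind"] != "scc" and strain in fam["members"]:
                    strand = "+" if rng_tab.random() < 0.5 else "-"
                    extras.append((fam["id"], strand, False))
        for fam in families:
            if fam["kind"] == "specific" and fam["members"] == [strain] \
                    and n > 0:
                strand = "+" if rng_tab.random() < 0.5 else "-"
                extras.append((fam["id"], strand, False))
        for fam_id in duplicates[strain]:
            strand = "+" if rng_tab.random() < 0.5 else "-"
            extras.append((fam_id, strand, True))
        for item in extras:
            slot = int(rng_tab.integers(0, len(entries) + 1))
            entries.insert(slot, item)
        for idx, (fam_id, strand, is_dup) in enumerate(entries):
            gene_id = f"g{idx+1:05d}"
            start = 1 + idx * (gene_nt + gap)
            fam = fam_by_id[fam_id]
            base = fam_seqs[fam_id][strain]
            seq = _mutate(rng_seq, base, 0.01) if is_dup else base
            genes.append(GeneRecord(strain=strain, gene_id=gene_id,
                                    contig="chr1", start=start,
                                    end=start + gene_nt - 1, strand=strand,
                                    cog=fam["category"], sequence=_decode(seq)))
            true_families[fam_id].append((strain, gene_id))

    collection = GenomeCollection(strains=list(cfg.all_strains), genes=genes)

    # ---- realized per-category divergence from the free-living average ----
    counts: dict[str, dict[str, int]] = {
        s: {c: 0 for c in cats} for s in cfg.clade_strains}
    for g in genes:
        if g.strain in counts and g.cog is not None:
            counts[g.strain][g.cog] += 1
    rel = {}
    for s, row in counts.items():
        tot = sum(row.values())
        rel[s] = {c: (row[c] / tot if tot else 0.0) for c in cats}
    fls_mean = {c: float(np.mean([rel[s][c] for s in cfg.fls_strains]))
                for c in cats}
    deltas = {s: {c: 100.0 * (rel[s][c] - fls_mean[c]) for c in cats}
              for s in cfg.clade_strains}

    truth = TruthRecord(
        true_families={fid: members for fid, members in true_families.items()},
        true_tree=tree.newick(),
        applied_inversions=applied,
        true_category_deltas=deltas,
        scc_families=scc_ids,
        leaf_orders=leaf_orders,
        fls_strains=cfg.fls_strains,
        endo_strains=cfg.endo_strains,
        outgroup=cfg.outgroup,
    )
    return collection, truth


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixture(collection: GenomeCollection, truth: TruthRecord | None,
                  directory: str | Path, config: SimConfig | None = None,
                  force: bool = False) -> list[Path]:
    """Write a collection (and optional truth/config) as plain-text files.

    Emits one protein FASTA per strain (header ``strain|gene_id``), a gene
    table TSV, a COG annotation TSV, ``truth.json`` and ``config.yaml``.
    Refuses to overwrite an existing non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} exists and is not empty; "
                              "pass force=True to overwrite")
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for strain in collection.strains:
        path = directory / f"{strain}.faa"
        with open(path, "w") as fh:
            for g in collection.by_strain(strain):
                fh.write(f">{g.strain}|{g.gene_id}\n{g.sequence}\n")
        written.append(path)

    gt = directory / "genes.tsv"
    with open(gt, "w") as fh:
        fh.write("strain\tgene_id\tcontig\tstart\tend\tstrand\tcog_category\n")
        for g in collection.genes:
            cog = g.cog if g.cog is not None else "."
            fh.write(f"{g.strain}\t{g.gene_id}\t{g.contig}\t{g.start}\t"
                     f"{g.end}\t{g.strand}\t{cog}\n")
    written.append(gt)

    ann = directory / "annotation.tsv"
    with open(ann, "w") as fh:
        fh.write("strain\tgene_id\tcog_category\n")
        for g in collection.genes:
            if g.cog is not None:
                fh.write(f"{g.strain}\t{g.gene_id}\t{g.cog}\n")
    written.append(ann)

    if truth is not None:
        tj = directory / "truth.json"
        payload = {
            "true_families": {k: [list(m) for m in v]
                              for k, v in truth.true_families.items()},
            "true_tree": truth.true_tree,
            "applied_inversions": {k: [list(s) for s in v]
                                   for k, v in truth.applied_inversions.items()},
            "true_category_deltas": truth.true_category_deltas,
            "scc_families": truth.scc_families,
            "leaf_orders": truth.leaf_orders,
            "fls_strains": truth.fls_strains,
            "endo_strains": truth.endo_strains,
            "outgroup": truth.outgroup,
        }
        tj.write_text(json.dumps(payload, indent=1))
        written.append(tj)

    if config is not None:
        cy = directory / "config.yaml"
        cy.write_text(yaml.safe_dump(asdict(config), sort_keys=False))
        written.append(cy)
    return written


def read_truth(path: str | Path) -> TruthRecord:
    payload = json.loads(Path(path).read_text())
    return TruthRecord(
        true_families={k: [tuple(m) for m in v]
                       for k, v in payload["true_families"].items()},
        true_tree=payload["true_tree"],
        applied_inversions={k: [tuple(s) for s in v]
                            for k, v in payload["applied_inversions"].items()},
        true_category_deltas=payload["true_category_deltas"],
        scc_families=payload["scc_families"],
        leaf_orders=payload["leaf_orders"],
        fls_strains=payload["fls_strains"],
        endo_strains=payload["endo_strains"],
        outgroup=payload["outgroup"],
    )
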