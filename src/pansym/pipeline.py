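"""End-to-end pipeline: simulate/ingest -> orthology -> pan-genome ->
functional profiles -> phylogeny -> rearrangements -> report."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from . import cogprofiles as cp
from . import io as pio
from . import orthology, pangenome, phylogeny, rearrange
from .evaluation import adjusted_rand_index, families_to_labels
from .orthology import OrthologFamily
from .records import GenomeCollection
from .synthdata import SimConfig, TruthRecord, simulate_clade, write_fixture


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``simulation`` (a :class:`SimConfig`) or ``input_dir`` (a fixture
    directory with per-strain FASTA, genes.tsv and annotation.tsv) provides
    the data. Strain roles drive the divergence reference (free-living set)
    and rooting (outgroup).
    """

    outdir: str = "pansym_out"
    seed: int = 0
    simulation: SimConfig | None = None
    input_dir: str | None = None
    free_living: list[str] = field(default_factory=list)
    endosymbionts: list[str] = field(default_factory=list)
    outgroup: str | None = None
    stages: list[str] = field(default_factory=lambda: [
        "orthology", "pangenome", "cogprofiles", "phylogeny", "rearrange"])
    # orthology parameters: k-mer size, Jaccard and coverage thresholds,
    # MCL inflation
    k: int = 3
    min_score: float = 0.10
    min_coverage: float = 0.35
    inflation: float = 1.5
    bootstrap_replicates: int = 100
    cluster_metric: str = "euclidean"
    cluster_linkage: str = "complete"

    def resolved(self) -> "PipelineConfig":
        if self.simulation is None and self.input_dir is None:
            self.simulation = SimConfig(seed=self.seed)
        if self.simulation is not None:
            sim = self.simulation.resolved()
            self.free_living = self.free_living or sim.fls_strains
            self.endosymbionts = self.endosymbionts or sim.endo_strains
            self.outgroup = self.outgroup or sim.outgroup
        return self


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "config": self.config,
                           "timings": self.timings, "stages": self.stages},
                          indent=1, sort_keys=True, default=str)


def _restrict_to_clade(families: list[OrthologFamily],
                       singletons: list[tuple[str, str]],
                       clade: set[str]) -> tuple[list[OrthologFamily],
                                                 list[tuple[str, str]]]:
    """Drop outgroup members: the pan-genome is defined over the clade."""
    fams: list[OrthologFamily] = []
    extra_singletons = list(s for s in singletons if s[0] in clade)
    for fam in families:
        members = tuple(m for m in fam.members if m[0] in clade)
        if len(members) >= 2:
            fams.append(OrthologFamily(fam.family_id, members))
        elif len(members) == 1:
            extra_singletons.append(members[0])
    return fams, sorted(extra_singletons)


def run_pipeline(config: PipelineConfig) -> RunReport:
    cfg = config.resolved()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(cfg), version=__version__)
    truth: TruthRecord | None = None

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                report.timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    # ---- data -------------------------------------------------------------
    with stage("data"):
        if cfg.simulation is not None:
            collection, truth = simulate_clade(cfg.simulation)
            write_fixture(collection, truth, outdir / "fixture",
                          config=cfg.simulation, force=True)
        else:
            collection = pio.read_collection(cfg.input_dir)
        clade = [s for s in collection.strains if s != cfg.outgroup]
        report.stages["data"] = {
            "strains": collection.strains,
            "n_genes": len(collection),
            "n_genes_per_strain": {s: len(collection.by_strain(s))
                                   for s in collection.strains},
        }

    annotations = collection.annotations()
    families: list[OrthologFamily] = []
    singletons: list[tuple[str, str]] = []

    if "orthology" in cfg.stages:
        with stage("orthology"):
            graph = orthology.build_similarity_graph(
                collection, k=cfg.k, min_score=cfg.min_score,
                min_coverage=cfg.min_coverage)
            families, singletons = orthology.mcl_cluster(
                graph, inflation=cfg.inflation)
            pio.write_clusters(families, singletons, outdir)
            consistency = orthology.cluster_consistency(families, annotations)
            assessable = [v for v in consistency.values() if v is not None]
            all_fams = families + [
                OrthologFamily(f"SG{i+1:05d}", (m,))
                for i, m in enumerate(singletons)]
            duplication = {s: round(orthology.duplication_level(all_fams, s), 2)
                           for s in collection.strains}
            summary = {
                "n_genes": len(collection),
                "n_families": len(families),
                "n_singletons": len(singletons),
                "clustered_genes": sum(len(f) for f in families),
                "mean_homogeneity": (round(sum(assessable) / len(assessable), 4)
                                     if assessable else None),
                "duplication_percent": duplication,
            }
            assert summary["clustered_genes"] + summary["n_singletons"] \
                == summary["n_genes"]
            if truth is not None:
                inferred = families_to_labels(families, singletons)
                true_labels = families_to_labels(
                    [(fid, members)
                     for fid, members in truth.true_families.items()])
                summary["ari_vs_truth"] = round(
                    adjusted_rand_index(inferred, true_labels), 4)
            report.stages["orthology"] = summary

    if "pangenome" in cfg.stages:
        with stage("pangenome"):
            clade_fams, clade_singl = _restrict_to_clade(
                families, singletons, set(clade))
            part = pangenome.partition(clade_fams, clade_singl, clade)
            pio.write_partition(part, outdir)
            summary = {
                "total_families": part.total_families,
                "core_count": part.core_count,
                "core_percent": pangenome.core_fraction(part),
                "strain_specific_counts": {
                    s: len(pangenome.strain_specific(part, s))
                    for s in clade},
            }
            if cfg.free_living:
                summary["fls_plus_core_percent"] = pangenome.subspace_fraction(
                    part, set(cfg.free_living))
            (outdir / "pangenome_summary.json").write_text(
                json.dumps(summary, indent=1))
            report.stages["pangenome"] = summary

    if "cogprofiles" in cfg.stages:
        with stage("cogprofiles"):
            clade_fams, clade_singl = _restrict_to_clade(
                families, singletons, set(clade))
            strain_mat = cp.strain_profiles(
                [g for g in collection.genes if g.strain in clade])
            all_fams = clade_fams + [
                OrthologFamily(f"SG{i+1:05d}", (m,))
                for i, m in enumerate(clade_singl)]
            core_fams = [f for f in clade_fams
                         if f.strains() == frozenset(clade)]
            core_mat = cp.family_profile(core_fams, annotations, "core")
            pan_mat = cp.family_profile(all_fams, annotations, "pan-genome")
            matrix = cp.stack_profiles(strain_mat, core_mat, pan_mat)
            rel = cp.relative_profile(matrix)
            rel.to_csv(outdir / "profiles_relative.tsv", sep="\t")
            matrix.counts.to_csv(outdir / "profiles_counts.tsv", sep="\t")
            div = cp.fls_divergence(rel, cfg.free_living)
            div.deltas.to_csv(outdir / "profiles_divergence.tsv", sep="\t")
            h_all, df_all, p_all = cp.kruskal_wallis(
                [list(matrix.counts.loc[u]) for u in matrix.units])
            h_fls, df_fls, p_fls = cp.kruskal_wallis(
                [list(matrix.counts.loc[u]) for u in cfg.free_living])
            retention = {}
            ratios = {}
            for endo in cfg.endosymbionts:
                calls = {c: cp.categorize_retention(div.deltas.loc[endo, c])
                         for c in div.deltas.columns}
                retention[endo] = calls
                ratios[endo] = cp.ratio_table(rel, endo, cfg.free_living)
            with open(outdir / "retention_calls.tsv", "w") as fh:
                fh.write("unit\tcategory\tdelta\tlabel\tratio_vs_fls\n")
                for endo, calls in retention.items():
                    for c, label in calls.items():
                        ratio = ratios[endo][c]
                        fh.write(f"{endo}\t{c}\t"
                                 f"{div.deltas.loc[endo, c]:.4f}\t{label}\t"
                                 f"{'' if ratio is None else round(ratio, 2)}\n")
            clust = cp.hierarchical_cluster(div.deltas,
                                            metric=cfg.cluster_metric,
                                            linkage=cfg.cluster_linkage)
            clust.reordered.to_csv(outdir / "profiles_heatmap.tsv", sep="\t")
            report.stages["cogprofiles"] = {
                "units": matrix.units,
                "kruskal_all": {"H": round(h_all, 4), "df": df_all,
                                "p": p_all},
                "kruskal_fls": {"H": round(h_fls, 4), "df": df_fls,
                                "p": p_fls},
                "retention_calls": retention,
                "row_order": clust.row_order,
                "dendrogram": cp.cluster_newick(clust, axis="row"),
            }

    scc: list[OrthologFamily] = []
    if "phylogeny" in cfg.stages:
        with stage("phylogeny"):
            scc = phylogeny.single_copy_core(
                families, collection.strains,
                require_outgroup=cfg.outgroup is not None,
                outgroup=cfg.outgroup)
            gene_map = collection.gene_map()
            fam_seqs = {
                f.family_id: {s: gene_map[(s, gid)].sequence
                              for s, gid in f.members}
                for f in scc}
            sm = phylogeny.concatenate(fam_seqs, collection.strains)
            dm = phylogeny.distance_matrix(sm)
            dm.to_csv(outdir / "distances.tsv", sep="\t")
            tree, support = phylogeny.bootstrap_support(
                sm, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed,
                outgroup=cfg.outgroup)
            newick = _newick_with_support(tree, support)
            (outdir / "tree.nwk").write_text(newick + "\n")
            terminal = {t.name: (t.length or 0.0) for t in tree.tips()
                        if t.name != cfg.outgroup}
            report.stages["phylogeny"] = {
                "n_single_copy_core": len(scc),
                "n_columns": sm.n_columns,
                "newick": newick,
                "min_support": min(support.values()) if support else None,
                "longest_terminal_branch": max(terminal, key=terminal.get)
                if terminal else None,
            }

    if "rearrange" in cfg.stages:
        with stage("rearrange"):
            clade_scc = []
            for fam in families:
                members = tuple(m for m in fam.members if m[0] in clade)
                if members and {m[0] for m in members} == set(clade) and \
                        len(members) == len(clade):
                    clade_scc.append(OrthologFamily(fam.family_id, members))
            reference = cfg.free_living[0] if cfg.free_living else clade[0]
            orders = rearrange.encode_orders(
                [g for g in collection.genes if g.strain in clade],
                clade_scc, reference_strain=reference)
            with open(outdir / "orders.tsv", "w") as fh:
                fh.write("strain\trank\tsigned_family\n")
                for s in clade:
                    for rank, v in enumerate(orders[s].order, start=1):
                        fh.write(f"{s}\t{rank}\t{v}\n")
            dists = {}
            for i, s1 in enumerate(clade):
                for s2 in clade[i + 1:]:
                    d, _ = rearrange.reversal_distance(orders[s1], orders[s2])
                    dists[f"{s1}-{s2}"] = d
            mgr = rearrange.mgr_tree([orders[s] for s in clade])
            (outdir / "rearrangement_tree.nwk").write_text(mgr.newick + "\n")
            synteny = rearrange.synteny_pairs(orders[clade[0]],
                                              orders[clade[-1]])
            synteny.to_csv(outdir / "synteny_runs.tsv", sep="\t", index=False)
            report.stages["rearrange"] = {
                "n_order_genes": len(clade_scc),
                "pairwise_reversal_distances": dists,
                "mgr_total_distance": mgr.total_distance,
                "mgr_edge_distances": {f"{u}-{v}": d for (u, v), d
                                       in mgr.edge_distances.items()},
                "mgr_newick": mgr.newick,
            }

    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report


def _newick_with_support(tree, support: dict[frozenset[str], float]) -> str:
    """Attach integer bootstrap supports as internal node labels."""
    taxa = sorted(t.name for t in tree.tips())
    full = frozenset(taxa)
    ref = min(full)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = full - side if ref in side else side
        if canon in support:
            node.name = str(int(round(support[canon])))
    return str(tree).strip()
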