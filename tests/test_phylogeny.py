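"""Supermatrix construction, distances, NJ and bootstrap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pansym import phylogeny as ph
from pansym.orthology import OrthologFamily
from pansym.synthdata import simulate_clade
from conftest import small_config


def _family(fid, members):
    return OrthologFamily(fid, tuple(members))


def test_single_copy_core_membership_rules():
    strains = ["A", "B"]
    good = _family("F1", [("A", "1"), ("B", "1")])
    dup = _family("F2", [("A", "2"), ("A", "3"), ("B", "2")])
    missing = _family("F3", [("A", "4")])
    assert ph.single_copy_core([good, dup, missing], strains) == [good]


def test_single_copy_core_with_outgroup_requirement():
    fam_no_og = _family("F1", [("A", "1"), ("B", "1")])
    fam_og = _family("F2", [("A", "2"), ("B", "2"), ("OG", "2")])
    got = ph.single_copy_core([fam_no_og, fam_og], ["A", "B"],
                              require_outgroup=True, outgroup="OG")
    assert got == [fam_og]


def test_concatenate_lengths_boundaries_and_equivariance():
    fams = {"F1": {"A": "M" * 100, "B": "K" * 100},
            "F2": {"A": "W" * 50, "B": "Y" * 50}}
    sm = ph.concatenate(fams, ["A", "B"])
    assert sm.n_columns == 150
    assert sm.family_boundaries == [("F1", 0, 100), ("F2", 100, 150)]
    flipped = ph.concatenate(fams, ["B", "A"])
    assert flipped.rows == [sm.rows[1], sm.rows[0]]
    bad = {"F1": {"A": "MM", "B": "MMM"}}
    with pytest.raises(ValueError, match="unequal"):
        ph.concatenate(bad, ["A", "B"])


@pytest.mark.parametrize("a, b, expected", [
    ("MKVL", "MKVL", 0.0),
    ("MKVLMKVL", "MKVLWWWW", np.log(2)),   # p = 0.5
    ("M" * 90 + "W" * 10, "M" * 100, -np.log(0.9)),
])
def test_poisson_distance_closed_form(a, b, expected):
    assert ph.poisson_distance(a, b) == pytest.approx(expected)


def test_poisson_distance_saturation_error():
    with pytest.raises(ValueError, match="saturated"):
        ph.poisson_distance("AAAA", "WWWW")


def test_nj_rejects_asymmetric_matrix():
    dm = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["A", "B"],
                      columns=["A", "B"])
    with pytest.raises(ValueError, match="symmetric"):
        ph.nj_tree(dm)


def test_nj_three_taxon_branch_lengths():
    # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
    d = {"AB": 3.0, "AC": 4.0, "BC": 5.0}
    dm = pd.DataFrame([[0, d["AB"], d["AC"]],
                       [d["AB"], 0, d["BC"]],
                       [d["AC"], 0 + d["BC"], 0]],
                      index=list("ABC"), columns=list("ABC"))
    tree = ph.nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_recovers_additive_four_taxon_split():
    names = list("ABCD")
    dm = pd.DataFrame(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]], index=names, columns=names, dtype=float)
    tree = ph.nj_tree(dm)
    splits = ph.tree_splits(tree, names)
    assert splits == {frozenset("CD")}  # AB|CD
    # internal branch length 1 from the four-point condition
    internal = [n.length for n in tree.non_tips(include_self=False)
                if {t.name for t in n.tips()} in ({"A", "B"}, {"C", "D"})]
    assert internal and internal[0] == pytest.approx(1.0)
    # pairwise path lengths reproduce the additive input exactly
    tip = {t.name: t for t in tree.tips()}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert tip[a].distance(tip[b]) == pytest.approx(dm.loc[a, b])


def test_nj_exact_on_random_additive_five_taxon_matrix():
    # build an additive matrix from a known tree, check exact recovery
    rng = np.random.default_rng(5)
    names = list("ABCDE")
    # caterpillar ((A,B),C),(D,E); edges drawn positive
    e = {k: float(rng.uniform(0.5, 3.0)) for k in
         ["A", "B", "C", "D", "E", "i1", "i2"]}
    path = {
        ("A", "B"): e["A"] + e["B"],
        ("A", "C"): e["A"] + e["i1"] + e["C"],
        ("B", "C"): e["B"] + e["i1"] + e["C"],
        ("A", "D"): e["A"] + e["i1"] + e["i2"] + e["D"],
        ("A", "E"): e["A"] + e["i1"] + e["i2"] + e["E"],
        ("B", "D"): e["B"] + e["i1"] + e["i2"] + e["D"],
        ("B", "E"): e["B"] + e["i1"] + e["i2"] + e["E"],
        ("C", "D"): e["C"] + e["i2"] + e["D"],
        ("C", "E"): e["C"] + e["i2"] + e["E"],
        ("D", "E"): e["D"] + e["E"],
    }
    dm = pd.DataFrame(0.0, index=names, columns=names)
    for (a, b), v in path.items():
        dm.loc[a, b] = dm.loc[b, a] = v
    tree = ph.nj_tree(dm)
    # canonical splits exclude the side containing taxon A
    assert ph.tree_splits(tree, names) == {frozenset("CDE"), frozenset("DE")}
    tip = {t.name: t for t in tree.tips()}
    for (a, b), v in path.items():
        assert tip[a].distance(tip[b]) == pytest.approx(v)


def _supermatrix_from_sim(seed, columns_cfg=None):
    cfg = small_config(seed=seed, n_core_families=50, n_fls_accessory=0,
                       strain_specific_counts=(0, 0, 0, 0, 0),
                       n_single_copy_core=50, protein_length=100)
    cfg = cfg.resolved()
    cfg.branch_inversion_counts = {k: 0 for k in cfg.branch_inversion_counts}
    collection, truth = simulate_clade(cfg)
    gene_map = collection.gene_map()
    fam_seqs = {}
    for fid in truth.scc_families:
        fam_seqs[fid] = {s: gene_map[(s, gid)].sequence
                         for s, gid in truth.true_families[fid]}
    sm = ph.concatenate(fam_seqs, collection.strains)
    return sm, truth


def test_simulated_supermatrix_recovers_topology_and_acceleration():
    sm, truth = _supermatrix_from_sim(seed=2)
    assert sm.n_columns >= 5000
    dm = ph.distance_matrix(sm)
    tree = ph.nj_tree(dm, outgroup=truth.outgroup)
    want = {frozenset(truth.endo_strains),
            frozenset(truth.endo_strains + ["FL1"]),
            frozenset(["FL2", "FL3"])}
    got = ph.tree_splits(tree, sm.taxa)
    assert want <= got | {frozenset(sm.taxa) - s for s in got}
    terminal = {t.name: t.length for t in tree.tips()
                if t.name != truth.outgroup}
    assert max(terminal, key=terminal.get) == truth.endo_strains[-1]


def test_poisson_distance_consistent_with_branch_rates():
    sm, truth = _supermatrix_from_sim(seed=4)
    dm = ph.distance_matrix(sm)
    # FL2-FL3 path: two 0.02 branches
    rate = 0.04
    p_exp = 19 / 20 * (1 - np.exp(-20 / 19 * rate))
    d_exp = -np.log(1 - p_exp)
    se = np.sqrt(p_exp * (1 - p_exp) / sm.n_columns) / (1 - p_exp)
    assert abs(dm.loc["FL2", "FL3"] - d_exp) < 3 * se


def test_bootstrap_support_ranges_and_degenerate_cases():
    sm, truth = _supermatrix_from_sim(seed=6)
    _, support = ph.bootstrap_support(sm, n_replicates=1, seed=0)
    assert set(support.values()) <= {0.0, 100.0}
    _, support20 = ph.bootstrap_support(sm, n_replicates=20, seed=0,
                                        outgroup=truth.outgroup)
    assert all(0.0 <= v <= 100.0 for v in support20.values())
    # zero-divergence matrix: topology is arbitrary, but splits of the
    # returned tree are still reported with supports in range
    rows = ["M" * 60] * 4
    sm0 = ph.Supermatrix(taxa=list("ABCD"), rows=rows, family_boundaries=[])
    _, s0 = ph.bootstrap_support(sm0, n_replicates=5, seed=1)
    assert all(0.0 <= v <= 100.0 for v in s0.values())
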