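"""Signed permutations: encoding, breakpoints, reversal distance, medians."""

from __future__ import annotations

import random

import pytest

from pansym.orthology import OrthologFamily
from pansym.rearrange import (SignedGenomeOrder, apply_reversal,
                              breakpoint_distance, canonical_linear,
                              encode_orders, mgr_tree, reversal_distance,
                              sorting_scenario, synteny_pairs)
from pansym.records import GeneRecord
from _oracles import bfs_reversal_distances


def _order(vals, strain="s", shape="linear"):
    return SignedGenomeOrder(strain=strain, order=tuple(vals), shape=shape)


def _random_signed(rng: random.Random, n: int) -> tuple[int, ...]:
    vals = list(range(1, n + 1))
    rng.shuffle(vals)
    return tuple(v if rng.random() < 0.5 else -v for v in vals)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _gene(strain, gid, start, strand):
    return GeneRecord(strain=strain, gene_id=gid, contig="c", start=start,
                      end=start + 5, strand=strand, cog=None, sequence="M")


def test_encode_orders_reference_is_identity_and_inversion_recovered():
    fams = [OrthologFamily(f"F{i}", (("R", f"r{i}"), ("Q", f"q{i}")))
            for i in range(1, 6)]
    genes = [_gene("R", f"r{i}", start=i * 10, strand="+")
             for i in range(1, 6)]
    # Q equals R with segment [2..4] inverted: 1, -4, -3, -2, 5
    q_perm = [1, -4, -3, -2, 5]
    genes += [_gene("Q", f"q{abs(v)}", start=(k + 1) * 10,
                    strand="+" if v > 0 else "-")
              for k, v in enumerate(q_perm)]
    orders = encode_orders(genes, fams, reference_strain="R")
    assert orders["R"].order == (1, 2, 3, 4, 5)
    assert orders["Q"].order == (1, -4, -3, -2, 5)
    d, _ = reversal_distance(orders["R"], orders["Q"])
    assert d == 1


def test_encode_orders_rejects_missing_core_gene():
    fams = [OrthologFamily("F1", (("R", "r1"), ("Q", "q1"))),
            OrthologFamily("F2", (("R", "r2"), ("Q", "q2")))]
    genes = [_gene("R", "r1", 10, "+"), _gene("R", "r2", 20, "+"),
             _gene("Q", "q1", 10, "+")]
    with pytest.raises(ValueError, match="exactly one gene"):
        encode_orders(genes, fams, reference_strain="R")


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def test_breakpoint_distance_examples():
    assert breakpoint_distance(_order([1, 2, 3]), _order([1, 2, 3])) == 0
    assert breakpoint_distance(_order([1, 2, 3]), _order([1, -2, 3])) == 2


def test_breakpoints_at_most_twice_reversal_distance():
    rng = random.Random(1)
    for _ in range(50):
        n = rng.randint(2, 8)
        a, b = _order(_random_signed(rng, n)), _order(_random_signed(rng, n))
        bp = breakpoint_distance(a, b)
        d, _ = reversal_distance(a, b)
        assert bp <= 2 * d


# ---------------------------------------------------------------------------
# reversal distance
# ---------------------------------------------------------------------------

def test_reversal_distance_examples():
    assert reversal_distance(_order([1, 2]), _order([1, 2]))[0] == 0
    assert reversal_distance(_order([-1]), _order([1]))[0] == 1
    d, summary = reversal_distance(_order([3, 2, 1]), _order([1, 2, 3]))
    assert d == 3
    assert summary.h == 1  # one unoriented component: a hurdle


def test_reversal_distance_matches_bfs_oracle_exhaustively_small():
    oracle = bfs_reversal_distances(4)
    ident = _order([1, 2, 3, 4])
    for perm in oracle:
        assert reversal_distance(_order(perm), ident)[0] == oracle[perm]


def test_reversal_distance_metric_properties():
    rng = random.Random(3)
    for _ in range(25):
        n = rng.randint(3, 7)
        a = _order(_random_signed(rng, n), "a")
        b = _order(_random_signed(rng, n), "b")
        c = _order(_random_signed(rng, n), "c")
        dab = reversal_distance(a, b)[0]
        dba = reversal_distance(b, a)[0]
        dac = reversal_distance(a, c)[0]
        dbc = reversal_distance(b, c)[0]
        assert dab == dba
        assert (dab == 0) == (a.order == b.order)
        assert dac <= dab + dbc


def test_distance_bounds_from_breakpoint_graph():
    rng = random.Random(9)
    for _ in range(40):
        n = rng.randint(2, 8)
        a, b = _order(_random_signed(rng, n)), _order(_random_signed(rng, n))
        d, s = reversal_distance(a, b)
        assert s.b - s.c <= d <= s.n + 1
        assert 0 <= s.c <= s.n + 1
        assert s.b <= s.n + 1 and s.h >= 0


def test_mismatched_gene_sets_rejected():
    with pytest.raises(ValueError, match="different gene sets"):
        reversal_distance(_order([1, 2]), _order([1, 3]))


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_sorting_scenario_replay():
    rng = random.Random(11)
    cases = [((1, 2, 3), (1, 2, 3)), ((3, 2, 1), (1, 2, 3)),
             ((-1,), (1,))]
    for a_vals, b_vals in cases:
        a, b = _order(a_vals, "a"), _order(b_vals, "b")
        scenario = sorting_scenario(a, b)
        d, _ = reversal_distance(a, b)
        assert len(scenario) == d
    # random pairs: replay ends at the target
    for _ in range(10):
        n = rng.randint(2, 7)
        a = _order(_random_signed(rng, n), "a")
        b = _order(_random_signed(rng, n), "b")
        scenario = sorting_scenario(a, b)
        d, _ = reversal_distance(a, b)
        assert len(scenario) == d
        from pansym.rearrange import _relative_to
        cur = _relative_to(a, b)
        for i, j in scenario:
            cur = apply_reversal(cur, i, j)
        assert cur == tuple(range(1, n + 1))


# ---------------------------------------------------------------------------
# circular canonicalization
# ---------------------------------------------------------------------------

def test_circular_rotations_and_reflection_are_equivalent():
    base = (1, -3, 2, 4)
    a = _order(base, "a", shape="circular")
    for shift in range(4):
        rotated = base[shift:] + base[:shift]
        b = _order(rotated, "b", shape="circular")
        assert reversal_distance(a, b)[0] == 0
    reflected = tuple(-v for v in reversed(base))
    c = _order(reflected, "c", shape="circular")
    assert reversal_distance(a, c)[0] == 0
    assert canonical_linear(c).order[0] == 1


# ---------------------------------------------------------------------------
# MGR tree and medians
# ---------------------------------------------------------------------------

def test_mgr_three_identical_genomes():
    ident = tuple(range(1, 11))
    res = mgr_tree([_order(ident, s) for s in ("x", "y", "z")])
    assert res.total_distance == 0


def test_mgr_single_reversal_star_median_is_identity():
    n = 10
    ident = tuple(range(1, n + 1))
    leaf1 = apply_reversal(ident, 2, 4)
    leaf2 = apply_reversal(ident, 6, 9)
    res = mgr_tree([_order(ident, "anc"), _order(leaf1, "l1"),
                    _order(leaf2, "l2")])
    assert res.total_distance == 2
    median = res.internal_orders["M1"].order
    assert median == ident


def test_mgr_requires_three_genomes():
    with pytest.raises(ValueError, match="at least 3"):
        mgr_tree([_order([1, 2]), _order([1, 2])])


def test_mgr_recovers_sparse_inversion_totals_on_fixture():
    rng = random.Random(21)
    hits = 0
    trials = 5
    for t in range(trials):
        n = 40
        ident = tuple(range(1, n + 1))
        # three leaves, each a few inversions away from the ancestor
        leaves = []
        k_total = 0
        for s in ("a", "b", "c"):
            cur = ident
            k = rng.randint(1, 3)
            k_total += k
            for _ in range(k):
                i = rng.randint(1, n)
                j = rng.randint(i, n)
                cur = apply_reversal(cur, i, j)
            leaves.append(_order(cur, s))
        res = mgr_tree(leaves)
        assert res.total_distance <= k_total
        if res.total_distance == k_total:
            hits += 1
    assert hits >= trials - 1


# ---------------------------------------------------------------------------
# synteny runs
# ---------------------------------------------------------------------------

def test_synteny_identity_single_run():
    a = _order([1, 2, 3, 4, 5], "a")
    runs = synteny_pairs(a, _order([1, 2, 3, 4, 5], "b"))
    assert len(runs) == 1
    assert runs.iloc[0].tolist() == [1, 5, 1, 5, "+"]


def test_synteny_single_inversion_three_runs():
    ident = tuple(range(1, 9))
    inv = apply_reversal(ident, 3, 6)
    runs = synteny_pairs(_order(inv, "a"), _order(ident, "b"))
    assert len(runs) == 3
    assert runs.iloc[1]["orientation"] == "-"
    assert runs.iloc[1][["start_b", "end_b"]].tolist() == [6, 3]


def test_synteny_fully_shuffled_gives_unit_runs():
    a = _order([2, -5, 4, -1, -3], "a")
    runs = synteny_pairs(a, _order([1, 2, 3, 4, 5], "b"))
    assert len(runs) == 5
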