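"""Functional profiles, divergence, retention calls, rank tests, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pansym import cogprofiles as cp
from pansym.orthology import OrthologFamily
from conftest import make_gene


def _matrix(rows: dict[str, dict[str, int]]) -> cp.CogProfileMatrix:
    cats = sorted({c for row in rows.values() for c in row})
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=cats).fillna(0)
    return cp.CogProfileMatrix(counts=df.astype(int))


def test_strain_profiles_tally_assigned_only():
    genes = [make_gene(gene_id="g1", cog="J"), make_gene(gene_id="g2", cog="J"),
             make_gene(gene_id="g3", cog="K"), make_gene(gene_id="g4", cog=None)]
    mat = cp.strain_profiles(genes)
    assert mat.counts.loc["S1", "J"] == 2
    assert mat.counts.loc["S1", "K"] == 1
    assert mat.assigned_totals["S1"] == 3


def test_all_unassigned_gives_zero_matrix():
    genes = [make_gene(gene_id=f"g{i}", cog=None) for i in range(3)]
    mat = cp.strain_profiles(genes)
    assert mat.assigned_totals["S1"] == 0
    with pytest.raises(ValueError, match="zero assigned"):
        cp.relative_profile(mat)


def test_family_profile_uses_modal_member_labels():
    fams = [OrthologFamily("F1", (("A", "1"), ("B", "1"), ("C", "1"))),
            OrthologFamily("F2", (("A", "2"), ("B", "2")))]
    ann = {("A", "1"): "J", ("B", "1"): "J", ("C", "1"): "K",
           ("A", "2"): "M", ("B", "2"): "M"}
    mat = cp.family_profile(fams, ann, "core")
    assert mat.counts.loc["core", "J"] == 1
    assert mat.counts.loc["core", "M"] == 1
    assert mat.assigned_totals["core"] == 2


def test_relative_profile_rows_sum_to_one():
    mat = _matrix({"u": {"J": 10, "K": 30, "L": 60}})
    rel = cp.relative_profile(mat)
    assert rel.loc["u"].tolist() == pytest.approx([0.10, 0.30, 0.60])
    assert rel.sum(axis=1).tolist() == pytest.approx([1.0])


def test_divergence_arithmetic_and_zero_reference():
    rel = pd.DataFrame({"J": [0.10, 0.12, 0.14, 0.20],
                        "K": [0.90, 0.88, 0.86, 0.80]},
                       index=["f1", "f2", "f3", "endo"])
    div = cp.fls_divergence(rel, ["f1", "f2", "f3"])
    assert div.deltas.loc["endo", "J"] == pytest.approx(8.0)
    # a strain identical to the free-living mean diverges nowhere
    rel2 = pd.concat([rel, rel.loc[["f1", "f2", "f3"]].mean(
        axis=0).to_frame("mean_strain").T])
    div2 = cp.fls_divergence(rel2, ["f1", "f2", "f3"])
    assert np.allclose(div2.deltas.loc["mean_strain"], 0.0)
    # deltas sum to zero across categories for every unit
    assert np.allclose(div.deltas.sum(axis=1), 0.0, atol=1e-9)


def test_divergence_requires_reference():
    rel = pd.DataFrame({"J": [0.5], "K": [0.5]}, index=["u"])
    with pytest.raises(ValueError, match="empty"):
        cp.fls_divergence(rel, [])


@pytest.mark.parametrize("delta, label", [
    (-6.0, "extremely_reduced"),
    (-3.0, "highly_reduced"),
    (-1.0, "moderately_reduced"),
    (0.0, "moderately_reduced"),
    (1.0, "moderately_retained"),
    (3.0, "highly_retained"),
    (6.0, "extremely_retained"),
    # boundary values join the higher-magnitude class
    (5.0, "extremely_retained"),
    (2.0, "highly_retained"),
    (-2.0, "highly_reduced"),
    (-5.0, "extremely_reduced"),
])
def test_retention_categorization_grid(delta, label):
    assert cp.categorize_retention(delta) == label


def test_retention_is_total_and_monotone():
    grid = np.linspace(-8, 8, 161)
    ranks = {lab: i for i, lab in enumerate(cp.RETENTION_LABELS)}
    labels = [cp.categorize_retention(d) for d in grid]
    # larger delta never maps to a more reduced label
    assert all(ranks[a] >= ranks[b] for a, b in zip(labels, labels[1:]))
    with pytest.raises(ValueError, match="non-finite"):
        cp.categorize_retention(float("nan"))


def test_ratio_table_arithmetic():
    rel = pd.DataFrame({"J": [0.4, 0.2], "K": [0.6, 0.8]},
                       index=["num", "den"])
    ratios = cp.ratio_table(rel, "num", "den")
    assert ratios["J"] == pytest.approx(2.0)
    assert ratios["K"] == pytest.approx(0.75)
    same = cp.ratio_table(rel, "num", "num")
    assert all(v == pytest.approx(1.0) for v in same.values())
    zero = pd.DataFrame({"J": [0.4, 0.0]}, index=["num", "den"])
    assert cp.ratio_table(zero, "num", "den")["J"] is None


def test_kruskal_wallis_reference_values():
    h, df, p = cp.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert round(h, 3) == 3.857
    assert df == 1
    h0, df0, p0 = cp.kruskal_wallis([[5, 5], [5, 5, 5]])
    assert (h0, p0) == (0.0, 1.0)
    assert cp.kruskal_wallis([[1], [2], [3], [4], [5], [6], [7]])[1] == 6
    with pytest.raises(ValueError, match="zero observations"):
        cp.kruskal_wallis([[1, 2], []])


def test_kruskal_wallis_invariant_under_monotone_transform():
    groups = [[1.0, 3.0, 9.0], [2.0, 8.0, 20.0], [0.5, 4.0, 7.0]]
    h1, _, _ = cp.kruskal_wallis(groups)
    h2, _, _ = cp.kruskal_wallis([[np.exp(v) for v in g] for g in groups])
    assert h1 == pytest.approx(h2)


def test_combine_profiles_adds_counts():
    mat = _matrix({"a": {"J": 1, "K": 2}, "b": {"J": 3, "K": 4},
                   "z": {"J": 0, "K": 0}})
    out = cp.combine_profiles(mat, "a", "b")
    assert out.counts.loc["a+b"].tolist() == [4, 6]
    # adding a zero profile is the identity on counts
    zid = cp.combine_profiles(mat, "z", "b", name="zb")
    assert zid.counts.loc["zb"].tolist() == mat.counts.loc["b"].tolist()
    # self-sum doubles counts but leaves the relative profile unchanged
    self_sum = cp.combine_profiles(mat, "b", "b", name="bb")
    self_sum = cp.CogProfileMatrix(self_sum.counts.drop(index="z"))
    rel = cp.relative_profile(self_sum)
    assert rel.loc["bb"].tolist() == pytest.approx(rel.loc["b"].tolist())
    with pytest.raises(ValueError, match="already present"):
        cp.combine_profiles(mat, "a", "b", name="z")


def test_identical_rows_merge_at_height_zero():
    df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]],
                      index=["a", "b", "c"], columns=["J", "K"])
    res = cp.hierarchical_cluster(df)
    assert res.row_linkage[0, 2] == pytest.approx(0.0)
    # the identical rows end up adjacent in the leaf ordering
    assert abs(res.row_order.index("a") - res.row_order.index("b")) == 1


def test_one_dimensional_complete_linkage_heights():
    df = pd.DataFrame([[0.0], [1.0], [10.0]], index=["x", "y", "z"],
                      columns=["J"])
    res = cp.hierarchical_cluster(df, metric="euclidean", linkage="complete")
    # {x,y} merge first at height 1, then z joins at height 10
    assert res.row_linkage[0, 2] == pytest.approx(1.0)
    assert res.row_linkage[1, 2] == pytest.approx(10.0)
    with pytest.raises(ValueError, match="at least 2"):
        cp.hierarchical_cluster(df.iloc[:1])


def test_stack_profiles_rejects_duplicates():
    a = _matrix({"u": {"J": 1, "K": 1}})
    with pytest.raises(ValueError, match="duplicate"):
        cp.stack_profiles(a, a)
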