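"""Comparison of inferred against true clusterings."""

from __future__ import annotations

from collections import Counter
from math import comb


def adjusted_rand_index(labels_a: dict[object, object],
                        labels_b: dict[object, object]) -> float:
    """Adjusted Rand index between two partitions of the same item set.

    Each argument maps an item to its cluster label. 1.0 means identical
    partitions; 0.0 is the chance expectation.
    """
    if set(labels_a) != set(labels_b):
        raise ValueError("partitions cover different item sets")
    items = list(labels_a)
    contingency: Counter[tuple[object, object]] = Counter(
        (labels_a[x], labels_b[x]) for x in items)
    a_sizes = Counter(labels_a[x] for x in items)
    b_sizes = Counter(labels_b[x] for x in items)
    n = len(items)
    sum_cells = sum(comb(c, 2) for c in contingency.values())
    sum_a = sum(comb(c, 2) for c in a_sizes.values())
    sum_b = sum(comb(c, 2) for c in b_sizes.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def families_to_labels(families, singletons=()) -> dict[tuple[str, str], str]:
    """Flatten a family list (+ singleton genes) into item -> cluster label."""
    labels: dict[tuple[str, str], str] = {}
    for fam in families:
        fam_id = fam.family_id if hasattr(fam, "family_id") else fam[0]
        members = fam.members if hasattr(fam, "members") else fam[1]
        for m in members:
            labels[tuple(m)] = str(fam_id)
    for i, m in enumerate(singletons):
        labels[tuple(m)] = f"__singleton_{i}"
    return labels
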