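"""Independent brute-force oracles used by the test suite."""

from __future__ import annotations

from collections import deque

from pansym.rearrange import apply_reversal


def bfs_reversal_distances(n: int) -> dict[tuple[int, ...], int]:
    """Breadth-first search over the whole space of signed permutations of
    size n: exact reversal distance from the identity to every permutation.

    Independent of the breakpoint-graph implementation under test.
    """
    identity = tuple(range(1, n + 1))
    dist: dict[tuple[int, ...], int] = {identity: 0}
    queue: deque[tuple[int, ...]] = deque([identity])
    moves = [(i, j) for i in range(1, n + 1) for j in range(i, n + 1)]
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        for i, j in moves:
            nxt = apply_reversal(cur, i, j)
            if nxt not in dist:
                dist[nxt] = d + 1
                queue.append(nxt)
    return dist


def brute_force_median_total(orders: list[tuple[int, ...]],
                             dist: dict[tuple[int, ...], int],
                             relabel) -> int:
    """Exhaustive median: min over all permutations of the summed reversal
    distance to the given orders (uses a precomputed BFS distance table)."""
    best = None
    for candidate in dist:
        total = sum(dist[relabel(o, candidate)] for o in orders)
        if best is None or total < best:
            best = total
    return best
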