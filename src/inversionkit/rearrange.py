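"""Reversal distances and minimal sorting scenarios for signed permutations.

Two independent routes are provided:

* :func:`reversal_distance` — the exact Hannenhalli–Pevzner distance via
  the breakpoint graph (cycles, hurdles, fortress) for linear signed
  permutations, ``d = n + 1 - c + h + f``.
* :func:`reversal_distance_bfs` — an exhaustive breadth-first oracle over
  the reversal graph, guarded to small ``n``, used to validate the
  closed-form computation.

Arms of the complex are linear and all fixed differences are paracentric
inversions, so reversals are the only operation modelled.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import SignedPermutation

BFS_LIMIT = 8


class OracleLimitError(ValueError):
    pass


@dataclass(frozen=True)
class Reversal:
    """Inclusive block [start_index, end_index] on 0-based positions."""

    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_index <= self.end_index:
            raise ValueError(f"invalid reversal block {self}")


def apply_reversal(perm: SignedPermutation, r: Reversal) -> SignedPermutation:
    """Reverse the block's order and flip every sign in it (an involution)."""
    if r.end_index >= perm.n:
        raise IndexError(f"reversal {r} out of range for n={perm.n}")
    e = perm.elements
    a, b = r.start_index, r.end_index + 1
    return SignedPermutation(perm.arm, e[:a] + tuple(-x for x in reversed(e[a:b])) + e[b:])


def _relabel_to_identity_target(p: SignedPermutation, q: SignedPermutation) -> tuple[int, ...]:
    """Rename segments so that q becomes the identity; returns renamed p."""
    if p.n != q.n:
        raise ValueError("permutations are over different segment universes")
    rank: dict[int, int] = {}
    for i, e in enumerate(q.elements, start=1):
        rank[abs(e)] = i if e > 0 else -i
    out = []
    for e in p.elements:
        r = rank[abs(e)]
        out.append(r if e > 0 else -r)
    return tuple(out)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def _all_reversals(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


def _rev(t: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    return t[:i] + tuple(-x for x in reversed(t[i:j + 1])) + t[j + 1:]


def bfs_distance_table(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every signed permutation of size n."""
    if n > BFS_LIMIT:
        raise OracleLimitError(f"BFS oracle limited to n <= {BFS_LIMIT}, got {n}")
    start = tuple(range(1, n + 1))
    dist = {start: 0}
    frontier = deque([start])
    moves = _all_reversals(n)
    while frontier:
        cur = frontier.popleft()
        d = dist[cur] + 1
        for i, j in moves:
            nxt = _rev(cur, i, j)
            if nxt not in dist:
                dist[nxt] = d
                frontier.append(nxt)
    return dist


def reversal_distance_bfs(p: SignedPermutation, q: SignedPermutation) -> int:
    """Exact minimum reversal count by BFS over the reversal graph (n <= 8)."""
    if p.n > BFS_LIMIT:
        raise OracleLimitError(f"BFS oracle limited to n <= {BFS_LIMIT}, got {p.n}")
    source = _relabel_to_identity_target(p, q)
    target = tuple(range(1, p.n + 1))
    if source == target:
        return 0
    seen = {source: 0}
    frontier = deque([source])
    moves = _all_reversals(p.n)
    while frontier:
        cur = frontier.popleft()
        d = seen[cur] + 1
        for i, j in moves:
            nxt = _rev(cur, i, j)
            if nxt == target:
                return d
            if nxt not in seen:
                seen[nxt] = d
                frontier.append(nxt)
    raise AssertionError("reversal graph is connected; unreachable")


# ---------------------------------------------------------------------------
# breakpoint-graph distance
# ---------------------------------------------------------------------------

def _extended(perm: tuple[int, ...]) -> list[int]:
    n = len(perm)
    out = [0]
    for e in perm:
        x = abs(e)
        out.extend((2 * x - 1, 2 * x) if e > 0 else (2 * x, 2 * x - 1))
    out.append(2 * n + 1)
    return out


def _hp_components(perm: tuple[int, ...]):
    """Cycles and unoriented-component structure of the breakpoint graph.

    Returns (n_cycles, list of unoriented components, position span per
    component) where each component is a set of gray-edge position
    intervals.  Trivial cycles (adjacencies) form no component.
    """
    n = len(perm)
    b = _extended(perm)
    pos = {v: i for i, v in enumerate(b)}
    m = n + 1  # number of black/gray edges
    # gray edge i joins values 2i and 2i+1; record as sorted position pair
    gray = []
    for i in range(m):
        p1, p2 = pos[2 * i], pos[2 * i + 1]
        gray.append((min(p1, p2), max(p1, p2)))

    # cycles: union-find joining gray edge indices that share a black edge.
    # black edge k connects positions 2k and 2k+1; map position -> gray edge.
    owner = {}
    for gi, (p1, p2) in enumerate(gray):
        owner[p1] = gi
        owner[p2] = gi
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for k in range(m):
        union(owner[2 * k], owner[2 * k + 1])
    n_cycles = len({find(i) for i in range(m)})

    # interval-overlap components over gray edges (same cycle => same comp)
    for a in range(m):
        pa, qa = gray[a]
        for bdx in range(a + 1, m):
            pb, qb = gray[bdx]
            if (pa < pb < qa < qb) or (pb < pa < qb < qa):
                union(a, bdx)

    oriented = [((p1 + p2) % 2 == 0) for (p1, p2) in gray]
    trivial = [(p2 - p1 == 1) for (p1, p2) in gray]
    comp_edges: dict[int, list[int]] = {}
    for gi in range(m):
        comp_edges.setdefault(find(gi), []).append(gi)
    unoriented_comps = []
    for edges in comp_edges.values():
        if all(trivial[gi] for gi in edges):
            continue
        if any(oriented[gi] for gi in edges):
            continue
        positions = sorted({p for gi in edges for p in gray[gi]})
        unoriented_comps.append(positions)
    return n_cycles, unoriented_comps


def _hurdles_and_fortress(unoriented: list[list[int]]) -> tuple[int, int]:
    """Count hurdles and the fortress correction from unoriented components."""
    if not unoriented:
        return 0, 0
    # collapsed circular sequence of component labels along the line
    marks = sorted(
        (p, ci) for ci, positions in enumerate(unoriented) for p in positions
    )
    seq = [ci for _, ci in marks]
    collapsed: list[int] = []
    for ci in seq:
        if not collapsed or collapsed[-1] != ci:
            collapsed.append(ci)
    if len(collapsed) > 1 and collapsed[0] == collapsed[-1]:
        collapsed.pop()

    k = len(collapsed)
    occurrences: dict[int, int] = {}
    for ci in collapsed:
        occurrences[ci] = occurrences.get(ci, 0) + 1
    hurdles = {ci for ci, cnt in occurrences.items() if cnt == 1}

    super_hurdles = set()
    for idx, ci in enumerate(collapsed):
        if ci not in hurdles:
            continue
        left = collapsed[(idx - 1) % k]
        right = collapsed[(idx + 1) % k]
        if k >= 3 and left == right and occurrences[left] == 2:
            super_hurdles.add(ci)

    h = len(hurdles)
    fortress = 1 if (h % 2 == 1 and h > 0 and hurdles == super_hurdles) else 0
    return h, fortress


def reversal_distance(p: SignedPermutation, q: SignedPermutation) -> int:
    """Hannenhalli–Pevzner reversal distance ``n + 1 - c + h + f``."""
    perm = _relabel_to_identity_target(p, q)
    n = len(perm)
    if perm == tuple(range(1, n + 1)):
        return 0
    n_cycles, unoriented = _hp_components(perm)
    h, f = _hurdles_and_fortress(unoriented)
    return n + 1 - n_cycles + h + f


# ---------------------------------------------------------------------------
# minimal sorting scenarios
# ---------------------------------------------------------------------------

SORTING_GUARD = 4


def minimal_sorting_sequences(
    p: SignedPermutation,
    q: SignedPermutation,
    limit: int = 1000,
) -> list[list[Reversal]]:
    """All (up to ``limit``) shortest reversal sequences transforming p into q.

    Sequences are enumerated depth-first with reversals ordered
    lexicographically by (start, end); each prefix keeps only reversals
    that decrease the remaining distance, so enumeration is exhaustive
    over minimal scenarios.  Guarded to distance <= 4.
    """
    d0 = reversal_distance(p, q)
    if d0 > SORTING_GUARD:
        raise OracleLimitError(
            f"sorting-scenario enumeration guarded to distance <= {SORTING_GUARD}"
        )
    results: list[list[Reversal]] = []

    def recurse(cur: SignedPermutation, remaining: int, prefix: list[Reversal]) -> None:
        if len(results) >= limit:
            return
        if remaining == 0:
            results.append(list(prefix))
            return
        for i, j in _all_reversals(cur.n):
            r = Reversal(i, j)
            nxt = apply_reversal(cur, r)
            if reversal_distance(nxt, q) == remaining - 1:
                prefix.append(r)
                recurse(nxt, remaining - 1, prefix)
                prefix.pop()
                if len(results) >= limit:
                    return

    recurse(p, d0, [])
    return results


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray
    per_arm: dict[str, np.ndarray]

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i, j = self.taxa.index(pair[0]), self.taxa.index(pair[1])
        return int(self.values[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def pairwise_distance_matrix(
    karyotypes: Mapping[str, Mapping[str, SignedPermutation]],
    method: str = "hp",
) -> DistanceMatrix:
    """Per-pair rearrangement distance summed over arms.

    ``karyotypes`` maps taxon -> arm -> signed permutation; all taxa must
    share the same arm set and segment counts.
    """
    taxa = tuple(karyotypes)
    arms = None
    for t in taxa:
        tarms = tuple(sorted(karyotypes[t]))
        if arms is None:
            arms = tarms
        elif tarms != arms:
            raise ValueError(f"taxon {t} has mismatched arms {tarms} != {arms}")
    assert arms is not None
    dist_fn = reversal_distance if method == "hp" else reversal_distance_bfs
    k = len(taxa)
    per_arm = {arm: np.zeros((k, k), dtype=int) for arm in arms}
    total = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            for arm in arms:
                d = dist_fn(karyotypes[taxa[i]][arm], karyotypes[taxa[j]][arm])
                per_arm[arm][i, j] = per_arm[arm][j, i] = d
                total[i, j] += d
            total[j, i] = total[i, j]
    return DistanceMatrix(taxa, total, per_arm)
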