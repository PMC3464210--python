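"""Minimum-event inversion phylogenies with outgroup rooting.

Karyotypes are binary character vectors (one character per catalogued
inversion), except that inversions whose segment intervals overlap on an
arm are scored jointly: transitions between joint states are charged the
length of the shortest valid flip trajectory (module
:mod:`inversionkit.catalog`), so e.g. toggling one member of an
overlapping pair on the wrong background costs more than one event, and
impossible elementary steps are never charged as single events.

Tree search is exhaustive over all unrooted binary topologies (guarded
to 8 taxa, (2n-5)!! trees), replacing heuristic rearrangement-median
searches with a deterministic scan.  Scenario analysis scores the same
ingroup matrix under alternative outgroup X-chromosome arrangements and
flags the scenario(s) whose optimum needs every inversion to originate
only once.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .catalog import (
    INVERTED,
    OUTGROUP,
    STANDARD,
    UNKNOWN,
    X_STATE_OPTIONS,
    ArrangementStates,
    InversionCatalog,
    SignedPermutation,
    _single_reversal_between,
    build_segment_map,
    encode_arm,
    gambiae_complex_catalog,
    gambiae_complex_karyotypes,
    outgroup_states,
)

INF = 1 << 20

MAX_TAXA = 8


class TooManyTaxaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeTopology:
    """An unrooted binary topology, stored rooted on the first leaf's edge.

    ``structure`` is a nested pair of leaf indices over ``leaves[1:]``;
    leaf 0 attaches at the top.  Two topologies are equal iff their
    canonical Newick strings are equal.
    """

    leaves: tuple[str, ...]
    structure: object

    def _name(self, node) -> str:
        if isinstance(node, int):
            return self.leaves[node]
        return f"({self._name(node[0])},{self._name(node[1])})"

    def newick(self) -> str:
        return f"({self.leaves[0]},{self._name(self.structure)});"

    def canonical_newick(self) -> str:
        def canon(node):
            if isinstance(node, int):
                return self.leaves[node]
            a, b = canon(node[0]), canon(node[1])
            return f"({min(a, b)},{max(a, b)})"

        return f"({self.leaves[0]},{canon(self.structure)});"


def _insertions(node, leaf: int) -> list[object]:
    """All shapes obtained by attaching ``leaf`` on any edge at or below node."""
    out: list[object] = [(node, leaf)]
    if not isinstance(node, int):
        out.extend((sub, node[1]) for sub in _insertions(node[0], leaf))
        out.extend((node[0], sub) for sub in _insertions(node[1], leaf))
    return out


@lru_cache(maxsize=8)
def _structures(m: int) -> tuple[object, ...]:
    """All (2m-3)!! rooted binary shapes over leaf indices 1..m, stepwise order."""
    if m < 1:
        return ()
    trees: list[object] = [1]
    for leaf in range(2, m + 1):
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return tuple(trees)


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> list[TreeTopology]:
    """All (2n-5)!! unrooted binary topologies over the taxa, 3 <= n <= 8."""
    n = len(taxa)
    if not 3 <= n <= MAX_TAXA:
        raise TooManyTaxaError(f"need 3..{MAX_TAXA} taxa, got {n}")
    return [TreeTopology(tuple(taxa), s) for s in _structures(n - 1)]


# ---------------------------------------------------------------------------
# character compilation
# ---------------------------------------------------------------------------

@dataclass
class GroupCharacter:
    """Joint character for a set of mutually overlapping inversions on one arm."""

    arm: str
    inversions: tuple[str, ...]
    dist: np.ndarray
    #: canonical shortest flip path between any two states (state-index lists)
    paths: dict[tuple[int, int], tuple[int, ...]]

    def state_index(self, states: ArrangementStates) -> int | None:
        """Joint state index, or None when any member state is unknown."""
        idx = 0
        for bit, name in enumerate(self.inversions):
            s = states.state(name)
            if s == UNKNOWN:
                return None
            if s == INVERTED:
                idx |= 1 << bit
        return idx


@dataclass
class CharacterModel:
    binary: tuple[str, ...]
    groups: tuple[GroupCharacter, ...]

    @property
    def inversion_names(self) -> tuple[str, ...]:
        return self.binary + tuple(n for g in self.groups for n in g.inversions)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    sa = set(range(a[0] + 1, a[1] + 1))
    sb = set(range(b[0] + 1, b[1] + 1))
    return bool(sa & sb)


def _flip_graph(catalog: InversionCatalog, arm: str, names: tuple[str, ...]):
    """All-pairs shortest valid-flip distances over joint arrangement states."""
    sub = catalog.subset(names)
    smap = build_segment_map(sub, arm)
    k = len(names)
    perms: list[SignedPermutation] = []
    for idx in range(1 << k):
        st = ArrangementStates(
            f"s{idx}",
            {names[b]: (INVERTED if idx >> b & 1 else STANDARD) for b in range(k)},
        )
        perms.append(encode_arm(st, smap, sub, arm))
    adj: dict[int, list[int]] = {i: [] for i in range(1 << k)}
    for i, j in itertools.combinations(range(1 << k), 2):
        if bin(i ^ j).count("1") != 1:
            continue
        if _single_reversal_between(perms[i], perms[j]) is not None:
            adj[i].append(j)
            adj[j].append(i)
    n_states = 1 << k
    dist = np.full((n_states, n_states), INF, dtype=int)
    paths: dict[tuple[int, int], tuple[int, ...]] = {}
    for src in range(n_states):
        dist[src, src] = 0
        paths[(src, src)] = (src,)
        prev = {src: None}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in sorted(adj[u]):
                if v not in prev:
                    prev[v] = u
                    dist[src, v] = dist[src, u] + 1
                    q.append(v)
        for dst, p in list(prev.items()):
            path = [dst]
            while prev[path[-1]] is not None:
                path.append(prev[path[-1]])
            paths[(src, dst)] = tuple(reversed(path))
    return dist, paths


def compile_characters(catalog: InversionCatalog) -> CharacterModel:
    """Split the catalog into independent binary characters and overlap groups."""
    binary: list[str] = []
    groups: list[GroupCharacter] = []
    for arm in catalog.arms:
        invs = catalog.by_arm(arm)
        # connected components of the interval-overlap graph
        comp: dict[str, set[str]] = {i.name: {i.name} for i in invs}
        for a, b in itertools.combinations(invs, 2):
            if _overlap(a.interval, b.interval):
                merged = comp[a.name] | comp[b.name]
                for n in merged:
                    comp[n] = merged
        seen: set[frozenset] = set()
        for i in invs:
            key = frozenset(comp[i.name])
            if key in seen:
                continue
            seen.add(key)
            members = tuple(x.name for x in invs if x.name in key)
            if len(members) == 1:
                binary.append(members[0])
            else:
                dist, paths = _flip_graph(catalog, arm, members)
                groups.append(GroupCharacter(arm, members, dist, paths))
    return CharacterModel(tuple(binary), tuple(groups))


# ---------------------------------------------------------------------------
# karyotype matrix
# ---------------------------------------------------------------------------

@dataclass
class KaryotypeMatrix:
    """Taxon x inversion arrangement states, with one designated outgroup."""

    states: dict[str, ArrangementStates]
    outgroup: str

    def __post_init__(self) -> None:
        if self.outgroup not in self.states:
            raise ValueError(f"outgroup {self.outgroup!r} absent from matrix")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.states)

    def with_outgroup_states(self, states: ArrangementStates) -> "KaryotypeMatrix":
        new = dict(self.states)
        new[self.outgroup] = states
        return KaryotypeMatrix(new, self.outgroup)

    def present_inversions(self, catalog: InversionCatalog) -> tuple[str, ...]:
        """Inversions inverted in at least one taxon."""
        return tuple(
            inv.name
            for inv in catalog.inversions
            if any(s.state(inv.name) == INVERTED for s in self.states.values())
        )


def complex_matrix(x_state: str = "Xag") -> KaryotypeMatrix:
    """The seven ingroup taxa plus an outgroup with the given X arrangement."""
    states = dict(gambiae_complex_karyotypes())
    states[OUTGROUP] = outgroup_states(x_state)
    return KaryotypeMatrix(states, OUTGROUP)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _leaf_binary_masks(
    matrix: KaryotypeMatrix, model: CharacterModel, leaves: Sequence[str]
) -> list[int]:
    masks = []
    for taxon in leaves:
        st = matrix.states[taxon]
        m = 0
        for c, name in enumerate(model.binary):
            s = st.state(name)
            if s == STANDARD:
                m |= 1 << (2 * c)
            elif s == INVERTED:
                m |= 1 << (2 * c + 1)
            else:
                m |= 0b11 << (2 * c)
        masks.append(m)
    return masks


def _leaf_group_vectors(
    matrix: KaryotypeMatrix, group: GroupCharacter, leaves: Sequence[str]
) -> list[tuple[int, ...]]:
    n_states = group.dist.shape[0]
    vecs = []
    for taxon in leaves:
        idx = group.state_index(matrix.states[taxon])
        if idx is None:
            vecs.append(tuple(0 for _ in range(n_states)))
        else:
            vecs.append(tuple(0 if s == idx else INF for s in range(n_states)))
    return vecs


def _score_structure(structure, masks, group_vecs, group_dists, std_mask):
    """(total score, root mask, root group vectors) for one topology."""

    def rec(node):
        if isinstance(node, int):
            return masks[node], 0, [gv[node] for gv in group_vecs]
        m1, c1, v1 = rec(node[0])
        m2, c2, v2 = rec(node[1])
        inter = m1 & m2
        present = (inter | (inter >> 1)) & std_mask
        empty = std_mask & ~present
        changes = c1 + c2 + empty.bit_count()
        emask = empty | (empty << 1)
        mask = (inter & ~emask) | ((m1 | m2) & emask)
        vecs = []
        for D, a, b in zip(group_dists, v1, v2):
            vecs.append(tuple(
                min(a[t] + Ds[t] for t in range(len(a)))
                + min(b[t] + Ds[t] for t in range(len(b)))
                for Ds in D
            ))
        return mask, changes, vecs

    mask, changes, vecs = rec(structure)
    # join leaf 0 across the root edge (one more Fitch/Sankoff merge)
    inter = mask & masks[0]
    present = (inter | (inter >> 1)) & std_mask
    changes += (std_mask & ~present).bit_count()
    total = changes
    for D, v, leafv in zip(group_dists, vecs, [gv[0] for gv in group_vecs]):
        total += min(
            v[s] + min(leafv[t] + D[s][t] for t in range(len(v)))
            for s in range(len(v))
        )
    return total


def _scan(matrix: KaryotypeMatrix, catalog: InversionCatalog,
          model: CharacterModel) -> tuple[int, list[TreeTopology]]:
    """Exhaustive minimum-event search over all topologies."""
    taxa = list(matrix.taxa)
    # put the outgroup at position 0 (the rooting leaf)
    taxa.remove(matrix.outgroup)
    taxa.insert(0, matrix.outgroup)
    masks = _leaf_binary_masks(matrix, model, taxa)
    group_vecs = [_leaf_group_vectors(matrix, g, taxa) for g in model.groups]
    group_dists = [tuple(tuple(int(x) for x in row) for row in g.dist)
                   for g in model.groups]
    std_mask = 0
    for c in range(len(model.binary)):
        std_mask |= 1 << (2 * c)
    best = INF
    best_structs: list[object] = []
    for s in _structures(len(taxa) - 1):
        sc = _score_structure(s, masks, group_vecs, group_dists, std_mask)
        if sc < best:
            best, best_structs = sc, [s]
        elif sc == best:
            best_structs.append(s)
    topos = [TreeTopology(tuple(taxa), s) for s in best_structs]
    topos.sort(key=lambda t: t.canonical_newick())
    return best, topos


# -- detailed single-tree scoring -------------------------------------------

def _fitch_sets(structure, leaf_sets):
    """Bottom-up Fitch state sets and change count for one binary character."""
    sets: dict[int, set] = {}

    def rec(node):
        if isinstance(node, int):
            return leaf_sets[node], 0
        s1, c1 = rec(node[0])
        s2, c2 = rec(node[1])
        inter = s1 & s2
        s, c = (inter, c1 + c2) if inter else (s1 | s2, c1 + c2 + 1)
        sets[id(node)] = s
        return s, c

    root_set, changes = rec(structure)
    inter = root_set & leaf_sets[0]
    if not inter:
        changes += 1
    return sets, root_set, changes


def _fitch_labeling(structure, leaf_sets, root_state):
    """Top-down minimum-change labeling given bottom-up Fitch sets."""
    sets, _, _ = _fitch_sets(structure, leaf_sets)

    labels = {}

    def down(node, parent_state):
        s = leaf_sets[node] if isinstance(node, int) else sets[id(node)]
        state = parent_state if parent_state in s else min(s)
        labels[node if isinstance(node, int) else id(node)] = state
        if not isinstance(node, int):
            down(node[0], state)
            down(node[1], state)

    down(structure, root_state)
    return labels


def _sankoff_labeling(structure, leaf_vecs, D, root_leaf_vec):
    """Minimum-cost joint-state labeling (deterministic argmin tie-break)."""
    n_states = len(D)
    vecs = {}

    def up(node):
        if isinstance(node, int):
            vecs[node] = leaf_vecs[node]
            return vecs[node]
        a, b = up(node[0]), up(node[1])
        v = tuple(
            min(a[t] + D[s][t] for t in range(n_states))
            + min(b[t] + D[s][t] for t in range(n_states))
            for s in range(n_states)
        )
        vecs[id(node)] = v
        return v

    root_vec = up(structure)
    # choose the root state jointly with the outgroup leaf's state
    best = min(
        (root_vec[s] + min(root_leaf_vec[t] + D[s][t] for t in range(n_states)), s)
        for s in range(n_states)
    )
    total, root_state = best
    labels = {}

    def down(node, state):
        labels[node if isinstance(node, int) else id(node)] = state
        if isinstance(node, int):
            return
        for child in node:
            cv = vecs[child if isinstance(child, int) else id(child)]
            t = min(range(n_states), key=lambda t: (cv[t] + D[state][t], t))
            down(child, t)

    down(structure, root_state)
    leaf0_state = min(
        range(n_states),
        key=lambda t: (root_leaf_vec[t] + D[root_state][t], t),
    )
    return total, labels, root_state, leaf0_state


@dataclass
class TreeScore:
    total_events: int
    origins: dict[str, int]
    #: edge -> list of (inversion, new_state); edges keyed by the child
    #: clade's sorted leaf-name tuple ("()" root edge joins the outgroup)
    edge_events: dict[tuple[str, ...], list[tuple[str, str]]]
    #: node labels: clade leaf tuple -> ArrangementStates-like dict
    node_states: dict[tuple[str, ...], dict[str, str]]


def score_tree(
    topology: TreeTopology,
    matrix: KaryotypeMatrix,
    catalog: InversionCatalog,
    model: CharacterModel | None = None,
) -> TreeScore:
    """Minimum total inversion-fixation events on one topology.

    Returns the event total, per-inversion origin counts in a
    deterministic minimum-event labeling, and per-edge event placements.
    Overlap groups are charged shortest valid flip trajectories; the
    events on an edge are the flips of that trajectory.
    """
    if model is None:
        model = compile_characters(catalog)
    leaves = topology.leaves
    matrix_order = {t: i for i, t in enumerate(leaves)}
    if set(matrix.taxa) != set(leaves):
        raise ValueError("topology leaves do not match matrix taxa")

    def clade(node) -> tuple[str, ...]:
        if isinstance(node, int):
            return (leaves[node],)
        return tuple(sorted(clade(node[0]) + clade(node[1])))

    node_assign: dict[object, dict[str, str]] = {}

    def set_state(node, name, value):
        key = node if isinstance(node, int) else id(node)
        node_assign.setdefault(key, {})[name] = value

    total = 0
    # binary characters: Fitch with deterministic refinement, rooted at leaf 0
    for name in model.binary:
        leaf_sets = []
        for t in leaves:
            s = matrix.states[t].state(name)
            leaf_sets.append({STANDARD, INVERTED} if s == UNKNOWN else {s})
        sets, root_set, changes = _fitch_sets(topology.structure, leaf_sets)
        total += changes
        inter0 = leaf_sets[0] & root_set
        out_state = min(inter0) if inter0 else min(root_set)
        labels = _fitch_labeling(topology.structure, leaf_sets, out_state)
        labels[0] = out_state if out_state in leaf_sets[0] else min(leaf_sets[0])
        for key, st in labels.items():
            node_assign.setdefault(key, {})[name] = st

    group_labels = []
    for g, glv in zip(model.groups,
                      [_leaf_group_vectors(matrix, g, leaves) for g in model.groups]):
        D = tuple(tuple(int(x) for x in row) for row in g.dist)
        gtotal, labels, root_state, leaf0_state = _sankoff_labeling(
            topology.structure, glv, D, glv[0]
        )
        total += gtotal
        labels[0] = leaf0_state
        group_labels.append(labels)
        for key, idx in labels.items():
            for bit, nm in enumerate(g.inversions):
                node_assign.setdefault(key, {})[nm] = (
                    INVERTED if idx >> bit & 1 else STANDARD
                )

    # per-edge events from the labeling
    origins = {inv.name: 0 for inv in catalog.inversions}
    edge_events: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    node_states: dict[tuple[str, ...], dict[str, str]] = {}

    def key_of(node):
        return node if isinstance(node, int) else id(node)

    def walk(node, parent_key):
        ckey = key_of(node)
        node_states[clade(node)] = dict(node_assign[ckey])
        events: list[tuple[str, str]] = []
        for name in model.binary:
            a, b = node_assign[parent_key][name], node_assign[ckey][name]
            if a != b:
                events.append((name, b))
                origins[name] += 1
        for g, labels in zip(model.groups, group_labels):
            pa, ch = labels[parent_key], labels[ckey]
            path = g.paths[(pa, ch)]
            for s0, s1 in zip(path, path[1:]):
                bit = (s0 ^ s1).bit_length() - 1
                nm = g.inversions[bit]
                events.append((nm, INVERTED if s1 >> bit & 1 else STANDARD))
                origins[nm] += 1
        if events:
            edge_events[clade(node)] = events
        if not isinstance(node, int):
            walk(node[0], ckey)
            walk(node[1], ckey)

    root_key = key_of(topology.structure)
    node_states[("root",)] = dict(node_assign[root_key])
    # outgroup leaf hangs off the root edge
    walk(0, root_key)
    if not isinstance(topology.structure, int):
        walk(topology.structure[0], root_key)
        walk(topology.structure[1], root_key)

    origins = {k: int(v) for k, v in origins.items() if v > 0}
    return TreeScore(int(total), origins, edge_events, node_states)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    scenario: str
    total_events: int
    best_topologies: list[TreeTopology]
    origins: dict[str, int]
    edge_events: dict[tuple[str, ...], list[tuple[str, str]]]
    node_states: dict[tuple[str, ...], dict[str, str]]
    all_single_origin: bool = field(init=False)

    def __post_init__(self) -> None:
        self.all_single_origin = all(v == 1 for v in self.origins.values())

    def newicks(self) -> list[str]:
        return [t.canonical_newick() for t in self.best_topologies]


@dataclass
class ScenarioComparison:
    results: list[ScenarioResult]
    winners: list[str]

    @property
    def winner(self) -> str | None:
        return self.winners[0] if len(self.winners) == 1 else None


def best_scenario(
    matrix: KaryotypeMatrix,
    x_state_options: Sequence[str] = X_STATE_OPTIONS,
    catalog: InversionCatalog | None = None,
) -> ScenarioComparison:
    """Score the matrix under each hypothetical outgroup X arrangement.

    The winner is the scenario whose minimum-event optimum has every
    inversion originating exactly once; ties are reported, never broken
    silently.
    """
    if not x_state_options:
        raise ValueError("x_state_options must be non-empty")
    if catalog is None:
        catalog = gambiae_complex_catalog()
    model = compile_characters(catalog)
    results = []
    for option in x_state_options:
        m = matrix.with_outgroup_states(
            outgroup_states(option, species=matrix.outgroup)
        )
        best, topos = _scan(m, catalog, model)
        detail = score_tree(topos[0], m, catalog, model)
        assert detail.total_events == best
        results.append(
            ScenarioResult(option, best, topos, detail.origins,
                           detail.edge_events, detail.node_states)
        )
    winners = [r.scenario for r in results if r.all_single_origin]
    return ScenarioComparison(results, winners)


def search_best_topologies(
    matrix: KaryotypeMatrix, catalog: InversionCatalog,
    model: CharacterModel | None = None,
) -> tuple[int, list[TreeTopology]]:
    """Exhaustive minimum-event topologies for a matrix as given."""
    if model is None:
        model = compile_characters(catalog)
    return _scan(matrix, catalog, model)


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

@dataclass
class RootedTree:
    """Outgroup-rooted topology with per-edge event placements."""

    topology: TreeTopology
    outgroup: str
    score: TreeScore

    def newick(self) -> str:
        return self.topology.canonical_newick()


def root_tree(
    topology: TreeTopology,
    outgroup_label: str,
    matrix: KaryotypeMatrix,
    catalog: InversionCatalog,
) -> RootedTree:
    """Root on the outgroup edge and attach minimum-event placements."""
    if outgroup_label not in topology.leaves:
        raise ValueError(f"outgroup {outgroup_label!r} is not a leaf")
    if topology.leaves[0] != outgroup_label:
        # re-root: rebuild with the outgroup as leaf 0
        leaves = [outgroup_label] + [t for t in topology.leaves if t != outgroup_label]
        adj = _adjacency(topology)
        structure = _reroot(adj, topology.leaves, leaves)
        topology = TreeTopology(tuple(leaves), structure)
    score = score_tree(topology, matrix, catalog)
    return RootedTree(topology, outgroup_label, score)


def _adjacency(topology: TreeTopology):
    """Unrooted adjacency over leaf names and internal node ids."""
    adj: dict[object, list[object]] = {}

    def add(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    counter = itertools.count()

    def build(node):
        if isinstance(node, int):
            return topology.leaves[node]
        nid = ("i", next(counter))
        add(nid, build(node[0]))
        add(nid, build(node[1]))
        return nid

    top = build(topology.structure)
    add(topology.leaves[0], top)
    return adj


def _reroot(adj, old_leaves, new_leaves):
    """Nested structure over new_leaves[1:] rooted at new_leaves[0]'s edge."""
    index = {name: i for i, name in enumerate(new_leaves)}
    root_leaf = new_leaves[0]

    def build(node, parent):
        if isinstance(node, str):
            return index[node]
        kids = [k for k in adj[node] if k != parent]
        assert len(kids) == 2
        return (build(kids[0], node), build(kids[1], node))

    start = adj[root_leaf][0]
    return build(start, root_leaf)
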