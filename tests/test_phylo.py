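"""Scenario trees: topology enumeration, parsimony scoring, rooting."""

import itertools

import numpy as np
import pytest

from inversionkit.catalog import (
    INVERTED,
    STANDARD,
    ArrangementStates,
    OUTGROUP,
)
from inversionkit.phylo import (
    KaryotypeMatrix,
    TooManyTaxaError,
    TreeTopology,
    best_scenario,
    compile_characters,
    complex_matrix,
    enumerate_unrooted_topologies,
    root_tree,
    score_tree,
    search_best_topologies,
)
from inversionkit.simulate import simulate_inversion_history, synthetic_binary_catalog


class TestTopologies:
    @pytest.mark.parametrize("n,count", [(4, 3), (5, 15), (6, 105), (8, 10395)])
    def test_topology_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        topos = enumerate_unrooted_topologies(taxa)
        assert len(topos) == count
        assert len({t.canonical_newick() for t in topos}) == count

    def test_guard(self):
        with pytest.raises(TooManyTaxaError):
            enumerate_unrooted_topologies([f"t{i}" for i in range(9)])


def _true_complex_topology():
    """(out,(merus,(gambiae,(arab,((qA,qB),(bwa,melas))))))."""
    m = complex_matrix("Xag")
    taxa = [m.outgroup] + [t for t in m.taxa if t != m.outgroup]
    idx = {t: i for i, t in enumerate(taxa)}
    qa, qb = idx["An. quadriannulatus A"], idx["An. quadriannulatus B"]
    bw, me = idx["An. bwambae"], idx["An. melas"]
    structure = (idx["An. merus"],
                 (idx["An. gambiae"],
                  (idx["An. arabiensis"], ((qa, qb), (bw, me)))))
    return m, TreeTopology(tuple(taxa), structure)


class TestScoreTree:
    def test_true_topology_under_xag_needs_ten_single_origin_events(self, catalog):
        matrix, topo = _true_complex_topology()
        score = score_tree(topo, matrix, catalog)
        assert score.total_events == 10
        assert score.origins == {name: 1 for name in score.origins}
        assert set(score.origins) == {
            "Xa", "Xg", "Xb", "Xc", "Xd", "2Ro", "2Rp", "2Rm", "2La", "3La",
        }

    def test_x_plus_optimum_doubles_2Ro(self, catalog):
        """Under an all-standard-X outgroup the optimal topology regroups
        merus with gambiae and pays a second origin of 2Ro."""
        m = complex_matrix("X+")
        best, topos = search_best_topologies(m, catalog)
        score = score_tree(topos[0], m, catalog)
        assert score.total_events == best >= 11
        assert score.origins["2Ro"] == 2

    def test_fig_topology_is_suboptimal_under_x_plus(self, catalog):
        """Keeping merus basal while the outgroup X is standard forces the
        Xa/Xg pair to originate twice, costing more than the X+ optimum."""
        _, topo = _true_complex_topology()
        m = complex_matrix("X+")
        best, _ = search_best_topologies(m, catalog)
        score = score_tree(topo, m, catalog)
        assert score.total_events > best
        assert score.origins["Xa"] == score.origins["Xg"] == 2

    def test_identical_leaves_score_zero(self, catalog):
        m0 = complex_matrix("Xag")
        ref = m0.states["An. quadriannulatus A"]
        states = {
            t: ArrangementStates(t, dict(ref.states)) for t in m0.taxa
        }
        m = KaryotypeMatrix(states, m0.outgroup)
        _, topos = search_best_topologies(m, catalog)
        score = score_tree(topos[0], m, catalog)
        assert score.total_events == 0
        assert score.origins == {}

    def test_matches_fitch_brute_force_for_non_overlapping_characters(self):
        """Exhaustive internal-labeling parsimony is the oracle for matrices
        of mutually non-overlapping (independent binary) inversions."""
        rng = np.random.default_rng(11)
        catalog = synthetic_binary_catalog(4)
        names = [i.name for i in catalog.inversions]
        taxa = ["out", "a", "b", "c", "d"]
        for trial in range(5):
            states = {
                t: ArrangementStates(t, {
                    n: (INVERTED if rng.random() < 0.5 else STANDARD)
                    for n in names
                })
                for t in taxa
            }
            matrix = KaryotypeMatrix(states, "out")
            for topo in enumerate_unrooted_topologies(taxa):
                got = score_tree(topo, matrix, catalog).total_events
                assert got == _brute_force_parsimony(topo, matrix, names)


def _brute_force_parsimony(topo, matrix, names):
    """Minimum flips over all internal labelings, one character at a time."""
    internal, edges = [], []

    def build(node):
        if isinstance(node, int):
            return node
        key = id(node)
        internal.append(key)
        edges.append((key, build(node[0])))
        edges.append((key, build(node[1])))
        return key

    top = build(topo.structure)
    edges.append((top, 0))  # the first leaf hangs off the top node

    total = 0
    for name in names:
        lab0 = {i: matrix.states[t].state(name)
                for i, t in enumerate(topo.leaves)}
        best = None
        for assignment in itertools.product([STANDARD, INVERTED],
                                            repeat=len(internal)):
            lab = {**lab0, **dict(zip(internal, assignment))}
            cost = sum(1 for a, b in edges if lab[a] != lab[b])
            best = cost if best is None else min(best, cost)
        total += best
    return total


@pytest.fixture(scope="module")
def comparison():
    return best_scenario(complex_matrix())


class TestBestScenario:
    def test_xag_is_the_unique_winner(self, comparison):
        assert comparison.winners == ["Xag"]

    def test_xag_optimum_is_ten_events(self, comparison):
        xag = next(r for r in comparison.results if r.scenario == "Xag")
        assert xag.total_events == 10
        assert xag.all_single_origin

    def test_alternative_ancestries_force_a_second_2Ro_origin(self, comparison):
        for scen in ("X+", "Xbcd"):
            r = next(x for x in comparison.results if x.scenario == scen)
            assert r.total_events >= 11
            assert r.origins["2Ro"] == 2
            assert not r.all_single_origin

    def test_winning_trees_split_merus_gambiae_basally(self, comparison):
        xag = next(r for r in comparison.results if r.scenario == "Xag")
        for nwk in xag.newicks():
            # reading from the outgroup, merus branches first, then gambiae
            assert nwk.endswith("An. merus));")
            assert "An. gambiae)" in nwk

    def test_two_leaf_matrix_trivial(self, catalog):
        from inversionkit.catalog import outgroup_states, \
            gambiae_complex_karyotypes

        states = {
            "An. merus": gambiae_complex_karyotypes()["An. merus"],
            "o2": outgroup_states("Xag", species="o2"),
            OUTGROUP: outgroup_states("Xag"),
        }
        matrix = KaryotypeMatrix(states, OUTGROUP)
        score, topos = search_best_topologies(matrix, catalog)
        # merus differs from the Xag outgroup by 2Rp only
        assert score == 1

    def test_empty_options_rejected(self):
        with pytest.raises(ValueError):
            best_scenario(complex_matrix(), [])


class TestRootTree:
    def test_rooting_places_melas_terminal(self, catalog):
        matrix, topo = _true_complex_topology()
        rooted = root_tree(topo, OUTGROUP, matrix, catalog)
        # the 2Rm event sits on the melas terminal edge
        assert rooted.score.edge_events[("An. melas",)] == [("2Rm", INVERTED)]

    def test_event_replay_reproduces_leaf_states(self, catalog):
        matrix, topo = _true_complex_topology()
        rooted = root_tree(topo, OUTGROUP, matrix, catalog)
        root_state = dict(rooted.score.node_states[("root",)])

        def replay(node, state):
            clade = (tuple(sorted(_leaves_of(topo, node)))
                     if isinstance(node, tuple) else (topo.leaves[node],))
            for name, new in rooted.score.edge_events.get(clade, []):
                state = dict(state)
                state[name] = new
            if isinstance(node, tuple):
                replay(node[0], state)
                replay(node[1], state)
            else:
                leaf = topo.leaves[node]
                assert state == matrix.states[leaf].states, leaf
        replay(0, root_state)
        replay(topo.structure[0], root_state)
        replay(topo.structure[1], root_state)

    def test_missing_outgroup_rejected(self, catalog):
        matrix, topo = _true_complex_topology()
        with pytest.raises(ValueError, match="not a leaf"):
            root_tree(topo, "nope", matrix, catalog)


def _leaves_of(topo, node):
    if isinstance(node, int):
        return [topo.leaves[node]]
    return _leaves_of(topo, node[0]) + _leaves_of(topo, node[1])


class TestParameterRecovery:
    def test_simulated_single_origin_histories_are_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            matrix, topo, catalog = simulate_inversion_history(rng)
            _, topos = search_best_topologies(matrix, catalog)
            assert len(topos) == 1
            assert topos[0].canonical_newick() == topo.canonical_newick()
            hits += 1
        assert hits == 10

    def test_group_flip_costs_respect_overlap_constraint(self, catalog):
        """The overlapping 2Ro/2Rp pair's transition costs: every elementary
        step costs 1, the joint flip 2, and the impossible p-only-to-both
        route must detour (3 flips)."""
        model = compile_characters(catalog)
        group = next(g for g in model.groups if g.arm == "2R")
        assert group.inversions == ("2Ro", "2Rp")
        o, p = 1, 2  # state bits
        D = group.dist
        assert D[0, o] == D[0, p] == 1
        assert D[o, o | p] == 1
        assert D[0, o | p] == 2
        assert D[p, o | p] == 3
        assert (D == D.T).all()
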