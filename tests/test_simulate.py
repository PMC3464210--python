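"""Synthetic-data generator: determinism, truth replay, accounting."""

import numpy as np
import pytest

from inversionkit.matepair import LibrarySpec
from inversionkit.simulate import (
    AncestralGenome,
    EventTree,
    SimulationConfig,
    build_reference_arms,
    complex_event_tree,
    evolve_karyotypes,
    plant_mite,
    recover_permutation,
    replay_truth,
    simulate_ancestral_genome,
    simulate_inversion_history,
    simulate_matepair_pairs,
    simulate_toy_inversion,
)


class TestAncestralGenome:
    def test_requested_gene_count(self):
        g = simulate_ancestral_genome(SimulationConfig(seed=1, gene_count=100))
        assert len(g.genes) == 100
        assert len(g.sequence) == 500_000

    def test_genes_non_overlapping_and_stranded(self):
        g = simulate_ancestral_genome(SimulationConfig(seed=2, gene_count=80))
        df = g.genes.sort_values("start")
        assert (df.start.values[1:] >= df.end.values[:-1]).all()
        assert set(df.strand) <= {"+", "-"}

    def test_same_seed_reproduces_sequence(self):
        a = simulate_ancestral_genome(SimulationConfig(seed=3))
        b = simulate_ancestral_genome(SimulationConfig(seed=3))
        assert a.sequence == b.sequence
        assert a.genes.equals(b.genes)

    def test_infeasible_density_rejected(self):
        cfg = SimulationConfig(seed=4, genome_length=10_000, gene_count=100,
                               gene_length_range=(500, 600))
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_ancestral_genome(cfg)


@pytest.fixture(scope="module")
def evolved(catalog):
    rng = np.random.default_rng(9)
    arms = build_reference_arms(catalog, segment_length=1500, rng=rng)
    tree, root = complex_event_tree()
    genomes, truth = evolve_karyotypes(arms, tree, catalog, root_states=root,
                                       junction_gap=0, rng=rng)
    return arms, genomes, truth


class TestEvolveKaryotypes:
    def test_quadriannulatus_sisters_share_a_genome(self, evolved):
        _, genomes, _ = evolved
        qa = genomes["An. quadriannulatus A"].arms
        qb = genomes["An. quadriannulatus B"].arms
        assert qa == qb
        distinct = {tuple(g.arms[a] for a in sorted(g.arms))
                    for g in genomes.values()}
        assert len(distinct) == 7  # 8 leaves, one pair identical

    def test_anchor_order_recovers_encoded_permutations(self, evolved):
        arms, genomes, truth = evolved
        for sp, g in genomes.items():
            for arm, ref in arms.items():
                rec = recover_permutation(ref, g.arms[arm])
                assert rec.elements == truth.permutations[sp][arm].elements

    def test_truth_replay_is_byte_identical(self, evolved):
        _, genomes, truth = evolved
        replayed = replay_truth(truth)
        for sp, g in genomes.items():
            assert replayed[sp] == g.arms

    def test_pairwise_distances_match_engine(self, evolved, catalog):
        from inversionkit.rearrange import pairwise_distance_matrix

        _, _, truth = evolved
        dm = pairwise_distance_matrix(truth.permutations)
        assert dm[("An. gambiae", "An. merus")] == 2
        assert dm[("An. quadriannulatus A", "An. quadriannulatus B")] == 0
        assert dm[("outgroup", "An. merus")] == 1   # 2Rp only

    def test_empty_event_set_gives_identical_genomes(self, catalog):
        rng = np.random.default_rng(10)
        arms = build_reference_arms(catalog, segment_length=1000, rng=rng)
        tree = EventTree("root", (), (EventTree("a"), EventTree("b")))
        genomes, _ = evolve_karyotypes(arms, tree, catalog, rng=rng)
        assert genomes["a"].arms == genomes["b"].arms

    def test_invalid_trajectory_names_the_step(self, catalog):
        rng = np.random.default_rng(11)
        arms = build_reference_arms(catalog, segment_length=1000, rng=rng)
        # starting from all-standard, undoing p after entering the
        # both-inverted arrangement is geometrically impossible
        tree = EventTree("root", (), (
            EventTree("bad", ("2Ro", "2Rp", "2Ro")),
        ))
        with pytest.raises(ValueError, match="event 2"):
            evolve_karyotypes(arms, tree, catalog, rng=rng)

    def test_junction_gaps_inserted_at_novel_junctions(self, catalog):
        rng = np.random.default_rng(12)
        arms = build_reference_arms(catalog, segment_length=1000, rng=rng)
        tree = EventTree("root", (), (EventTree("sp", ("2La",)),))
        genomes, truth = evolve_karyotypes(arms, tree, catalog,
                                           junction_gap=500, rng=rng)
        g = genomes["sp"]
        assert len(g.novel_junctions["2L"]) == 2
        assert len(g.arms["2L"]) == len(arms["2L"].sequence) + 1000


class TestMatePairs:
    def test_pair_count_formula(self):
        rng = np.random.default_rng(13)
        genome = "ACGT" * 5000
        lib = LibrarySpec("mp2k", 2000, 0.0)
        pairs = simulate_matepair_pairs(genome, lib, 12, rng)
        # ceil(12 * 20000 / 72)
        assert len(pairs) == 3334

    def test_zero_coverage_zero_pairs(self):
        rng = np.random.default_rng(14)
        lib = LibrarySpec("mp2k", 2000, 0.0)
        assert simulate_matepair_pairs("ACGT" * 5000, lib, 0, rng) == []

    def test_mean_insert_tracks_spec_within_one_percent(self):
        from inversionkit._seq import random_dna, revcomp

        rng = np.random.default_rng(15)
        genome = random_dna(60_000, rng)
        lib = LibrarySpec("mp3k", 3000, 300.0)
        pairs = simulate_matepair_pairs(genome, lib, 120, rng)
        assert len(pairs) >= 100_000
        # measure observed inserts by re-locating a read subsample
        spans = []
        for _, r1, r2 in pairs[:3000]:
            s1 = genome.find(r1)
            s2 = genome.find(revcomp(r2))
            if s1 < 0 or s2 < 0:
                continue
            spans.append(s2 + 36 - s1)
        assert len(spans) > 2500
        mean = float(np.mean(spans))
        assert abs(mean - 3000) / 3000 < 0.01

    def test_insert_longer_than_genome_rejected(self):
        rng = np.random.default_rng(16)
        lib = LibrarySpec("mp5k", 5000, 0.0)
        with pytest.raises(ValueError):
            simulate_matepair_pairs("ACGT" * 100, lib, 5, rng)


class TestPlantMite:
    def test_length_accounting_identity(self, rng):
        from inversionkit._seq import random_dna

        genome = random_dna(50_000, rng)
        for copies, elen, tsd in [(5, 200, 3), (3, 400, 0), (8, 150, 7)]:
            g2, _, recs = plant_mite(genome, elen, tsd, copies, rng)
            assert len(g2) == len(genome) + copies * (elen + tsd)
            assert len(recs) == copies

    def test_flanking_duplications_present(self, rng):
        from inversionkit._seq import random_dna

        genome = random_dna(30_000, rng)
        g2, elem, recs = plant_mite(genome, 250, 3, 6, rng)
        for r in recs:
            assert g2[r.start - 3: r.start] == g2[r.end: r.end + 3] == r.tsd
            assert len(r.tsd) == 3

    def test_zero_tsd_plants_without_duplication(self, rng):
        from inversionkit._seq import random_dna

        genome = random_dna(30_000, rng)
        g2, elem, recs = plant_mite(genome, 250, 0, 4, rng)
        assert len(g2) == len(genome) + 4 * 250
        for r in recs:
            assert r.tsd == ""

    def test_oversized_element_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_mite("ACGTACGT", 100, 3, 1, rng)


class TestHistorySimulation:
    def test_every_inversion_originates_once(self):
        rng = np.random.default_rng(17)
        matrix, topo, catalog = simulate_inversion_history(rng, n_inversions=10)
        # single-origin: each inversion's inverted taxa form one clade of
        # the generating topology (checked via parsimony score = count)
        from inversionkit.phylo import score_tree

        score = score_tree(topo, matrix, catalog)
        present = matrix.present_inversions(catalog)
        assert score.total_events == len(present)
        assert all(v == 1 for v in score.origins.values())

    def test_toy_inversion_structure(self):
        rng = np.random.default_rng(18)
        toy = simulate_toy_inversion(rng, flank_length=500, block_length=800,
                                     junction_gap=100)
        from inversionkit._seq import revcomp

        b1, b2 = toy.breakpoints
        assert toy.derived[:b1] == toy.reference[:b1]
        assert toy.derived[b1 + 100: b1 + 100 + (b2 - b1)] == \
            revcomp(toy.reference[b1:b2])
        assert len(toy.derived) == len(toy.reference) + 200
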