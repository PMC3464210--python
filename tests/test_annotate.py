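"""Annotator: ancestry calls, region arithmetic, repeat/TSD procedure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inversionkit._seq import random_dna, revcomp
from inversionkit.annotate import (
    AdjacencyObservation,
    BreakpointRegion,
    UNRESOLVED,
    compare_region_sizes,
    define_element_boundaries,
    discover_repeat_candidate,
    element_spans,
    find_repeat_copies,
    infer_arrangement_state,
    infer_arrangement_states,
    region_length,
)
from inversionkit.catalog import INVERTED, STANDARD
from inversionkit.simulate import plant_mite


class TestRegionArithmetic:
    @pytest.mark.parametrize("start,end,length", [
        (9_485_167, 9_486_712, 1_546),    # distal breakpoint region
        (29_838_366, 29_839_163, 798),    # proximal breakpoint region
        (5, 5, 1),
    ])
    def test_printed_span_lengths(self, start, end, length):
        assert region_length(BreakpointRegion("AgamP3", start, end)) == length

    def test_reversed_coordinates_rejected(self):
        with pytest.raises(ValueError):
            BreakpointRegion("x", 10, 9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 10**8), st.integers(0, 10**6))
    def test_coordinate_convention_round_trip(self, start, extra):
        region = BreakpointRegion("x", start, start + extra)
        s0, e0 = region.to_half_open()
        back = BreakpointRegion.from_half_open("x", s0, e0)
        assert back == region
        assert e0 - s0 == region.length

    @pytest.mark.parametrize("a,b,ratio", [
        (1546, 595, 2.6),
        (10, 5, 2.0),
        (798, 798, 1.0),
    ])
    def test_fold_ratios(self, a, b, ratio):
        assert compare_region_sizes(a, b) == ratio

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            compare_region_sizes(10, 0)


class TestArrangementCalls:
    def test_outgroup_cross_junctions_call_inverted(self, catalog):
        obs = [
            AdjacencyObservation("An. stephensi", "AGAP001760", "AGAP002933"),
            AdjacencyObservation("An. stephensi", "AGAP001762", "AGAP002935"),
        ]
        call = infer_arrangement_state(obs, catalog.get("2Ro"), catalog)
        assert call.state == INVERTED and not call.conflict

    def test_reference_adjacencies_call_standard(self, catalog):
        obs = [
            AdjacencyObservation("An. gambiae", "AGAP001983", "AGAP001984"),
            AdjacencyObservation("An. gambiae", "AGAP003327", "AGAP003328"),
        ]
        call = infer_arrangement_state(obs, catalog.get("2Rp"), catalog)
        assert call.state == STANDARD

    def test_split_scaffolds_stay_unresolved(self, catalog):
        obs = [
            AdjacencyObservation("Aedes", "AGAP001983", "AGAP001984"),
            AdjacencyObservation("Aedes", "AGAP003327", "AGAP003328",
                                 same_scaffold=False),
        ]
        call = infer_arrangement_state(obs, catalog.get("2Rp"), catalog)
        assert call.state == UNRESOLVED
        assert "scaffold" in call.reason

    def test_ortholog_adjacencies_resolve_2la_ancestry(self, catalog):
        orthologs = {
            "CPIJ004936": "AGAP007068", "CPIJ004938": "AGAP005778",
            "CPIJ005693": "AGAP007069", "CPIJ005692": "AGAP005780",
        }
        obs = [
            AdjacencyObservation("Culex", "CPIJ004936", "CPIJ004938"),
            AdjacencyObservation("Culex", "CPIJ005693", "CPIJ005692"),
        ]
        call = infer_arrangement_state(obs, catalog.get("2La"), catalog,
                                       orthologs=orthologs)
        assert call.state == INVERTED

    def test_conflicting_evidence_is_flagged(self, catalog):
        obs = [
            AdjacencyObservation("odd", "AGAP001760", "AGAP001762"),
            AdjacencyObservation("odd", "AGAP002933", "AGAP002935"),
            AdjacencyObservation("odd", "AGAP001760", "AGAP002933"),
            AdjacencyObservation("odd", "AGAP001762", "AGAP002935"),
        ]
        call = infer_arrangement_state(obs, catalog.get("2Ro"), catalog)
        assert call.conflict and call.state == UNRESOLVED

    def test_round_trip_from_junction_models(self, catalog, full_maps):
        """Adjacencies read off any encoded karyotype reproduce the
        generating state for every inversion."""
        from inversionkit.catalog import (
            ArrangementStates, encode_karyotype, junction_adjacencies,
        )

        inverted = {"Xa", "2Ro", "2La"}
        states = ArrangementStates("sim", {
            i.name: (INVERTED if i.name in inverted else STANDARD)
            for i in catalog.inversions
        })
        perms = encode_karyotype(states, full_maps, catalog)
        obs = [
            AdjacencyObservation("sim", a, b)
            for arm, perm in perms.items()
            for a, b in junction_adjacencies(perm, full_maps[arm])
        ]
        calls = infer_arrangement_states(obs, catalog)
        got = dict(zip(calls.inversion, calls.state))
        assert got == states.states

    def test_unresolved_species_excluded_from_voting(self, catalog):
        from inversionkit.annotate import ancestry_vote

        obs = [
            AdjacencyObservation("sp1", "AGAP001760", "AGAP002933"),
            AdjacencyObservation("sp1", "AGAP001762", "AGAP002935"),
            AdjacencyObservation("sp2", "AGAP001760", "AGAP001762",
                                 same_scaffold=False),
        ]
        calls = infer_arrangement_states(obs, catalog, inversions=["2Ro"])
        votes = ancestry_vote(calls, "2Ro")
        assert votes == {INVERTED: 1}


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(77)
    genome = random_dna(150_000, rng)
    genome, element, records = plant_mite(genome, 350, 3, 15, rng)
    return genome, element, records


class TestRepeatCopies:
    def test_all_planted_copies_found(self, planted):
        genome, element, records = planted
        copies = find_repeat_copies(element, genome, min_length=100)
        assert len(copies) == len(records)
        truth = sorted((r.start, r.end) for r in records)
        for c, (ts, te) in zip(copies, truth):
            assert abs(c.start - ts) <= 2 and abs(c.end - te) <= 2

    def test_absent_candidate_finds_nothing(self, planted):
        genome, _, _ = planted
        rng = np.random.default_rng(99)
        assert find_repeat_copies(random_dna(300, rng), genome) == []

    def test_single_exact_copy(self):
        rng = np.random.default_rng(3)
        genome = random_dna(30_000, rng)
        candidate = genome[5000:5400]
        copies = find_repeat_copies(candidate, genome, min_length=100)
        assert len(copies) == 1
        assert (copies[0].start, copies[0].end, copies[0].strand) == \
            (5000, 5400, "+")


class TestElementBoundaries:
    def test_tsd_three_recovered(self, planted):
        genome, element, records = planted
        copies = find_repeat_copies(element, genome, min_length=100)
        model = define_element_boundaries(genome, copies)
        assert model.tsd_length == 3
        assert len(model.consensus) == 350

    def test_boundaries_within_one_bp(self, planted):
        genome, element, records = planted
        copies = find_repeat_copies(element, genome, min_length=100)
        model = define_element_boundaries(genome, copies)
        spans = element_spans(genome, model)
        truth = sorted((r.start, r.end) for r in records)
        assert len(spans) == len(truth)
        for (a, b), (ta, tb) in zip(spans, truth):
            assert abs(a - ta) <= 1 and abs(b - tb) <= 1

    def test_no_duplication_gives_tsd_zero(self):
        rng = np.random.default_rng(21)
        genome = random_dna(80_000, rng)
        genome, element, _ = plant_mite(genome, 300, 0, 10, rng)
        copies = find_repeat_copies(element, genome, min_length=100)
        model = define_element_boundaries(genome, copies)
        assert model.tsd_length == 0

    def test_invariant_to_copy_order_and_strand(self, planted):
        genome, element, records = planted
        copies = find_repeat_copies(element, genome, min_length=100)
        model_fwd = define_element_boundaries(genome, copies)
        shuffled = list(reversed(copies))
        model_rev = define_element_boundaries(genome, shuffled)
        assert model_rev.tsd_length == model_fwd.tsd_length
        assert sorted(element_spans(genome, model_rev)) == \
            sorted(element_spans(genome, model_fwd))
        # searching with the reverse-complement candidate flips reported
        # strands but not the inferred element model
        rc_copies = find_repeat_copies(revcomp(element), genome, min_length=100)
        model_rc = define_element_boundaries(genome, rc_copies)
        assert model_rc.tsd_length == model_fwd.tsd_length

    def test_fewer_than_two_copies_rejected(self, planted):
        genome, element, _ = planted
        copies = find_repeat_copies(element, genome, min_length=100)
        with pytest.raises(ValueError):
            define_element_boundaries(genome, copies[:1])


class TestDiscovery:
    def test_truth_blind_candidate_supports_full_recovery(self, planted):
        genome, element, records = planted
        candidate = discover_repeat_candidate(genome)
        copies = find_repeat_copies(candidate, genome, min_length=100)
        model = define_element_boundaries(genome, copies)
        assert model.tsd_length == 3
        assert len(model.consensus) == 350
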