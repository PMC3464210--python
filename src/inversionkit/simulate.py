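"""Synthetic genomes, karyotype histories, mate-pair libraries and MITEs.

Everything the analysis consumes can be generated here with
machine-readable truth records: a random ancestral genome with gene
annotations, per-species genomes produced by playing inversion events
along a tree (with optional novel "breakpoint region" sequence at
derived junctions, emulating transposable-element accumulation),
mate-pair read sets with configurable insert geometry, and MITE
insertions with direct target-site duplications.

All randomness flows through :class:`numpy.random.Generator` objects,
so a fixed seed reproduces every byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp
from .catalog import (
    INVERTED,
    STANDARD,
    ArrangementStates,
    Breakpoint,
    InversionCatalog,
    InversionDef,
    SignedPermutation,
    build_segment_map,
    encode_arm,
    validate_trajectory,
)
from .matepair import LibrarySpec, default_libraries

ANCHOR_LENGTH = 36


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic pipeline."""

    seed: int
    genome_length: int = 500_000
    gene_count: int = 100
    gene_length_range: tuple[int, int] = (500, 3000)
    segment_length: int = 50_000
    junction_gap: int = 0
    libraries: tuple[LibrarySpec, ...] = field(default_factory=default_libraries)
    coverage: float = 30.0
    mite_length: int = 350
    mite_copies: int = 15
    mite_tsd_length: int = 3

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# ancestral genome
# ---------------------------------------------------------------------------

@dataclass
class AncestralGenome:
    sequence: str
    genes: pd.DataFrame  # BED-like: start, end, name, strand


def simulate_ancestral_genome(config: SimulationConfig,
                              rng: np.random.Generator | None = None) -> AncestralGenome:
    """Random genome with non-overlapping genes on both strands."""
    rng = config.rng() if rng is None else rng
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1,
                           size=config.gene_count)
    slack = config.genome_length - int(lengths.sum())
    if slack < 0:
        raise ValueError("genes cannot fit in the genome length")
    cuts = np.sort(rng.integers(0, slack + 1, size=config.gene_count))
    starts = cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
    strands = np.where(rng.random(config.gene_count) < 0.5, "+", "-")
    genes = pd.DataFrame({
        "start": starts.astype(int),
        "end": (starts + lengths).astype(int),
        "name": [f"gene{i:04d}" for i in range(config.gene_count)],
        "strand": strands,
    })
    return AncestralGenome(random_dna(config.genome_length, rng), genes)


# ---------------------------------------------------------------------------
# karyotype evolution on a tree
# ---------------------------------------------------------------------------

@dataclass
class ArmGenome:
    """One arm's reference sequence with its segment/anchor layout."""

    arm: str
    sequence: str
    #: reference coordinate of each interior segment boundary
    boundary_coords: tuple[int, ...]
    #: anchor gene id -> (start, end) in the reference
    anchor_coords: dict[str, tuple[int, int]]
    segment_length: int


def build_reference_arms(
    catalog: InversionCatalog,
    segment_length: int = 50_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, ArmGenome]:
    """Reference (all-standard) arm sequences realizing a catalog's layout.

    Each segment is random DNA; the gene anchors flanking every interior
    boundary occupy the terminal 36-mers of the adjacent segments, so
    unique 36-bp reads can anchor each junction.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    arms = {}
    for arm in catalog.arms:
        smap = build_segment_map(catalog, arm)
        seq = random_dna(segment_length * smap.n, rng)
        coords = tuple(segment_length * i for i in range(1, smap.n))
        anchors: dict[str, tuple[int, int]] = {}
        for i, bp in enumerate(smap.boundaries, start=1):
            c = coords[i - 1]
            anchors[bp.telomeric_gene] = (c - ANCHOR_LENGTH, c)
            anchors[bp.centromeric_gene] = (c, c + ANCHOR_LENGTH)
        arms[arm] = ArmGenome(arm, seq, coords, anchors, segment_length)
    return arms


@dataclass
class EventTree:
    """A rooted tree whose edges carry inversion flip events."""

    name: str
    events: tuple[str, ...] = ()
    children: tuple["EventTree", ...] = ()

    def leaves(self) -> list["EventTree"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class SpeciesGenome:
    species: str
    arms: dict[str, str]
    permutations: dict[str, SignedPermutation]
    #: per arm, derived-coordinate junction intervals carrying novel sequence
    novel_junctions: dict[str, list[tuple[int, int]]]


@dataclass
class TruthRecord:
    """Everything needed to replay and verify a simulated history."""

    tree: EventTree
    states: dict[str, ArrangementStates]
    permutations: dict[str, dict[str, SignedPermutation]]
    #: species -> arm -> ordered novel junction gap sequences
    gap_sequences: dict[str, dict[str, list[str]]]
    reference_arms: dict[str, ArmGenome]


def _arm_sequence_for_perm(
    ref: ArmGenome,
    perm: SignedPermutation,
    gaps: list[str],
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate oriented segments, inserting gap sequence at novel junctions."""
    L = ref.segment_length
    pieces = []
    novel = []
    ref_adjacent = set(range(1, perm.n))  # reference junction after segment i
    gap_iter = iter(gaps)
    offset = 0
    for k, e in enumerate(perm.elements):
        s = abs(e)
        seg = ref.sequence[(s - 1) * L: s * L]
        if e < 0:
            seg = revcomp(seg)
        if k > 0:
            prev = perm.elements[k - 1]
            is_reference_junction = (prev > 0 and e > 0 and abs(prev) + 1 == s)
            if not is_reference_junction:
                gap = next(gap_iter, "")
                if gap:
                    novel.append((offset, offset + len(gap)))
                    pieces.append(gap)
                    offset += len(gap)
        pieces.append(seg)
        offset += len(seg)
    return "".join(pieces), novel


def _count_novel_junctions(perm: SignedPermutation) -> int:
    n = 0
    for prev, e in zip(perm.elements, perm.elements[1:]):
        if not (prev > 0 and e > 0 and abs(prev) + 1 == abs(e)):
            n += 1
    return n


def evolve_karyotypes(
    reference_arms: Mapping[str, ArmGenome],
    tree: EventTree,
    catalog: InversionCatalog,
    root_states: ArrangementStates | None = None,
    junction_gap: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, SpeciesGenome], TruthRecord]:
    """Play inversion events along a tree; emit leaf genomes plus truth.

    Every edge's events must form a valid flip trajectory from the
    parent's arrangement (checked; a violating step aborts with the step
    named).  Leaf genomes are the reference segments reordered by each
    leaf's signed permutations, with ``junction_gap`` bases of novel
    sequence inserted at every non-reference junction.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    maps = {arm: build_segment_map(catalog, arm) for arm in catalog.arms}
    if root_states is None:
        root_states = ArrangementStates(
            "root", {inv.name: STANDARD for inv in catalog.inversions}
        )

    leaf_states: dict[str, ArrangementStates] = {}

    def walk(node: EventTree, states: ArrangementStates) -> None:
        current = states
        for i, ev in enumerate(node.events):
            name = catalog.get(ev).name
            nxt_states = dict(current.states)
            nxt_states[name] = INVERTED if current.states[name] == STANDARD else STANDARD
            nxt = ArrangementStates(node.name, nxt_states)
            report = validate_trajectory([current, nxt], maps, catalog)
            if not report.valid:
                raise ValueError(
                    f"edge to {node.name!r}, event {i} ({ev}): invalid step: "
                    f"{report.detail}"
                )
            current = nxt
        if not node.children:
            leaf_states[node.name] = ArrangementStates(node.name, dict(current.states))
        for child in node.children:
            walk(child, current)

    walk(tree, root_states)

    genomes: dict[str, SpeciesGenome] = {}
    perms_rec: dict[str, dict[str, SignedPermutation]] = {}
    gaps_rec: dict[str, dict[str, list[str]]] = {}
    for species, states in leaf_states.items():
        arm_seqs: dict[str, str] = {}
        arm_perms: dict[str, SignedPermutation] = {}
        arm_novel: dict[str, list[tuple[int, int]]] = {}
        gaps_rec[species] = {}
        for arm, ref in reference_arms.items():
            perm = encode_arm(states, maps[arm], catalog, arm)
            gaps = [
                random_dna(junction_gap, rng) if junction_gap else ""
                for _ in range(_count_novel_junctions(perm))
            ]
            seq, novel = _arm_sequence_for_perm(ref, perm, gaps)
            arm_seqs[arm] = seq
            arm_perms[arm] = perm
            arm_novel[arm] = novel
            gaps_rec[species][arm] = gaps
        genomes[species] = SpeciesGenome(species, arm_seqs, arm_perms, arm_novel)
        perms_rec[species] = arm_perms
    truth = TruthRecord(tree, leaf_states, perms_rec, gaps_rec,
                        dict(reference_arms))
    return genomes, truth


def replay_truth(truth: TruthRecord) -> dict[str, dict[str, str]]:
    """Rebuild every recorded genome from the truth record (byte-identical)."""
    out: dict[str, dict[str, str]] = {}
    for species, arm_perms in truth.permutations.items():
        out[species] = {}
        for arm, perm in arm_perms.items():
            seq, _ = _arm_sequence_for_perm(
                truth.reference_arms[arm], perm, list(truth.gap_sequences[species][arm])
            )
            out[species][arm] = seq
    return out


def recover_permutation(ref: ArmGenome, derived: str) -> SignedPermutation:
    """Read a derived arm's permutation off its anchor order (round-trip check)."""
    L = ref.segment_length
    n = len(ref.boundary_coords) + 1
    marks = []
    for s in range(1, n + 1):
        head = ref.sequence[(s - 1) * L: (s - 1) * L + ANCHOR_LENGTH]
        fwd = derived.find(head)
        rev = derived.find(revcomp(head))
        if fwd >= 0:
            marks.append((fwd, s))
        elif rev >= 0:
            marks.append((rev, -s))
        else:
            raise ValueError(f"segment {s} not found in derived arm")
    marks.sort()
    return SignedPermutation(ref.arm, tuple(e for _, e in marks))


def complex_event_tree() -> tuple[EventTree, ArrangementStates]:
    """The complex's accepted history as an event tree plus root karyotype.

    The root is the inferred ancestral karyotype (Xag, 2Ro and 2La
    inverted); the outgroup leaf carries no further events.
    """
    tree = EventTree("root", (), (
        EventTree("outgroup"),
        EventTree("ingroup", (), (
            EventTree("An. merus", ("2Rp",)),
            EventTree("gambiae+", ("2Ro",), (
                EventTree("An. gambiae"),
                EventTree("arabiensis+", ("Xa", "Xg"), (
                    EventTree("An. arabiensis", ("Xb", "Xc", "Xd")),
                    EventTree("quad+", ("2La",), (
                        EventTree("An. quadriannulatus A"),
                        EventTree("An. quadriannulatus B"),
                        EventTree("bwambae+", ("3La",), (
                            EventTree("An. bwambae"),
                            EventTree("An. melas", ("2Rm",)),
                        )),
                    )),
                )),
            )),
        )),
    ))
    from .catalog import INVERSION_NAMES

    root = ArrangementStates("root", {
        name: (INVERTED if name in {"Xa", "Xg", "2Ro", "2La"} else STANDARD)
        for name in INVERSION_NAMES
    })
    return tree, root


# ---------------------------------------------------------------------------
# mate-pair libraries
# ---------------------------------------------------------------------------

def simulate_matepair_pairs(
    genome: str,
    lib: LibrarySpec,
    coverage: float,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> list[tuple[str, str, str]]:
    """Error-free (by default) mate pairs at a physical coverage.

    Pair count = ceil(coverage * L / (2 * read_length)); inserts are
    Normal(insert_size, insert_sd) truncated positive (degenerate at the
    nominal size when sd = 0); orientation is forward–reverse.
    """
    L = len(genome)
    rl = lib.read_length
    if lib.insert_size >= L:
        raise ValueError("insert exceeds genome length")
    n_pairs = math.ceil(coverage * L / (2 * rl))
    if n_pairs == 0:
        return []
    if lib.insert_sd > 0:
        inserts = rng.normal(lib.insert_size, lib.insert_sd, size=n_pairs)
        inserts = np.clip(np.rint(inserts), 2 * rl + 1, L - 1).astype(np.int64)
    else:
        inserts = np.full(n_pairs, lib.insert_size, dtype=np.int64)
    starts = rng.integers(0, L - inserts + 1)
    pairs = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        r1 = genome[s: s + rl]
        r2 = revcomp(genome[s + ins - rl: s + ins])
        pairs.append((f"{lib.name}:{i}", r1, r2))
    if error_rate > 0:
        pairs = [
            (pid, _mutate(r1, error_rate, rng), _mutate(r2, error_rate, rng))
            for pid, r1, r2 in pairs
        ]
    return pairs


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    out = list(read)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[rng.integers(0, 4)]
    return "".join(out)


@dataclass
class ToyInversion:
    reference: str
    derived: str
    breakpoints: tuple[int, int]
    junction_gap: int


def simulate_toy_inversion(
    rng: np.random.Generator,
    reference: str | None = None,
    breakpoints: tuple[int, int] | None = None,
    reference_length: int | None = None,
    flank_length: int = 12_000,
    block_length: int = 20_000,
    junction_gap: int = 0,
) -> ToyInversion:
    """A reference and a derived genome differing by one paracentric inversion.

    The derived genome reverse-complements the block between the
    breakpoints and carries ``junction_gap`` bases of novel sequence at
    each junction (the divergent breakpoint regions of a derived
    arrangement).
    """
    if breakpoints is None:
        breakpoints = (flank_length, flank_length + block_length)
        if reference_length is None:
            reference_length = block_length + 2 * flank_length
    if reference is None:
        assert reference_length is not None
        reference = random_dna(reference_length, rng)
    b1, b2 = breakpoints
    if not 0 < b1 < b2 < len(reference):
        raise ValueError("breakpoints outside the reference")
    gap1 = random_dna(junction_gap, rng) if junction_gap else ""
    gap2 = random_dna(junction_gap, rng) if junction_gap else ""
    derived = reference[:b1] + gap1 + revcomp(reference[b1:b2]) + gap2 + reference[b2:]
    return ToyInversion(reference, derived, breakpoints, junction_gap)


# ---------------------------------------------------------------------------
# MITE insertion
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    start: int       # element start in the modified genome (0-based)
    end: int         # element end (half-open)
    strand: str
    tsd: str


def plant_mite(
    genome: str,
    element: str | int,
    tsd_length: int,
    copies: int,
    rng: np.random.Generator,
) -> tuple[str, str, list[PlantedElement]]:
    """Insert copies of one element, duplicating the target site.

    Insertion at site ``s`` duplicates ``genome[s:s+t]``: the element is
    flanked by identical direct repeats of length ``t`` on both sides.
    Returns (modified genome, element consensus, truth records).
    """
    if copies < 1:
        raise ValueError("need at least one copy")
    if isinstance(element, int):
        element = random_dna(element, rng)
    if len(element) > len(genome):
        raise ValueError("element longer than genome")
    # sites spaced so that TSD windows never overlap another insertion
    sites = np.sort(rng.choice(
        np.arange(tsd_length, len(genome) - tsd_length),
        size=copies, replace=False,
    ))
    strands = np.where(rng.random(copies) < 0.5, "+", "-")
    pieces = []
    records = []
    prev = 0
    pos = 0  # cursor in the modified genome
    for s, strand in zip(sites.tolist(), strands.tolist()):
        tsd = genome[s: s + tsd_length]
        ins = element if strand == "+" else revcomp(element)
        # original sequence up to and including the duplicated target site
        pieces.append(genome[prev: s + tsd_length])
        pos += len(pieces[-1])
        pieces.append(ins)
        records.append(PlantedElement(pos, pos + len(ins), strand, tsd))
        pos += len(ins)
        prev = s
    pieces.append(genome[prev:])
    return "".join(pieces), element, records


# ---------------------------------------------------------------------------
# simulated histories for parameter-recovery checks
# ---------------------------------------------------------------------------

def synthetic_binary_catalog(n_inversions: int) -> InversionCatalog:
    """A catalog of mutually non-overlapping inversions on one arm."""
    bps = tuple(
        Breakpoint(f"sim{i}:{end}:tel", f"sim{i}:{end}:cen")
        for i in range(n_inversions) for end in ("d", "p")
    )
    invs = [
        InversionDef(f"inv{i}", "sim",
                     bps[2 * i].anchors, bps[2 * i + 1].anchors,
                     (2 * i + 1, 2 * i + 2))
        for i in range(n_inversions)
    ]
    return InversionCatalog({"sim": bps}, invs)


def simulate_inversion_history(
    rng: np.random.Generator,
    n_ingroup: int = 7,
    n_inversions: int | None = None,
    outgroup: str = "outgroup",
):
    """A random single-origin inversion history on a random binary tree.

    Each inversion originates exactly once; every internal edge carries
    at least one inversion, so the generating topology is the unique
    parsimony optimum.  Returns (matrix, true topology, catalog).
    """
    from .phylo import KaryotypeMatrix, TreeTopology, _structures

    if n_inversions is None:
        n_inversions = int(rng.integers(8, 13))
    shapes = _structures(n_ingroup)
    structure = shapes[int(rng.integers(0, len(shapes)))]
    taxa = [outgroup] + [f"sp{i}" for i in range(1, n_ingroup + 1)]
    topology = TreeTopology(tuple(taxa), structure)

    # collect edges as (node, clade-leaf-set); internal edges first
    internal_edges = []
    all_edges = []

    def walk(node):
        leaves = ({node} if isinstance(node, int)
                  else walk(node[0]) | walk(node[1]))
        all_edges.append(frozenset(leaves))
        if not isinstance(node, int):
            internal_edges.append(frozenset(leaves))
        return leaves

    walk(structure)
    # the edge above the whole structure is the root edge; exclude it from
    # "internal" requirements (it is the outgroup edge)
    internal_edges = [e for e in internal_edges if len(e) < n_ingroup]

    catalog = synthetic_binary_catalog(n_inversions)
    names = [inv.name for inv in catalog.inversions]
    if n_inversions < len(internal_edges):
        raise ValueError("need at least one inversion per internal edge")
    assignment = {}
    for name, edge in zip(names, internal_edges):
        assignment[name] = edge
    rest = names[len(internal_edges):]
    for name in rest:
        assignment[name] = all_edges[int(rng.integers(0, len(all_edges)))]

    states = {}
    for i, taxon in enumerate(taxa):
        inv_set = {n for n, edge in assignment.items() if i in edge}
        states[taxon] = ArrangementStates(taxon, {
            n: (INVERTED if n in inv_set else STANDARD) for n in names
        })
    matrix = KaryotypeMatrix(states, outgroup)
    return matrix, topology, catalog
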