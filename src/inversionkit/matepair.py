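"""Inversion-breakpoint detection from discordant mate pairs.

Mate-pair libraries (2–5 kb inserts, short reads) are mapped back to a
reference assembly; read pairs that align far apart *in the same
orientation* betray an inversion between them, because one read of the
pair falls inside the inverted block.  Clusters of such pairs localize
the two breakpoints, each within at most one insert length.

Mapping is deliberately minimal: a read maps iff it has exactly one
exact occurrence in the reference (either strand), found through a
k-mer seed index.  Multimapping and unplaced reads are flagged and
excluded from calling, which reproduces the behaviour of breakpoints
buried in repeats: no unique pairs, no call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp

READ_LENGTH_DEFAULT = 36

#: classification outcomes
CONCORDANT = "concordant"
INVERSION_DISCORDANT = "inversion_discordant"
DISTANCE_DISCORDANT = "distance_discordant"
UNRESOLVED = "unresolved"

#: mapping statuses
UNIQUE = "unique"
UNMAPPED = "unmapped"
MULTIMAPPED = "multimapped"


@dataclass(frozen=True)
class LibrarySpec:
    """A mate-pair library: long circularized inserts, short paired reads.

    ``expected_orientation`` declares the concordant-pair convention;
    the packaged simulator and classifier both use forward–reverse
    ("fr"), and "same orientation" always means equal mapped strands.
    """

    name: str
    insert_size: int
    insert_sd: float
    read_length: int = READ_LENGTH_DEFAULT
    expected_orientation: str = "fr"

    def __post_init__(self) -> None:
        if self.insert_size <= 2 * self.read_length:
            raise ValueError("insert must exceed two read lengths")
        if self.insert_sd < 0:
            raise ValueError("insert sd must be non-negative")

    def max_insert(self, factor: float = 3.0) -> int:
        return int(round(self.insert_size + factor * self.insert_sd))


def default_libraries(read_length: int = READ_LENGTH_DEFAULT,
                      sd_fraction: float = 0.1) -> tuple[LibrarySpec, ...]:
    """The 2/3/5-kb library mix with 36-bp reads."""
    return tuple(
        LibrarySpec(f"mp{size // 1000}k", size, sd_fraction * size, read_length)
        for size in (2000, 3000, 5000)
    )


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

_MULTI = -1


class ReferenceIndex:
    """Exact-match seed index over one reference sequence.

    Seeds of ``seed_length`` bases locate candidates; a read maps iff the
    full read matches at exactly one place over both strands.  A read
    whose seed is itself non-unique is conservatively flagged multimapped.
    """

    def __init__(self, reference: str, seed_length: int = 20) -> None:
        if not reference:
            raise ValueError("empty reference")
        self.reference = reference
        self.seed_length = seed_length
        index: dict[str, int] = {}
        k = seed_length
        for i in range(len(reference) - k + 1):
            kmer = reference[i:i + k]
            if index.setdefault(kmer, i) != i:
                index[kmer] = _MULTI
        self._index = index

    def _occurrences(self, read: str) -> int | None:
        """Unique match position of ``read`` on the forward strand.

        Returns the position, None for no hit, or _MULTI.
        """
        hit = self._index.get(read[: self.seed_length])
        if hit is None:
            return None
        if hit == _MULTI:
            return _MULTI
        if self.reference[hit: hit + len(read)] == read:
            return hit
        return None

    def map_read(self, read: str) -> tuple[int, str] | str:
        """Map one read; returns (position, strand) or a status flag."""
        if len(read) < self.seed_length:
            raise ValueError("read shorter than seed length")
        fwd = self._occurrences(read)
        rev = self._occurrences(revcomp(read))
        if fwd == _MULTI or rev == _MULTI:
            return MULTIMAPPED
        if fwd is not None and rev is not None:
            return MULTIMAPPED
        if fwd is not None:
            return (fwd, "+")
        if rev is not None:
            return (rev, "-")
        return UNMAPPED


@dataclass
class ReadHit:
    read_id: str
    status: str
    position: int = -1
    strand: str = "."


@dataclass
class PairAlignment:
    """Mapped locations of the two reads of one mate pair."""

    pair_id: str
    library: str
    hit1: ReadHit
    hit2: ReadHit
    category: str = ""

    @property
    def both_unique(self) -> bool:
        return self.hit1.status == UNIQUE and self.hit2.status == UNIQUE

    @property
    def span(self) -> int:
        """Outer distance on the reference (requires both reads mapped)."""
        lo = min(self.hit1.position, self.hit2.position)
        hi = max(self.hit1.position, self.hit2.position)
        return hi - lo


def map_reads(
    reads: Iterable[tuple[str, str]],
    reference: str | ReferenceIndex,
    seed_length: int = 20,
) -> list[ReadHit]:
    """Map (read_id, sequence) records; unique exact matches only."""
    index = (reference if isinstance(reference, ReferenceIndex)
             else ReferenceIndex(reference, seed_length))
    hits = []
    for read_id, seq in reads:
        res = index.map_read(seq)
        if isinstance(res, tuple):
            hits.append(ReadHit(read_id, UNIQUE, res[0], res[1]))
        else:
            hits.append(ReadHit(read_id, res))
    return hits


def map_pairs(
    pairs: Sequence[tuple[str, str, str]],
    index: ReferenceIndex,
    library: LibrarySpec,
) -> list[PairAlignment]:
    """Map (pair_id, read1, read2) triples against an indexed reference."""
    out = []
    for pair_id, r1, r2 in pairs:
        h1, h2 = index.map_read(r1), index.map_read(r2)
        hit1 = (ReadHit(pair_id + "/1", UNIQUE, h1[0], h1[1])
                if isinstance(h1, tuple) else ReadHit(pair_id + "/1", h1))
        hit2 = (ReadHit(pair_id + "/2", UNIQUE, h2[0], h2[1])
                if isinstance(h2, tuple) else ReadHit(pair_id + "/2", h2))
        out.append(PairAlignment(pair_id, library.name, hit1, hit2))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(
    pair: PairAlignment,
    lib: LibrarySpec,
    max_insert_factor: float = 3.0,
) -> str:
    """Classify one mapped pair against the library's insert geometry.

    Same mapped strands -> inversion_discordant; correct forward–reverse
    orientation within insert tolerance -> concordant; correct
    orientation but excessive span -> distance_discordant; anything else
    (including unmapped/multimapped mates) -> unresolved.
    """
    if not pair.both_unique:
        pair.category = UNRESOLVED
        return pair.category
    h1, h2 = pair.hit1, pair.hit2
    if h1.strand == h2.strand:
        pair.category = INVERSION_DISCORDANT
        return pair.category
    left, right = (h1, h2) if h1.position <= h2.position else (h2, h1)
    tol = max_insert_factor * lib.insert_sd
    span = right.position + lib.read_length - left.position
    if left.strand == "+" and right.strand == "-":
        if abs(span - lib.insert_size) <= tol:
            pair.category = CONCORDANT
        elif span > lib.insert_size + tol:
            pair.category = DISTANCE_DISCORDANT
        else:
            pair.category = UNRESOLVED
    else:
        pair.category = UNRESOLVED
    return pair.category


def classify_pairs(
    pairs: Sequence[PairAlignment],
    libs: dict[str, LibrarySpec],
    max_insert_factor: float = 3.0,
) -> None:
    for p in pairs:
        classify_pair(p, libs[p.library], max_insert_factor)


# ---------------------------------------------------------------------------
# clustering and calling
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCall:
    """One inferred breakpoint interval (0-based, half-open) and its partner."""

    start: int
    end: int
    partner_start: int
    partner_end: int
    support: int
    strand_pair: str
    libraries: tuple[str, ...] = field(default_factory=tuple)

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


#: slack (bp) absorbed by reads that cross a junction yet still map because
#: the first bases beyond it agree with the reference by chance
JUNCTION_SLACK = 12


def _footprint(position: int, strand: str, lib: LibrarySpec,
               max_insert_factor: float) -> tuple[int, int]:
    """Half-open interval that must contain the read's nearby breakpoint.

    A forward read looks toward larger coordinates (its mate crossed the
    junction to the right); a reverse read looks back.
    """
    rl = lib.read_length
    reach = lib.max_insert(max_insert_factor) - rl
    if strand == "+":
        lo, hi = position + rl, position + reach + 1
    else:
        lo, hi = position - reach + rl, position + 1
    return lo - JUNCTION_SLACK, hi + JUNCTION_SLACK


def cluster_and_call(
    pairs: Sequence[PairAlignment],
    libs: dict[str, LibrarySpec],
    min_support: int = 2,
    max_insert_factor: float = 3.0,
) -> list[BreakpointCall]:
    """Group same-orientation distant pairs into reciprocal breakpoint calls.

    Pairs are clustered per strand orientation by proximity of both
    footprints (single linkage within one maximal insert); each cluster
    with enough support yields one call whose interval is the
    intersection of the low-side footprints and whose partner interval is
    the intersection of the high-side footprints.
    """
    events = []
    for p in pairs:
        if p.category != INVERSION_DISCORDANT:
            continue
        lib = libs[p.library]
        lo, hi = sorted((p.hit1.position, p.hit2.position))
        events.append((p.hit1.strand, lo, hi, lib))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    calls: list[BreakpointCall] = []
    cluster: list[tuple[str, int, int, LibrarySpec]] = []

    def flush() -> None:
        if len(cluster) < min_support:
            cluster.clear()
            return
        strand = cluster[0][0]
        lows = [_footprint(lo, strand, lib, max_insert_factor)
                for _, lo, _, lib in cluster]
        highs = [_footprint(hi, strand, lib, max_insert_factor)
                 for _, _, hi, lib in cluster]
        ls, le = max(a for a, _ in lows), min(b for _, b in lows)
        hs, he = max(a for a, _ in highs), min(b for _, b in highs)
        if ls < le and hs < he:
            calls.append(BreakpointCall(
                ls, le, hs, he, len(cluster), strand * 2,
                tuple(sorted({lib.name for _, _, _, lib in cluster})),
            ))
        cluster.clear()

    max_reach = max(lib.max_insert(max_insert_factor) for lib in libs.values())
    for ev in events:
        if cluster and (
            ev[0] != cluster[-1][0]
            or ev[1] - cluster[-1][1] > max_reach
            or abs(ev[2] - cluster[-1][2]) > max_reach
        ):
            flush()
        cluster.append(ev)
    flush()
    calls.sort(key=lambda c: (c.start, c.end, c.strand_pair))
    return calls


def calls_to_frame(calls: Sequence[BreakpointCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": c.start, "end": c.end,
                "partner_start": c.partner_start, "partner_end": c.partner_end,
                "support": c.support, "strand_pair": c.strand_pair,
                "libraries": ",".join(c.libraries),
            }
            for c in calls
        ]
    )


# ---------------------------------------------------------------------------
# detection limit
# ---------------------------------------------------------------------------

def spanning_pair_possible(lib: LibrarySpec, gap_length: int) -> bool:
    """Geometric detectability of a junction with a novel gap.

    A same-orientation pair spans the junction iff one read fits on each
    side of the gap, i.e. insert_size >= gap + 2 * read_length (taking
    the library's inserts at their nominal size).
    """
    return lib.insert_size >= gap_length + 2 * lib.read_length


def detection_limit(
    libs: Sequence[LibrarySpec],
    gap_lengths: Sequence[int],
    coverage: float,
    seed: int,
    flank: int = 12_000,
    block: int = 20_000,
) -> pd.DataFrame:
    """Simulated detectability of junction gaps of increasing length.

    For each gap length a toy inversion whose junctions carry novel
    sequence of that length is simulated, mate-pair libraries are drawn
    at ``coverage`` per library with nominal (fixed) insert sizes, reads
    are mapped back to the reference, and the gap counts as detected
    when at least one same-orientation discordant pair remains.  Fixed
    inserts make the analytic bound insert >= gap + 2*read_length exact.
    """
    from .simulate import simulate_matepair_pairs, simulate_toy_inversion

    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rows = []
    rng = np.random.default_rng(seed)
    for gap in gap_lengths:
        toy = simulate_toy_inversion(
            flank_length=flank, block_length=block, junction_gap=int(gap), rng=rng,
        )
        index = ReferenceIndex(toy.reference)
        detected = False
        expected = any(spanning_pair_possible(lib, gap) for lib in libs)
        for lib in libs:
            fixed = LibrarySpec(lib.name, lib.insert_size, 0.0, lib.read_length)
            pairs = simulate_matepair_pairs(toy.derived, fixed, coverage, rng)
            alignments = map_pairs(pairs, index, fixed)
            classify_pairs(alignments, {fixed.name: fixed})
            if any(p.category == INVERSION_DISCORDANT for p in alignments):
                detected = True
                break
        rows.append({
            "gap_length": int(gap),
            "detected": detected,
            "analytic_detectable": expected,
        })
    return pd.DataFrame(rows)


def expected_pairs(coverage: float, genome_length: int, read_length: int) -> int:
    """Pair count at a physical read coverage: ceil(cov * L / (2 * rl))."""
    return math.ceil(coverage * genome_length / (2 * read_length))
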