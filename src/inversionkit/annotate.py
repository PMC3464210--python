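"""Breakpoint annotation: ancestry calls, region arithmetic, MITE boundaries.

Three independent strands of evidence around inversion breakpoints:

* gene adjacencies observed in other species (via an ortholog table)
  matched against the junction models of the standard and inverted
  arrangements, to call each species' arrangement state;
* breakpoint-region coordinate arithmetic on printed 1-based inclusive
  spans (with explicit conversion to 0-based half-open);
* a repeat-element boundary procedure: find copies of a candidate
  repeat, align them with 1000-bp flanks, define the 5'/3' element
  boundaries where inter-copy similarity collapses, and measure the
  target-site duplication (TSD) each insertion created.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .catalog import (
    INVERTED,
    STANDARD,
    InversionCatalog,
    InversionDef,
)

UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# breakpoint-region arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointRegion:
    """A breakpoint-region span in printed 1-based inclusive coordinates."""

    assembly: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_half_open(self) -> tuple[int, int]:
        """Equivalent 0-based half-open interval."""
        return (self.start - 1, self.end)

    @classmethod
    def from_half_open(cls, assembly: str, start0: int, end0: int) -> "BreakpointRegion":
        return cls(assembly, start0 + 1, end0)


def region_length(region: BreakpointRegion) -> int:
    """1-based inclusive span length: end - start + 1."""
    return region.length


def compare_region_sizes(region_a: int, region_b: int) -> float:
    """Fold ratio a/b, rounded to one decimal as reported."""
    if region_a <= 0 or region_b <= 0:
        raise ValueError("region lengths must be positive")
    return round(region_a / region_b, 1)


# ---------------------------------------------------------------------------
# adjacency-based arrangement calls
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyObservation:
    """One observed gene adjacency in some assembly.

    ``same_scaffold`` is False when the two genes were located on
    different scaffolds/supercontigs, in which case the observation can
    only ever support an *unresolved* call.
    """

    species: str
    gene_a: str
    gene_b: str
    same_scaffold: bool = True
    intergenic_distance: int | None = None


@dataclass
class StateCall:
    species: str
    inversion: str
    state: str
    conflict: bool = False
    reason: str = ""


def _resolve(gene: str, catalog: InversionCatalog,
             orthologs: Mapping[str, str] | None) -> str:
    if orthologs and gene in orthologs:
        gene = orthologs[gene]
    return catalog.resolve_anchor(gene)


def junction_models(inv: InversionDef) -> dict[str, list[frozenset]]:
    """Diagnostic junction gene pairs for each arrangement state.

    Standard: both breakpoints intact (each anchor pair adjacent).
    Inverted: the four anchors cross-paired, one from each breakpoint.
    """
    d, p = set(inv.distal_anchor), set(inv.proximal_anchor)
    standard = [frozenset(inv.distal_anchor), frozenset(inv.proximal_anchor)]
    inverted = [frozenset({a, b}) for a in d for b in p]
    return {STANDARD: standard, INVERTED: inverted}


def infer_arrangement_state(
    observations: Sequence[AdjacencyObservation],
    inv: InversionDef,
    catalog: InversionCatalog,
    orthologs: Mapping[str, str] | None = None,
) -> StateCall:
    """Call one species' arrangement state for one inversion.

    The species is ``inverted`` when its adjacencies cross-pair the two
    breakpoints' anchors (covering all four), ``standard`` when both
    reference adjacencies are present, ``unresolved`` when the anchors
    sit on different scaffolds or match neither model, and flagged as a
    conflict when both models are matched.
    """
    if not observations:
        raise ValueError("no observations")
    species = observations[0].species
    models = junction_models(inv)
    anchors = set(inv.distal_anchor) | set(inv.proximal_anchor)
    same, split = [], []
    for obs in observations:
        pair = frozenset({
            _resolve(obs.gene_a, catalog, orthologs),
            _resolve(obs.gene_b, catalog, orthologs),
        })
        if not pair <= anchors:
            continue
        (same if obs.same_scaffold else split).append(pair)
    std = all(m in same for m in models[STANDARD])
    cross = [p for p in same if p in models[INVERTED]]
    inv_match = any(
        not (a & b) and (a | b) == anchors
        for a, b in itertools.combinations(cross, 2)
    ) or (len(cross) >= 1 and len(anchors) < 4)
    if std and inv_match:
        return StateCall(species, inv.name, UNRESOLVED, conflict=True,
                         reason="both junction models matched")
    if std:
        return StateCall(species, inv.name, STANDARD)
    if inv_match:
        return StateCall(species, inv.name, INVERTED)
    if split:
        return StateCall(species, inv.name, UNRESOLVED,
                         reason="anchors found on different scaffolds")
    return StateCall(species, inv.name, UNRESOLVED, reason="no model matched")


def infer_arrangement_states(
    observations: Sequence[AdjacencyObservation],
    catalog: InversionCatalog,
    inversions: Sequence[str] | None = None,
    orthologs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-species, per-inversion state calls from a table of adjacencies.

    Species called unresolved carry no weight in ancestry voting and are
    reported as such.
    """
    names = inversions or [i.name for i in catalog.inversions]
    rows = []
    by_species: dict[str, list[AdjacencyObservation]] = {}
    for obs in observations:
        by_species.setdefault(obs.species, []).append(obs)
    for species, obs in by_species.items():
        for name in names:
            call = infer_arrangement_state(obs, catalog.get(name), catalog, orthologs)
            rows.append({
                "species": species, "inversion": name, "state": call.state,
                "conflict": call.conflict, "reason": call.reason,
            })
    return pd.DataFrame(rows)


def ancestry_vote(calls: pd.DataFrame, inversion: str) -> dict[str, int]:
    """Count resolved outgroup calls per state (unresolved excluded)."""
    sub = calls[(calls.inversion == inversion) & (calls.state != UNRESOLVED)]
    return dict(Counter(sub.state))


# ---------------------------------------------------------------------------
# repeat-copy discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatCopy:
    start: int
    end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _diagonal_hits(candidate: str, genome_index: dict[str, list[int]],
                   k: int) -> Counter:
    votes: Counter = Counter()
    for i in range(0, len(candidate) - k + 1, k):
        for g in genome_index.get(candidate[i:i + k], ()):
            votes[g - i] += 1
    return votes


def _extend_diagonal(candidate: str, genome: str, offset: int,
                     min_identity: float, min_length: int,
                     smooth: int = 20) -> tuple[int, int, float] | None:
    """Best high-identity segment of the candidate laid on one diagonal."""
    a = max(0, -offset)
    b = min(len(candidate), len(genome) - offset)
    if b - a < min_length:
        return None
    cand = np.frombuffer(candidate[a:b].encode(), dtype=np.uint8)
    gen = np.frombuffer(genome[a + offset: b + offset].encode(), dtype=np.uint8)
    match = (cand == gen).astype(float)
    kernel = np.ones(smooth) / smooth
    local = np.convolve(match, kernel, mode="same")
    good = local >= min_identity
    if not good.any():
        return None
    # largest contiguous run of locally-good columns
    idx = np.flatnonzero(good)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    runs = [(idx[s], idx[e]) for s, e in zip(starts, ends)]
    lo, hi = max(runs, key=lambda r: r[1] - r[0])
    # trim to exact matching bases at the edges, then extend outward while
    # the exact match continues (smoothing blunts the run's true ends)
    while lo <= hi and not match[lo]:
        lo += 1
    while hi >= lo and not match[hi]:
        hi -= 1
    while lo > 0 and match[lo - 1]:
        lo -= 1
    while hi + 1 < len(match) and match[hi + 1]:
        hi += 1
    length = hi - lo + 1
    if length < min_length:
        return None
    ident = float(match[lo:hi + 1].mean())
    if ident < min_identity:
        return None
    return (a + lo + offset, a + hi + 1 + offset, ident)


def find_repeat_copies(
    candidate: str,
    genome: str,
    min_identity: float = 0.9,
    min_length: int = 100,
    seed_length: int = 20,
) -> list[RepeatCopy]:
    """All non-overlapping copies of a candidate repeat, both strands.

    Seeded local matching: exact k-mer seeds vote for diagonals, each
    promising diagonal is extended without gaps, and the longest local
    segment above the identity threshold is reported per locus.
    """
    if len(candidate) >= len(genome):
        raise ValueError("candidate must be shorter than the genome")
    index: dict[str, list[int]] = {}
    for i in range(len(genome) - seed_length + 1):
        index.setdefault(genome[i:i + seed_length], []).append(i)
    hits: list[RepeatCopy] = []
    for strand, query in (("+", candidate), ("-", revcomp(candidate))):
        for offset, votes in _diagonal_hits(query, index, seed_length).items():
            if votes < 2:
                continue
            seg = _extend_diagonal(query, genome, offset, min_identity, min_length)
            if seg:
                hits.append(RepeatCopy(seg[0], seg[1], strand, seg[2]))
    hits.sort(key=lambda h: (h.start, -h.length))
    out: list[RepeatCopy] = []
    for h in hits:
        if out and h.start < out[-1].end:
            if h.length > out[-1].length:
                out[-1] = h
            continue
        out.append(h)
    return out


def discover_repeat_candidate(
    genome: str, k: int = 20, min_count: int = 5, pad: int = 400
) -> str:
    """A window around the first locus of a high-copy k-mer (truth-blind).

    k-mers are counted strand-canonically so copies inserted in either
    orientation accumulate on one key.
    """
    counts: Counter = Counter()
    first: dict[str, int] = {}
    for i in range(len(genome) - k + 1):
        kmer = genome[i:i + k]
        canon = min(kmer, revcomp(kmer))
        counts[canon] += 1
        first.setdefault(canon, i)
    for i in range(len(genome) - k + 1):
        canon = min(genome[i:i + k], revcomp(genome[i:i + k]))
        if counts[canon] >= min_count and first[canon] == i:
            lo, hi = max(0, i - pad), min(len(genome), i + k + pad)
            return genome[lo:hi]
    raise ValueError("no repeated k-mer found")


# ---------------------------------------------------------------------------
# element boundaries and TSD
# ---------------------------------------------------------------------------

@dataclass
class MITEModel:
    """A repeat element's consensus, boundaries and inferred TSD length."""

    name: str
    consensus: str
    tsd_length: int
    copies: tuple[RepeatCopy, ...]
    #: consensus element span inside the flanked alignment window
    window_bounds: tuple[int, int] = (0, 0)
    tsd_votes: dict[int, int] = field(default_factory=dict)


def _column_identity(windows: list[str]) -> np.ndarray:
    arrays = [np.frombuffer(w.encode(), dtype=np.uint8) for w in windows]
    mat = np.vstack(arrays)
    ref = mat[0]
    return (mat[1:] == ref).mean(axis=0)


def _max_direct_repeat(left: str, right: str, limit: int) -> int:
    """Longest t <= limit with left's suffix equal to right's prefix."""
    best = 0
    for t in range(1, min(limit, len(left), len(right)) + 1):
        if left[-t:] == right[:t]:
            best = t
    return best


def _registered_windows(
    genome: str,
    copies: Sequence[RepeatCopy],
    flank: int,
    core: int,
    key: str,
    key_off: int,
    slop: int,
):
    """Oriented windows of equal length, registered on a shared core k-mer.

    Returns (window, strand, anchor) triples where window index ``w``
    maps to genome coordinate ``anchor + w`` (+ strand) or
    ``anchor - w`` (- strand).
    """
    width = 2 * flank + core
    out = []
    for c in copies:
        if c.strand == "+":
            raw_lo = c.start - flank - slop
            raw = _padded_slice(genome, raw_lo, c.start + core + flank + slop)
        else:
            raw_hi = c.end + flank + slop
            raw = revcomp(_padded_slice(genome, c.end - core - flank - slop, raw_hi))
        target = flank + slop + key_off
        best = None
        pos = raw.find(key)
        while pos != -1:
            if best is None or abs(pos - target) < abs(best - target):
                best = pos
            pos = raw.find(key, pos + 1)
        if best is None:
            continue
        shift = best - key_off - flank
        window_seq = raw[shift: shift + width]
        if len(window_seq) < width:
            continue
        if c.strand == "+":
            anchor = raw_lo + shift
        else:
            anchor = (c.end + flank + slop) - shift - 1
        out.append((window_seq, c.strand, anchor, c))
    return out


def define_element_boundaries(
    genome: str,
    copies: Sequence[RepeatCopy],
    flank: int = 1000,
    name: str = "element",
    window: int = 10,
    identity_threshold: float = 0.5,
    tsd_limit: int = 20,
) -> MITEModel:
    """Define 5'/3' element boundaries and the TSD length from aligned copies.

    Copy loci are extracted with ``flank`` bases of genomic context,
    oriented to the plus strand, registered on a shared core k-mer (so
    imprecise copy spans cannot shear the columns), and compared
    columnwise; the element is the block whose smoothed inter-copy
    identity stays above the threshold, since unrelated flanks collapse
    to background identity.  The TSD is the maximal direct repeat
    immediately flanking both refined termini of each copy, aggregated
    by majority vote (ties broken toward the shorter length).
    """
    if len(copies) < 2:
        raise ValueError("need at least two copies to define boundaries")
    shortest = min(copies, key=lambda c: c.length)
    core = shortest.length
    core_seq = genome[shortest.start:shortest.end]
    if shortest.strand == "-":
        core_seq = revcomp(core_seq)
    key_off = core // 2
    key = core_seq[key_off: key_off + min(20, core - key_off)]
    registered = _registered_windows(genome, copies, flank, core, key, key_off,
                                     slop=max(50, core // 2))
    if len(registered) < 2:
        raise ValueError("fewer than two copies could be registered")
    windows = [w for w, _, _, _ in registered]
    ident = _column_identity(windows)
    kernel = np.ones(window) / window
    smooth = np.convolve(ident, kernel, mode="same")
    good = smooth >= identity_threshold
    if not good.any():
        raise ValueError("no conserved block found")
    center = flank + core // 2
    idx = np.flatnonzero(good)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    runs = [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]
    lo, hi = min(runs, key=lambda r: 0 if r[0] <= center <= r[1] else min(
        abs(r[0] - center), abs(r[1] - center)))
    # refine to exact unanimous columns at the edges
    while lo <= hi and ident[lo] < 1.0:
        lo += 1
    while hi >= lo and ident[hi] < 1.0:
        hi -= 1
    consensus = windows[0][lo:hi + 1]

    votes: Counter = Counter()
    for window_seq, strand, anchor, _ in registered:
        if strand == "+":
            a, b = anchor + lo, anchor + hi + 1
        else:
            a, b = anchor - hi, anchor - lo + 1
        left = _padded_slice(genome, a - tsd_limit, a)
        right = _padded_slice(genome, b, b + tsd_limit)
        votes[_max_direct_repeat(left, right, tsd_limit)] += 1
    best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return MITEModel(
        name=name,
        consensus=consensus,
        tsd_length=int(best),
        copies=tuple(copies),
        window_bounds=(int(lo), int(hi + 1)),
        tsd_votes=dict(votes),
    )


def element_spans(genome: str, model: MITEModel, flank: int = 1000) -> list[tuple[int, int]]:
    """Refined per-copy element coordinates implied by the model boundaries."""
    shortest = min(model.copies, key=lambda c: c.length)
    core = shortest.length
    core_seq = genome[shortest.start:shortest.end]
    if shortest.strand == "-":
        core_seq = revcomp(core_seq)
    key_off = core // 2
    key = core_seq[key_off: key_off + min(20, core - key_off)]
    lo, hi1 = model.window_bounds
    spans = []
    for window_seq, strand, anchor, _ in _registered_windows(
            genome, model.copies, flank, core, key, key_off, slop=max(50, core // 2)):
        if strand == "+":
            spans.append((anchor + lo, anchor + hi1))
        else:
            spans.append((anchor - hi1 + 1, anchor - lo + 1))
    return sorted(spans)


def _padded_slice(genome: str, lo: int, hi: int) -> str:
    """Slice clamped to the genome, padded with N to keep window lengths equal."""
    left = "N" * max(0, -lo)
    right = "N" * max(0, hi - len(genome))
    return left + genome[max(0, lo):min(len(genome), hi)] + right
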