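"""Fixed-inversion catalogs and signed-permutation karyotype encoding.

A chromosome arm is partitioned into segments by the breakpoints of the
catalogued paracentric inversions.  A karyotype assigns each inversion a
binary arrangement state (``standard`` or ``inverted``); the arm-level
consequence of those states is a signed permutation of the segments, the
unit on which reversal-distance machinery operates.

Breakpoints are labelled by their flanking gene anchors.  For the
*Anopheles gambiae* complex the 2R and 2L anchors are real gene ids
(e.g. AGAP001760); arms for which no flanking genes are published carry
synthetic placeholder anchors (e.g. ``Xa:d:tel``).

Overlapping inversions (2Ro/2Rp on 2R) make the state -> permutation map
history dependent: an inversion can only be toggled when its two
breakpoints are exposed as junctions of the current arrangement, and the
resulting permutation depends on the order in which overlapping
inversions were fixed.  ``encode_karyotype`` composes reversals in
catalog order (the attested order for the complex), and
``validate_trajectory`` checks the elementary-step constraint that makes
e.g. the 2Rop -> 2R+o p transition impossible regardless of direction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STANDARD = "standard"
INVERTED = "inverted"
UNKNOWN = "unknown"

TELOMERE = "TEL"
CENTROMERE = "CEN"


class CatalogError(ValueError):
    pass


class UnorderedBreakpointsError(CatalogError):
    pass


class InconsistentStatesError(CatalogError):
    """No valid composition order realizes the requested arrangement states."""


class NonElementaryStepError(CatalogError):
    """Consecutive trajectory states differ by more (or fewer) than one flip."""


@dataclass(frozen=True)
class GeneAnchor:
    """A gene flanking an inversion breakpoint.

    ``side`` is the gene's position relative to its breakpoint in the
    reference (all-standard) arrangement: ``telomeric`` or ``centromeric``.
    """

    id: str
    arm: str
    side: str


@dataclass(frozen=True)
class Breakpoint:
    """An inversion breakpoint, labelled by its two flanking anchors."""

    telomeric_gene: str
    centromeric_gene: str

    @property
    def anchors(self) -> tuple[str, str]:
        return (self.telomeric_gene, self.centromeric_gene)


@dataclass(frozen=True)
class InversionDef:
    name: str
    arm: str
    distal_anchor: tuple[str, str]
    proximal_anchor: tuple[str, str]
    #: pair of segment-boundary indices on the arm's SegmentMap (1-based
    #: breakpoint indices; the inversion covers segments d+1 .. p).
    interval: tuple[int, int]

    def __post_init__(self) -> None:
        d, p = self.interval
        if not d < p:
            raise UnorderedBreakpointsError(
                f"{self.name}: distal boundary index {d} must precede proximal {p}"
            )


@dataclass(frozen=True)
class SegmentMap:
    """Ordered partition of one arm into segments, telomere -> centromere.

    ``boundaries[i]`` is the i-th interior breakpoint (1-based in the
    boundary-index convention used by :class:`InversionDef`), so an arm
    with ``n`` segments has ``n - 1`` interior boundaries.
    """

    arm: str
    boundaries: tuple[Breakpoint, ...]

    @property
    def n(self) -> int:
        return len(self.boundaries) + 1

    @property
    def segment_labels(self) -> tuple[str, ...]:
        return tuple(f"{self.arm}:S{i}" for i in range(1, self.n + 1))

    def side_gene(self, boundary_index: int, side: str) -> str:
        """Gene anchor on one side of a boundary (0 and n are the arm ends)."""
        if boundary_index == 0:
            return TELOMERE
        if boundary_index == self.n:
            return CENTROMERE
        bp = self.boundaries[boundary_index - 1]
        return bp.telomeric_gene if side == "telomeric" else bp.centromeric_gene


@dataclass(frozen=True)
class SignedPermutation:
    arm: str
    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.elements)
        if sorted(abs(e) for e in self.elements) != list(range(1, n + 1)):
            raise CatalogError(f"not a signed permutation: {self.elements}")

    @property
    def n(self) -> int:
        return len(self.elements)

    def is_identity(self) -> bool:
        return self.elements == tuple(range(1, self.n + 1))

    @classmethod
    def identity(cls, arm: str, n: int) -> "SignedPermutation":
        return cls(arm, tuple(range(1, n + 1)))


@dataclass
class ArrangementStates:
    """Per-inversion arrangement states for one taxon."""

    species: str
    states: dict[str, str]
    #: free-form notes, e.g. polymorphic status recorded but not scored
    metadata: dict[str, str] = field(default_factory=dict)

    def state(self, inversion: str) -> str:
        return self.states[inversion]

    def check_complete(self, catalog: "InversionCatalog") -> None:
        missing = {inv.name for inv in catalog.inversions} - set(self.states)
        extra = set(self.states) - {inv.name for inv in catalog.inversions}
        if missing or extra:
            raise CatalogError(
                f"{self.species}: states must cover the catalog exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )


class InversionCatalog:
    """An ordered collection of fixed inversions over named arms.

    Parameters
    ----------
    arm_breakpoints
        Mapping arm -> ordered (telomere to centromere) breakpoints.
    inversions
        Ordered inversion definitions; order is the canonical composition
        order used by :func:`encode_karyotype` for overlapping inversions.
    anchors
        Gene anchors; generated from breakpoints when omitted.
    name_aliases
        Alternative inversion names (e.g. the cytologically identical
        2La' of *An. merus* aliases 2La).
    anchor_aliases
        Alternative anchor gene ids resolving to a registered anchor.
    """

    def __init__(
        self,
        arm_breakpoints: Mapping[str, Sequence[Breakpoint]],
        inversions: Sequence[InversionDef],
        anchors: Sequence[GeneAnchor] | None = None,
        name_aliases: Mapping[str, str] | None = None,
        anchor_aliases: Mapping[str, str] | None = None,
    ) -> None:
        self.arm_breakpoints = {a: tuple(b) for a, b in arm_breakpoints.items()}
        self.inversions = tuple(inversions)
        self.name_aliases = dict(name_aliases or {})
        self.anchor_aliases = dict(anchor_aliases or {})
        names = [inv.name for inv in self.inversions]
        if len(set(names)) != len(names):
            raise CatalogError("inversion names must be unique")
        for arm, bps in self.arm_breakpoints.items():
            seen: set[tuple[str, str]] = set()
            for bp in bps:
                if bp.anchors in seen:
                    raise UnorderedBreakpointsError(
                        f"{arm}: duplicate breakpoint {bp.anchors}"
                    )
                seen.add(bp.anchors)
        for inv in self.inversions:
            nb = len(self.arm_breakpoints.get(inv.arm, ()))
            if not (1 <= inv.interval[0] and inv.interval[1] <= nb):
                raise CatalogError(f"{inv.name}: interval outside arm segment range")
        if anchors is None:
            anchors = [
                GeneAnchor(bp.telomeric_gene, arm, "telomeric")
                for arm, bps in self.arm_breakpoints.items()
                for bp in bps
            ] + [
                GeneAnchor(bp.centromeric_gene, arm, "centromeric")
                for arm, bps in self.arm_breakpoints.items()
                for bp in bps
            ]
        self.anchors = {a.id: a for a in anchors}
        for inv in self.inversions:
            for gid in (*inv.distal_anchor, *inv.proximal_anchor):
                if gid not in self.anchors:
                    raise CatalogError(f"{inv.name}: anchor {gid} not registered")

    # -- lookups ---------------------------------------------------------

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(self.arm_breakpoints)

    def by_arm(self, arm: str) -> tuple[InversionDef, ...]:
        return tuple(inv for inv in self.inversions if inv.arm == arm)

    def get(self, name: str) -> InversionDef:
        name = self.name_aliases.get(name, name)
        for inv in self.inversions:
            if inv.name == name:
                return inv
        raise KeyError(name)

    def resolve_anchor(self, gene_id: str) -> str:
        return self.anchor_aliases.get(gene_id, gene_id)

    def subset(self, names: Iterable[str]) -> "InversionCatalog":
        """Catalog restricted to the given inversions (breakpoints re-indexed)."""
        keep = [self.get(n) for n in names]
        arm_bps: dict[str, list[Breakpoint]] = {}
        for arm in self.arms:
            wanted_idx = sorted(
                {i for inv in keep if inv.arm == arm for i in inv.interval}
            )
            bps = [self.arm_breakpoints[arm][i - 1] for i in wanted_idx]
            if bps:
                arm_bps[arm] = bps
        new_invs = []
        for inv in keep:
            idx = sorted(
                {i for other in keep if other.arm == inv.arm for i in other.interval}
            )
            remap = {old: new + 1 for new, old in enumerate(idx)}
            new_invs.append(
                InversionDef(
                    inv.name,
                    inv.arm,
                    inv.distal_anchor,
                    inv.proximal_anchor,
                    (remap[inv.interval[0]], remap[inv.interval[1]]),
                )
            )
        return InversionCatalog(
            arm_bps, new_invs, name_aliases=self.name_aliases,
            anchor_aliases=self.anchor_aliases,
        )

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "arms": {
                arm: [list(bp.anchors) for bp in bps]
                for arm, bps in self.arm_breakpoints.items()
            },
            "inversions": [
                {
                    "name": inv.name,
                    "arm": inv.arm,
                    "distal_anchor": list(inv.distal_anchor),
                    "proximal_anchor": list(inv.proximal_anchor),
                    "interval": list(inv.interval),
                }
                for inv in self.inversions
            ],
            "name_aliases": self.name_aliases,
            "anchor_aliases": self.anchor_aliases,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InversionCatalog":
        payload = json.loads(text)
        arm_bps = {
            arm: [Breakpoint(*bp) for bp in bps]
            for arm, bps in payload["arms"].items()
        }
        invs = [
            InversionDef(
                d["name"], d["arm"], tuple(d["distal_anchor"]),
                tuple(d["proximal_anchor"]), tuple(d["interval"]),
            )
            for d in payload["inversions"]
        ]
        return cls(
            arm_bps, invs,
            name_aliases=payload.get("name_aliases"),
            anchor_aliases=payload.get("anchor_aliases"),
        )


# ---------------------------------------------------------------------------
# segment maps and junction algebra
# ---------------------------------------------------------------------------

def build_segment_map(catalog: InversionCatalog, arm: str) -> SegmentMap:
    """Partition an arm into segments between consecutive catalog breakpoints.

    An arm with ``n`` distinct breakpoints yields ``n + 1`` segments.
    """
    bps = catalog.arm_breakpoints.get(arm, ())
    return SegmentMap(arm, tuple(bps))


def _element_sides(element: int, n: int) -> tuple[tuple[str, int], tuple[str, int]]:
    """(left, right) exposed breakpoint sides of a signed segment.

    Side ``("D", i)`` is the telomeric face of boundary ``i`` (the last gene
    of reference segment ``i``); ``("P", i)`` its centromeric face (the
    first gene of segment ``i + 1``).  Boundary 0 / n are the arm ends.
    """
    s = abs(element)
    left, right = ("P", s - 1), ("D", s)
    return (left, right) if element > 0 else (right, left)


def _junction_sides(perm: SignedPermutation) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Interior junctions as (left-exposed side, right-exposed side) pairs."""
    out = []
    for a, b in zip(perm.elements, perm.elements[1:]):
        out.append((_element_sides(a, perm.n)[1], _element_sides(b, perm.n)[0]))
    return out


def _side_gene(side: tuple[str, int], smap: SegmentMap) -> str:
    kind, i = side
    return smap.side_gene(i, "telomeric" if kind == "D" else "centromeric")


def junction_adjacencies(
    perm: SignedPermutation, smap: SegmentMap
) -> list[tuple[str, str]]:
    """Ordered gene-anchor pairs at the internal segment junctions.

    One pair per junction, reading telomere to centromere along the
    current arrangement; the order within a pair respects segment signs
    (each gene is reported from the segment face meeting the junction).
    """
    if perm.n != smap.n:
        raise CatalogError("permutation and segment map disagree on segment count")
    return [
        (_side_gene(left, smap), _side_gene(right, smap))
        for left, right in _junction_sides(perm)
    ]


def _apply_block_reversal(perm: SignedPermutation, a: int, b: int) -> SignedPermutation:
    """Reverse elements a..b-1 (between junction positions a and b)."""
    e = perm.elements
    block = tuple(-x for x in reversed(e[a:b]))
    return SignedPermutation(perm.arm, e[:a] + block + e[b:])


def _junction_positions_with_side(perm: SignedPermutation, side: tuple[str, int]) -> list[int]:
    """Junction positions (1..n-1) exposing a given breakpoint side."""
    out = []
    for j, (l, r) in enumerate(_junction_sides(perm), start=1):
        if side in (l, r):
            out.append(j)
    return out


def _intact_junction(perm: SignedPermutation, boundary: int) -> int | None:
    """Junction position where boundary's two faces meet, or None."""
    want = {("D", boundary), ("P", boundary)}
    for j, (l, r) in enumerate(_junction_sides(perm), start=1):
        if {l, r} == want:
            return j
    return None


def inversion_state_in(perm: SignedPermutation, inv: InversionDef) -> str | None:
    """Arrangement state of one inversion in a permutation.

    ``standard`` when both breakpoints are intact adjacencies, ``inverted``
    when the four breakpoint faces are cross-paired such that a single
    block reversal restores both, ``None`` when the inversion has no
    defined state in this arrangement.
    """
    d, p = inv.interval
    if _intact_junction(perm, d) is not None and _intact_junction(perm, p) is not None:
        return STANDARD
    flipped = _try_flip_from_inverted(perm, inv)
    return INVERTED if flipped is not None else None


def _try_flip_from_inverted(perm: SignedPermutation, inv: InversionDef) -> SignedPermutation | None:
    d, p = inv.interval
    sides = [("D", d), ("P", d), ("D", p), ("P", p)]
    junctions = sorted({j for s in sides for j in _junction_positions_with_side(perm, s)})
    for a, b in itertools.combinations(junctions, 2):
        cand = _apply_block_reversal(perm, a, b)
        if (_intact_junction(cand, d) is not None
                and _intact_junction(cand, p) is not None):
            return cand
    return None


def flip_inversion(perm: SignedPermutation, inv: InversionDef) -> SignedPermutation:
    """Toggle one inversion's state by cutting at its exposed breakpoints.

    Raises :class:`InconsistentStatesError` when neither a standard nor a
    restorable inverted configuration of the breakpoints is present.
    """
    d, p = inv.interval
    jd, jp = _intact_junction(perm, d), _intact_junction(perm, p)
    if jd is not None and jp is not None:
        a, b = sorted((jd, jp))
        return _apply_block_reversal(perm, a, b)
    flipped = _try_flip_from_inverted(perm, inv)
    if flipped is None:
        raise InconsistentStatesError(
            f"{inv.name}: breakpoints not toggleable in arrangement {perm.elements}"
        )
    return flipped


def encode_arm(
    states: ArrangementStates, smap: SegmentMap, catalog: InversionCatalog, arm: str
) -> SignedPermutation:
    """Signed permutation of one arm realizing the taxon's states.

    Inverted-state reversals are composed in catalog order; if that order
    is not a valid trajectory, other orders are searched.
    """
    inverted = [inv for inv in catalog.by_arm(arm) if states.state(inv.name) == INVERTED]
    identity = SignedPermutation.identity(arm, smap.n)
    if not inverted:
        return identity
    for order in itertools.permutations(inverted):
        perm = identity
        ok = True
        for inv in order:
            try:
                perm = flip_inversion(perm, inv)
            except InconsistentStatesError:
                ok = False
                break
        if ok:
            return perm
    raise InconsistentStatesError(
        f"{states.species}/{arm}: no valid composition order for "
        f"{[inv.name for inv in inverted]}"
    )


def encode_karyotype(
    states: ArrangementStates,
    maps: Mapping[str, SegmentMap],
    catalog: InversionCatalog,
) -> dict[str, SignedPermutation]:
    """Per-arm signed permutations for a complete set of arrangement states."""
    states.check_complete(catalog)
    return {arm: encode_arm(states, maps[arm], catalog, arm) for arm in catalog.arms}


# ---------------------------------------------------------------------------
# trajectory validation
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryReport:
    valid: bool
    #: index of the first invalid step (transition i -> i+1), or None
    first_violation: int | None = None
    detail: str = ""


def _single_reversal_between(p: SignedPermutation, q: SignedPermutation) -> tuple[int, int] | None:
    """Junction cut positions (a, b) with one block reversal taking p to q."""
    if p.elements == q.elements:
        return None
    n = p.n
    diff = [i for i in range(n) if p.elements[i] != q.elements[i]]
    a, b = diff[0], diff[-1] + 1
    if _apply_block_reversal(p, a, b).elements == q.elements:
        return (a, b)
    return None


def validate_trajectory(
    state_sequence: Sequence[ArrangementStates],
    maps: Mapping[str, SegmentMap],
    catalog: InversionCatalog,
) -> TrajectoryReport:
    """Check that a sequence of karyotype states is an elementary inversion path.

    Consecutive states must differ by exactly one inversion's flip, and
    each flip must be realizable as a single block reversal between the
    canonical arrangements of the two states.  The check is direction
    independent: a sequence is valid iff its reverse is.
    """
    if len(state_sequence) <= 1:
        return TrajectoryReport(valid=True)
    encoded = [encode_karyotype(s, maps, catalog) for s in state_sequence]
    for i, (s0, s1) in enumerate(zip(state_sequence, state_sequence[1:])):
        changed = [
            name for name in s0.states
            if s0.states[name] != s1.states[name]
        ]
        if len(changed) != 1:
            raise NonElementaryStepError(
                f"step {i}: states differ by {len(changed)} flips, expected 1"
            )
        arm = catalog.get(changed[0]).arm
        if _single_reversal_between(encoded[i][arm], encoded[i + 1][arm]) is None:
            return TrajectoryReport(
                valid=False,
                first_violation=i,
                detail=(
                    f"step {i}: flipping {changed[0]} cannot take "
                    f"{encoded[i][arm].elements} to {encoded[i + 1][arm].elements} "
                    "in one reversal"
                ),
            )
    return TrajectoryReport(valid=True)


# ---------------------------------------------------------------------------
# the An. gambiae complex
# ---------------------------------------------------------------------------

#: taxa of the complex, in conventional order
COMPLEX_TAXA = (
    "An. merus",
    "An. gambiae",
    "An. arabiensis",
    "An. quadriannulatus A",
    "An. quadriannulatus B",
    "An. bwambae",
    "An. melas",
)

OUTGROUP = "outgroup"

INVERSION_NAMES = ("Xa", "Xg", "Xb", "Xc", "Xd", "2Ro", "2Rp", "2Rm", "2La", "3La")


def _placeholder_bp(tag: str) -> Breakpoint:
    return Breakpoint(f"{tag}:tel", f"{tag}:cen")


def gambiae_complex_catalog() -> InversionCatalog:
    """The complex's 10 fixed paracentric inversions.

    2R carries the overlapping pair 2Ro/2Rp (breakpoints interleaved in
    the reference frame: o-distal < p-distal < o-proximal < p-proximal)
    plus 2Rm, modelled as non-overlapping since no interleaving is
    documented.  The five X inversions are modelled as disjoint
    single-segment intervals, which preserves per-clade event counts
    (Xag = 2 elementary inversions, Xbcd = 3).  Arms 2L and 3L carry one
    inversion each.  Anchors without published flanking genes are
    synthetic placeholders.
    """
    arm_breakpoints = {
        "X": tuple(
            _placeholder_bp(f"{name}:{end}")
            for name in ("Xa", "Xg", "Xb", "Xc", "Xd")
            for end in ("d", "p")
        ),
        "2R": (
            Breakpoint("AGAP001760", "AGAP001762"),   # 2Ro distal, ~9.48 Mb
            Breakpoint("AGAP001983", "AGAP001984"),   # 2Rp distal
            Breakpoint("AGAP002933", "AGAP002935"),   # 2Ro proximal, ~29.84 Mb
            Breakpoint("AGAP003327", "AGAP003328"),   # 2Rp proximal
            _placeholder_bp("2Rm:d"),
            _placeholder_bp("2Rm:p"),
        ),
        "2L": (
            Breakpoint("AGAP005778", "AGAP005780"),   # 2La distal, ~20.52 Mb
            Breakpoint("AGAP007068", "AGAP007069"),   # 2La proximal, ~42.16 Mb
        ),
        "3L": (
            _placeholder_bp("3La:d"),
            _placeholder_bp("3La:p"),
        ),
    }
    x_invs = [
        InversionDef(name, "X",
                     arm_breakpoints["X"][2 * i].anchors,
                     arm_breakpoints["X"][2 * i + 1].anchors,
                     (2 * i + 1, 2 * i + 2))
        for i, name in enumerate(("Xa", "Xg", "Xb", "Xc", "Xd"))
    ]
    inversions = x_invs + [
        InversionDef("2Ro", "2R",
                     ("AGAP001760", "AGAP001762"),
                     ("AGAP002933", "AGAP002935"), (1, 3)),
        InversionDef("2Rp", "2R",
                     ("AGAP001983", "AGAP001984"),
                     ("AGAP003327", "AGAP003328"), (2, 4)),
        InversionDef("2Rm", "2R",
                     arm_breakpoints["2R"][4].anchors,
                     arm_breakpoints["2R"][5].anchors, (5, 6)),
        InversionDef("2La", "2L",
                     ("AGAP005778", "AGAP005780"),
                     ("AGAP007068", "AGAP007069"), (1, 2)),
        InversionDef("3La", "3L",
                     arm_breakpoints["3L"][0].anchors,
                     arm_breakpoints["3L"][1].anchors, (1, 2)),
    ]
    return InversionCatalog(
        arm_breakpoints,
        inversions,
        name_aliases={"2La'": "2La", "2La′": "2La"},
        anchor_aliases={"AGAP013533": "AGAP001983"},
    )


def _states(species: str, inverted: Iterable[str], **metadata: str) -> ArrangementStates:
    inverted = set(inverted)
    return ArrangementStates(
        species,
        {name: (INVERTED if name in inverted else STANDARD) for name in INVERSION_NAMES},
        metadata=dict(metadata),
    )


def gambiae_complex_karyotypes() -> dict[str, ArrangementStates]:
    """Fixed arrangement states of the seven ingroup taxa.

    2La is coded as fixed-inverted in *An. gambiae* for scoring; its
    polymorphic 2La/+ status is recorded as metadata only.  The 2La'
    arrangement of *An. merus* is coded via the 2La alias.
    """
    return {
        "An. merus": _states("An. merus", {"Xa", "Xg", "2Ro", "2Rp", "2La"},
                             note="2La recorded cytologically as 2La'"),
        "An. gambiae": _states("An. gambiae", {"Xa", "Xg", "2La"},
                               polymorphic_2La="2La/+ segregates; coded inverted"),
        "An. arabiensis": _states("An. arabiensis", {"Xb", "Xc", "Xd", "2La"}),
        "An. quadriannulatus A": _states("An. quadriannulatus A", ()),
        "An. quadriannulatus B": _states("An. quadriannulatus B", ()),
        "An. bwambae": _states("An. bwambae", {"3La"}),
        "An. melas": _states("An. melas", {"3La", "2Rm"}),
    }


X_STATE_OPTIONS = ("X+", "Xag", "Xbcd")

_X_INVERTED = {"X+": (), "Xag": ("Xa", "Xg"), "Xbcd": ("Xb", "Xc", "Xd")}


def outgroup_states(x_state: str, species: str = OUTGROUP) -> ArrangementStates:
    """Outgroup karyotype: fixed 2Ro/2La inverted and 2R+p standard, X per scenario."""
    if x_state not in _X_INVERTED:
        raise CatalogError(f"unknown outgroup X arrangement {x_state!r}")
    return _states(species, set(_X_INVERTED[x_state]) | {"2Ro", "2La"},
                   x_scenario=x_state)
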