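# Methods

`inversionkit` reconstructs rooted chromosomal phylogenies of the
*Anopheles gambiae* sibling-species complex from its ten fixed
paracentric inversions, and re-implements the supporting genomic
evidence chain — discordant mate-pair breakpoint detection, gene-order
comparison at breakpoints across outgroup species, and the definition
of a transposable element's boundaries from its target-site
duplications — so that the whole analysis can be exercised and tested
on seeded synthetic data.

## Karyotype model

Each chromosome arm is partitioned into segments by the breakpoints of
its catalogued inversions; a karyotype is a binary state vector
(*standard* vs *inverted*) over the catalog, and its arm-level
realization is a signed permutation of the segments. Breakpoints are
labelled by flanking gene anchors: on 2R the published genes
(AGAP001760|AGAP001762 and AGAP002933|AGAP002935 for 2Ro;
AGAP001983|AGAP001984 and AGAP003327|AGAP003328 for 2Rp, with
AGAP013533 registered as an alias of the AGAP001983-side block), on 2L
the 2La anchors (AGAP005778|AGAP005780 and AGAP007068|AGAP007069). No
flanking genes are published for 2Rm, 3La or the X inversions, so those
carry synthetic placeholder anchors; only junction identity, not gene
content, matters to the analysis.

The 2Ro/2Rp pair overlaps in a staggered way (o-distal < p-distal <
o-proximal < p-proximal in the reference frame), which makes the state
→ permutation map history dependent. An inversion can be toggled only
when its two breakpoints are exposed as junctions of the current
arrangement (its two faces either intact or restorably cross-paired);
composing the o-reversal and then the p-reversal from the all-standard
AgamP3 frame yields the attested *An. merus* arrangement
(1, −3, −4, 2, 5), while the p-first composition yields a different —
never observed — arrangement. `encode_karyotype` therefore composes
inverted-state reversals in catalog order (falling back to a search
over orders), and `validate_trajectory` accepts a step exactly when a
single block reversal connects the canonical arrangements of its two
states. This reproduces the central trajectory constraint: 2Rop →
2Ro+p → 2R+o+p is a legal elementary path, 2Rop → 2R+o p is not, in
either direction.

**X-arm layout.** The five X inversions are modelled as disjoint,
non-adjacent single-segment intervals (an 11-segment map). Tiling them
edge-to-edge would make adjacent inversions share breakpoints, and a
shared breakpoint leaves a neighbour's state undefined after a flip —
the Xag karyotype would become unencodable. The disjoint layout
preserves what actually matters for scoring: Xag costs 2 elementary
inversions, Xbcd costs 3. 2Rm is modelled as non-overlapping with
2Ro/2Rp since no interleaving is documented. 2La is coded fixed-inverted
in *An. gambiae* for scoring; its polymorphic status is kept as
metadata.

## Reversal engine

Distances between signed permutations use the Hannenhalli–Pevzner
breakpoint-graph formula `d = n + 1 − c + h + f` (cycles, hurdles,
fortress) for linear chromosomes, with an exhaustive breadth-first
oracle over the reversal graph (guarded to n ≤ 8) as the independent
arbiter; the two agree on every signed permutation with n ≤ 5 and on
thousands of random n ≤ 7 pairs. Minimal sorting scenarios are
enumerated depth-first, keeping only distance-decreasing reversals,
with lexicographic (start, end) ordering for determinism; enumeration
is guarded to distance ≤ 4. Species distances are per-arm sums.

## Phylogeny scoring

Each non-overlapping inversion is an independent binary character with
unit flip cost (Fitch parsimony). Overlapping inversions on one arm are
scored jointly: the transition cost between joint states is the length
of the shortest *valid flip trajectory* between their canonical
arrangements (breadth-first search over the flip graph), not the raw
reversal distance — events are fixations of the named inversions, so a
transition that cannot be realized by legal flips must detour. For the
2Ro/2Rp pair this gives cost 1 for each legal elementary step, 2 for
the joint o-then-p flip, and 3 for the (p-inverted) → (both-inverted)
route, which must pass back through all-standard. Internal nodes range
over arrangement-state combinations (Sankoff dynamic programming with
deterministic argmin tie-breaks); for mutually non-overlapping
catalogs this provably reduces to per-character Fitch, which the test
suite checks against brute-force enumeration of internal labelings.

Tree search is exhaustive over all (2n−5)!! unrooted binary topologies
(10,395 at 8 taxa; the implementation is guarded there), replacing a
heuristic rearrangement-median search with a deterministic scan. Ties
among equally parsimonious topologies are all reported, ordered by
canonical Newick string; the quadriannulatus A/B pair is
indistinguishable (no fixed difference), so its three local
resolutions tie in every scenario. The scenario comparison scores the
same ingroup matrix under outgroup X arrangements X+, Xag and Xbcd
(outgroup autosomes fixed at 2Ro inverted, 2R+p standard, 2La
inverted) and flags as winner the scenario whose optimum has every
inversion originating exactly once. On the complex's matrix the Xag
scenario attains 10 events with all single origins; X+ and Xbcd attain
11 with a forced second origin of 2Ro. Rooting places the root on the
outgroup edge and assigns each flip to one edge; replaying the events
from root to leaves reproduces every leaf karyotype.

## Mate-pair breakpoint detection

The simulator draws mate pairs in forward–reverse orientation with
insert ~ Normal(size, sd) truncated positive (sd defaults to 10% of
the insert) and pair count ⌈coverage·L/(2·read length)⌉; reads are
error-free by default (an optional uniform substitution rate exists but
is off in all shipped analyses). Mapping is a deliberately minimal
re-implementation of unique exact matching: a k-mer seed index (seed
20 bp) locates candidates and a read maps iff it has exactly one exact
occurrence over both strands; reads whose seed is non-unique are
conservatively flagged multimapped and excluded, which reproduces the
repeat-buried-breakpoint failure mode. Pairs mapping on equal strands
are inversion-discordant; correctly oriented pairs within
insert ± 3·sd are concordant; correctly oriented pairs beyond that are
distance-discordant.

Same-strand pairs are clustered by single linkage on both footprints
within one maximal insert. A forward read at p constrains its nearby
breakpoint to [p + r, p + I − r] and a reverse read to [p − I + 2r, p]
(read length r, insert I); each cluster's call interval is the
intersection of its low-side footprints, the partner interval the
intersection of the high-side ones, each widened by a 12-bp slack
because an error-free read can cross a junction by a base or two and
still map when the first bases beyond the junction agree with the
reference by chance. Calls require ≥ 2 supporting pairs by default. An
inversion yields two reciprocal calls (the ++ and −− clusters).

**Detection limit.** Junction "breakpoint regions" are modelled as
novel random sequence inserted at derived junctions, emulating the
transposable-element accumulation of derived arrangements. A junction
with a gap of g is spannable iff some library satisfies
insert ≥ g + 2·read length. The detection-limit experiment draws
inserts at their nominal size (sd = 0) so that this analytic bound is
exact; with the default 10% sd a 6-kb gap would be spanned a couple of
times per 50× run by insert-size outliers, and the experiment would
measure the insert distribution's tail rather than the method's
geometry. With 2/3/5-kb libraries and 36-bp reads on a 1-kb gap grid,
gaps of 1–4 kb are always detected at 50× and gaps of 5 kb and above
never are, matching the 5-kb nominal limit.

## Breakpoint annotation

Arrangement-state calls from gene adjacencies use per-inversion
junction models: *standard* requires both reference adjacencies
(distal pair and proximal pair each intact on one scaffold); *inverted*
requires two observed cross-pairings that partition the four anchors
between the breakpoints; anchors on different scaffolds leave the
species *unresolved*, and unresolved species never contribute to
ancestry voting. Foreign gene ids resolve through a user-supplied
two-column ortholog table (no homology search is performed).

Breakpoint-region lengths are computed from printed 1-based inclusive
coordinates (length = end − start + 1; the 0-based half-open
conversion is explicit and round-trips), and fold ratios are reported
to one decimal.

**Repeat copies and boundaries.** The repeat-copy finder is a seeded
local matcher: exact 20-mers of the candidate vote for diagonals, each
promising diagonal is extended without gaps, and the longest local
segment above the identity threshold (default 0.9, min length 100) is
kept per locus, both strands, non-overlapping. Boundary definition
extracts each copy with 1000-bp flanks, orients all copies to one
strand and registers them on a shared core k-mer — a gap-free,
registration-based stand-in for a progressive multiple alignment,
exact for the near-identical copies the procedure targets and robust
to imprecise copy spans. The element is the column block whose
smoothed inter-copy identity (10-bp window) stays above 0.5, refined
to unanimous columns at the edges; flanks are unrelated sequence and
collapse to ~25% background identity. The TSD is the longest direct
repeat (≤ 20 bp) immediately flanking both refined termini of each
copy, aggregated by majority vote with ties broken toward the shorter
length — individual copies occasionally gain a base by chance
(P ≈ 1/4 per extra base), which the vote absorbs.

## Synthetic data

The generator is the package's definition of the study conditions:
2/3/5-kb libraries with 36-bp reads; mate-pair coverage 30× for
breakpoint recovery at the 1:10-scaled coordinates 948 kb / 2,984 kb
on a 4-Mb toy genome; 50× per library for the detection-limit grid;
a 350-bp element, 15 copies, 3-bp TSD in a 200-kb genome for the
boundary procedure. Karyotype histories are played along an event
tree (each edge's events validated as a flip trajectory, violations
abort with the step named); leaf genomes are reference segments
reordered by the leaf's signed permutations with optional novel gap
sequence at non-reference junctions, and the truth record replays
byte-identically. Segment lengths in shipped configurations (1.5–50 kb)
are uniform per arm — gene anchors occupy the terminal 36-mers of the
adjacent segments, so 36-bp reads and anchor lookups behave exactly as
at full scale while keeping runs desk-sized. For parameter-recovery
runs, random single-origin histories place at least one inversion on
every internal edge, making the generating topology the unique
parsimony optimum by construction; recovering it therefore tests the
search, not the generator's luck.

What the generator does *not* emulate: sequencing errors and base
qualities, real insert-size and chimera artefacts of mate-pair
chemistry, repeat landscapes beyond planted identical copies, segment
length heterogeneity, and sequence divergence between species outside
junction regions. Passing tests demonstrate the combinatorial and
geometric correctness of the methods under clean mappings, not their
robustness to noisy real libraries.

## Numerical and determinism choices

All randomness flows through `numpy.random.Generator` seeded
explicitly; identical seeds reproduce every byte (the pipeline manifest
records config hash and output digests). Deterministic tie-breaks:
lexicographic (start, end) for reversal enumeration, smallest state
index in Sankoff backtraces, canonical Newick order for topology ties,
shorter length for TSD vote ties. Degenerate inputs raise typed errors:
unordered or duplicated breakpoints, non-elementary trajectory steps,
state sets with no valid composition order, empty references, oversized
oracle calls.

## Known limitations

* The flip-graph restriction of internal-node states to arrangement
  combinations is exact for the single-origin optima reported here and
  oracle-checked at small size, but is not a general proof for
  arbitrarily nested overlapping catalogs.
* The mapper's uniqueness test keys on the read's seed; a read whose
  seed repeats but whose full sequence is unique is conservatively
  discarded.
* The breakpoint caller assumes one inversion per cluster
  neighbourhood; nested or adjacent inversions closer than one insert
  are not deconvolved.
* Hurdle/fortress handling follows the standard formula and is
  validated against the BFS oracle only to n ≤ 7; the complex's arms
  never exceed n = 11 segments and never form hurdles in practice.
* The boundary procedure expects near-identical copies (a young MITE
  family); diverged families would need a true progressive aligner.
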