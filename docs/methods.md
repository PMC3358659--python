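# Methods

`svfocal` calls deletions with exact breakpoints, and insertion
breakpoints, from low-coverage paired-end sequencing data.  It is a
split-read method: a read straddling a deletion junction is reported by a
soft-clip-aware mapper as a partial alignment plus a clipped terminal
segment, and re-placing that clipped segment on the reference reveals the
other side of the junction.  The package's central idea is to realign the
clip only inside a small *focal region* derived from discordant read-pair
geometry, rather than scanning up to some maximum event size.

## Model and notation

Let `l_i` be the expected outer distance of a read pair (leftmost base of
one read to rightmost base of its mate), `sigma` its standard deviation,
`l_1`, `l_2` the mapped spans of the two ends of a pair, `l_s` the length of
a clipped segment, `m_d` the minimum deletion size, and `k` the number of
standard deviations used for the probabilistic windows (default 3).  All
formulas below are stated in 1-based closed coordinates; internally every
interval is 0-based half-open and the conversion happens only at the
formula boundary (this removes off-by-one hazards from interval unions
while letting each worked example reproduce digit for digit).

Two split-read configurations support a deletion:

* **Type I** — the mapped segment `[a, b]` of the split read faces its
  anchor; the clip must be placed upstream at `[c, d]`, `d < a`.  An
  independent *spanning pair* `([s1, e1], [s2, e2])` whose ends flank the
  deletion localizes the search:
  - the reverse end of a spanning pair satisfies
    `a <= s2 <= a - l1 - l2 + l_i + k*sigma`;
  - given such a pair, the clip start satisfies
    `e1 - l_s <= c <= min(e1 + l_i - l_s - l1 - l2 + k*sigma, a - m_d - l_s)`.
* **Type II** — the clip is anchor-proximal and the pair itself spans the
  deletion, mapped `[a, b]`, anchor `[s, e]`:
  `max(b + m_d, s - l_i - l_s + l1 + l2 - k*sigma) <= c <= s`.

With `l_s = 50`, `l1 = l2 = 100`, `l_i = 200`, `sigma = 50` the spanning
window is at most 150 bp wide and the total searched span of a type-I focal
region (admissible starts plus the clip footprint) is at most 200 bp —
orders of magnitude below a maximum-event-size scan, which is why no
maximum deletion size parameter exists.

Reverse-strand split reads with an upstream anchor use the mirror image of
each bound, obtained by reflecting every coordinate (`x -> R - x + 1`); a
property test checks the mirrored functions against reflected forward
outputs.  When several spanning pairs exist, their focal regions are
unioned (conservative against mis-mapped pairs); the union is capped at
5,000 bp of admissible positions per split read to guard against anchor
scatter, keeping the intervals nearest the mapped segment.

One deliberate refinement: the `l_1`, `l_2` entering the window formulas
are the *mapped spans* of the pair's ends, not the read lengths.  A
soft-clipped end contributes only its aligned footprint to the geometry;
using full read lengths shifts the window by the clip length and can push
the true clip start outside the focal region when a breakpoint-crossing
read serves as a pair end.

## Placement scoring

The clipped segment is placed by a fitting ("semi-global") alignment:
every segment base is consumed, region bases outside the aligned core are
free, and inside the core a match scores +1, a mismatch −1 and each gap
column −3 (linear gap cost; the gap parameter is per column, exposed as
`gap_penalty`).  `N` scores as a mismatch so masked sequence cannot attract
placements.  Ties are broken deterministically: smallest start of the
aligned core, then fewest gap columns.  Focal regions are a few hundred
bases, so the quadratic DP is not a bottleneck; an exhaustive-recursion
oracle verifies the DP on hundreds of random small instances.

A placement is accepted when its score reaches
`ceil((2*min_segment_identity - 1) * l_s)` — equivalent to demanding
`min_segment_identity` (default 0.8) matching bases in an ungapped
placement — and when the implied deletion is at least `m_d = 50` bp.  The
identity threshold and the minimum clip length (`min_clip_length = 20`)
are this package's choices where the method leaves the filter unstated:
20 bp keeps spurious placements rare under the default scoring (a random
20-mer reaches the 0.8-identity score in a ~500 bp region with probability
around 1e-4), while still accepting the canonical half-read clips of
100-bp reads.  Both are overridable.

## Breakpoint adjustment and voting

Soft-clip mappers occasionally extend an alignment past the true junction
by opening a short spurious gap, which shifts the implied deletion length
(typically by one).  For every supporting read whose mapped-side CIGAR or
clip placement contains an internal gap, the caller attempts a gap-free
re-split: with the two outer alignment ends fixed, the split point is moved
by up to 5 bases and both parts are rescored without gaps; the
rearrangement is adopted if its score is at least the original total
(mapped side plus placement).  Because the outer ends are fixed, the
adjusted deletion length equals the reference span between them minus the
read length — the engineered regression case turns an implied 101 bp back
into the true 100 bp.  After adjustment, reads are grouped by implied
deletion and the group with the highest summed alignment score wins the
vote (ties: more supporters, then leftmost); only agreeing reads stay in
the emitted call.

Single-read calls are clustered before adjustment by single-linkage on
both breakpoints within `adjacency_tolerance` (5 bp).  A cluster is emitted
when its summed pattern weight reaches `deletion_weight_cutoff` (3), with
type-I reads weighing 3 and type-II reads 1 — so one type-I read suffices,
or three type-II reads when no type-I read exists.  The asymmetry reflects
that type-I evidence re-places the read's 3' clip while the more reliable
5' head stays anchored.

## Insertion test

Insertions are detected from pairs of properly-paired reads whose 5' head
is soft-clipped: a reverse read whose tail maps ending at the breakpoint
and a forward read whose tail starts there.  If the clipped heads really
extended along the reference, each head would agree with the partner
read's bases over the reference positions the two reads share; heads drawn
from inserted sequence are unrelated to the partner.  The two head/partner
windows are aligned globally with the deletion-case scoring and the summed
score is divided by the summed overlap length; a fraction below 0.1 makes
the pair evidence (unrelated sequence has expected fraction ≈ −0.5, so the
threshold separates cleanly).  A breakpoint with at least
`insertion_support_cutoff` (3) supporting reads, from both strands, is
emitted, at the floor-midpoint when the two strands disagree within
tolerance.  The clipped heads are reported as the recovered prefix/suffix
of the inserted sequence.  Reads whose head mapping merely contains ≥2 gap
events are extracted as low-quality-head candidates but do not enter
pairing: without a clipped sequence there is nothing to run the overlap
test on.  Overlaps shorter than 10 bp are not judged.

## Library model estimation

`l_i` and `sigma` are estimated from up to 100,000 proper, fully-mapped FR
pairs as the sample mean and standard deviation of outer distances after
discarding the top 0.5% (stray discordant pairs would otherwise inflate
`sigma` and widen every window); at least 100 usable pairs are required,
otherwise the user must supply the values.  Anchors, and both ends of
candidate spanning pairs, must have mapping quality ≥ 20: a mis-placed
anchor poisons the focal region, so the filter is applied wherever a read
*positions* a search rather than merely supports it.

## Synthetic data

The bundled generator emulates a low-coverage paired-end study design:
a pseudo-random reference (default GC 0.41), two haplotypes with
heterozygous variants placed ≥2 kb apart and ≥1.5 kb from the ends, FR
pairs with outer distance Normal(500, 50), read length 100, and uniform
substitution errors (default 2%).  Coverage means total diploid depth:
`pairs = coverage * genome / (2 * read_len)`, so each haplotype receives
about half.  The default deletion-length mixture spans three strata —
70% in 60–1,000 bp, 25% in 1–7 kb, 5% in 7–12 kb — mimicking the
short-dominated length spectrum of population deletion callsets.
Insertions default to 150–500 bp of random sequence.

Instead of running an external mapper, each read's known donor coordinates
are projected onto the reference: breakpoint-crossing reads emit the major
side as the aligned block and the minor side as a soft clip (the geometry a
soft-clip-aware mapper reports), reads inside inserted sequence are
unmapped, and mate/proper-pair/TLEN fields are set so the output is valid
coordinate-sorted SAM.  What this does *not* emulate: mapping ambiguity in
repeats, chimeric fragments, indel sequencing errors, quality strings and
PCR duplicates.  Passing tests therefore demonstrate the geometric and
scoring logic of the caller, not robustness to mapper idiosyncrasies on
real genomes.

## Expected operating envelope (detection ceiling)

At 6× total depth a heterozygous deletion sits on a ~3× haplotype.  A
junction-crossing read needs ≥ `min_clip_length` = 20 bp on the clipped
side, so crossing candidates arrive at rate ≈ 0.03/bp × 61 bp ≈ Poisson(1.8)
per deletion, of which about half are type I.  With the default cutoff the
detection probability is
`P(N_I ≥ 1) + P(N_I = 0)·P(N_II ≥ 3) ≈ 0.63`, so exact-length sensitivity
around 55–70% at 6× (and roughly half that at 3×) is the information-
theoretic ceiling of these study conditions, not a tuning artifact;
precision stays near 100% because the identity threshold rejects spurious
placements.  Sensitivity rises with depth, longer reads, or pooling, which
is exactly the regime the method targets.

## Numerical and edge-case choices

* Window bounds are floored/ceiled to integers in the direction that keeps
  them conservative; empty bounds produce empty intervals, which simply
  drop the candidate.
* Focal regions are clamped to the chromosome; the fetched region is padded
  by 5 bp past the last admissible start so placements using a few gap
  columns remain reachable.
* The adjustment search moves at most 5 bases across the junction and is
  attempted only when a gap is present; gap-free groups are fixed points,
  making the operation idempotent.
* Deterministic tie-breaks everywhere (leftmost placement, smallest split
  shift, leftmost consensus interval) make repeated runs byte-identical.
* Overlapping deletion calls are both emitted; no reciprocal-overlap
  deduplication is applied.

## Evaluation conventions

Two deletion criteria: *strict* (an overlapping truth record of identical
length) and *overlap50* (≥50% of called bases supported, support
accumulating over multiple truth records).  One truth record may validate
several calls, but sensitivity counts each truth record once.  Insertions
are matched by breakpoint distance (default 10 bp) with one-to-one greedy
assignment.  Note the two deletion criteria are not nested in pathological
cases: an equal-length call shifted by more than half its length is strict-
correct but not overlap-correct; for split-read calls with small breakpoint
jitter the strict criterion is the stronger one.

## Limitations

Deletions shorter than `m_d` = 50 bp, tandem duplications, inversions and
translocations are out of scope, as is genotyping (a call does not state
hom/het).  Type-I calling requires at least one spanning pair by design —
there is no genome-wide fallback search.  The insertion caller reports
breakpoints and partial inserted sequence only; the inserted length is
unknown when it exceeds what the clipped heads cover.  The in-memory read
store targets focal-region-scale experiments (up to a few million records);
whole-genome use would stream per chromosome.
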