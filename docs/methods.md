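# Methods

This note records the model assumptions, the parameter surface, and the
design decisions made where the procedure was genuinely open, in the order
the pipeline runs.

## Motif families

Motifs of 1–6 bp are equivalence classes under three identifications:
cyclic rotation (phase), reverse complement (strand), and whole-multiple
reduction (ATAT → AT). The class is named by its lexicographically
smallest member, which is deterministic, human-readable, and coincides
with the conventional family names (A, AC, AAC, …). Primitivity is tested
by checking every divisor-length prefix; a non-primitive input is silently
reduced to its root rather than rejected, since a run of ATAT *is* a run
of AT. The catalogue over lengths 1–6 comprises 501 families and is
verified in the tests against an independent orbit enumeration of all
5,460 strings.

Input is case-insensitive; softmasked (lowercase) genome bases are treated
as ordinary bases throughout — masking is an explicit, separate input.

## Perfect locus scanning

A perfect locus is a maximal run with exact period p for one family,
found by comparing the sequence against itself shifted by p
(`seq[i] == seq[i+p]`): a chain of j−i matches starting at i spans the
period-p region [i, j+p). Design choices:

- **Partial trailing copies count.** Locus length is measured in bp, not
  repeat units; 13 bp of a trinucleotide is a 13 bp locus. A 12 bp
  minimum in units would be unsatisfiable for 5–6 bp motifs.
- **N and contig ends terminate runs**; a run shorter than its period
  leaves inner positions unchecked by the shifted comparison, so motifs
  containing N are rejected explicitly.
- **Non-primitive motifs are skipped per period**: a period-p region whose
  leading p-mer is a repeat of a shorter root has period |root|
  throughout and is already reported by the shorter-period scan.
- **Same-family runs that touch (0 bp gap, a phase shift at the junction,
  e.g. …ACACAC|CACACA…) are merged into one locus**: loci are distinct
  only when separated by at least one non-motif base. Different families
  may overlap freely and are all reported; downstream consumers decide
  precedence.
- Any starting phase is allowed and recorded (`repeat_phase`); loci are
  reported strand-agnostically on forward coordinates since families
  already fold in the reverse complement.

The default 12 bp minimum corresponds to the repeat length at which
slippage-driven expansion becomes likely. Equivalence with a brute-force
scanner that extends every (start, period) pair is asserted on random
sequences up to 200 bp.

## Flank profiling

Similarity between two equal-length segments is the proportion of
identical positions (ATAG vs AAAG = 0.75). The decay profile takes, at
every offset from a locus boundary, a motif-length segment read moving
away from the locus (mirrored on the left flank) and scores its **maximum**
similarity over all family members — the "closest repeat k-mer", which is
what phase-and-strand-folded families imply. Offsets reaching into the
locus itself (default inset 11 bp) are reported but are trivially
saturated. The background band is the mean ± sd of *per-locus-side window
means* over the distal 300–1000 bp range: the sd of single short segments
would be several-fold wider than the sampling spread of window means that
the band is meant to depict.

Neighbour-motif enrichment classifies same-length families by
phase-minimised Hamming distance from the focal motif (1 difference =
75% similar for a 4-mer, and so on). Observed (focal, neighbour) pair
counts per distance bin are divided by the genome-average expectation:
class density × 2 flanks × bin width × focal count, which is exactly 1
under uniform random placement. Overlapping loci carry no defined
separation and are excluded; each (focal, neighbour) pair is counted
once — the alternative (deduplicating overlapping neighbours) is noted
as an open ambiguity.

Perfect-run enrichment compares observed counts of maximal runs of ≥ r
motif units with the i.i.d. expectation from single-nucleotide
frequencies, with a left-boundary factor (1 − f(last motif base)) so a
run is counted once at its left-maximal start; gaps between consecutive
loci are binned at 5 bp.

## Cloud construction

Training uses a seeded random 90/10 locus split; families with fewer than
100 training loci are skipped. Training loci of one family closer than
100 bp are merged first so inter-locus sequence is not double counted,
then every 16-mer window fully inside a 50 bp flank (and outside any
supplied mask) is counted on the observed strand.

Expansion is the least fixed point of a monotone closure, so the result
is independent of processing order: starting from the family's
perfect-repeat 16-mers, any oligo at Hamming distance exactly 1
(substitutions only — the only reading that keeps k fixed) from an
in-cloud oligo joins if its strand-folded count (count(o) +
count(revcomp(o))) strictly exceeds the tier threshold; its reverse
complement joins with it, so clouds are strand-symmetric. The tests
assert equivalence with an exhaustive BFS over the complete Hamming graph
at k ≤ 6.

Tiers use strictly decreasing thresholds; tier sets are stored
cumulatively, so nesting (tier 1 ⊆ tier 2 ⊆ …) holds by construction.
Every 16-mer containing a ≥ 12 bp perfect run of the family (any phase,
any strand, arbitrary remaining 4 bp) is a tier-1 member automatically:
this is the uniform-k rendering of "perfect 12-mers belong to the highest
stringency cloud", and it is what gives the annotator sensitivity at the
12 bp perfect threshold. Oligos may belong to several families' clouds;
no cross-family deduplication is done.

Default tier thresholds scale with training volume as fractions
{1e-2, 1e-3, 1e-4} of the total counted flank windows, floored at 2.
These are a stated stand-in — the appropriate per-family values depend on
training depth and are fully config-overridable; at small training
volumes the floor collapses the tiers and the clouds reduce to their
automatic tier-1 membership.

## Annotation

A hit is exact set membership of the 16 bp window; a locus's extent is
the union of full hit windows, merged across families when separated by
at most `merge_dist` bp (presets 0/5/30, default 5; the union is merged
first, then ranked by the best tier found). Per family the locus records
the unweighted mean tier over covering oligo instances, the best tier,
and the fraction of locus bp covered. Per stringency tier t the locus
records the bp covered and the longest consecutive stretch covered by
oligos of tier ≤ t (tiers are nested, so "annotated by that stringency"
includes all stricter oligos); the longest perfect stretch uses only the
pure tandem 16-mers. Relaxing stringency can only extend coverage, so
annotated bp is non-decreasing and every stricter locus is contained in a
relaxed locus — both asserted in the tests.

Reference comparison (e.g. against Tandem Repeats Finder BED) reports
locus and bp recovery in both directions, novel loci, and the fraction of
overlapping cloud loci extending beyond the reference on one/both sides.
The grouped intersection operation attributes labelled target windows
(e.g. 30 bp downstream of retroelement termini, grouped by age class) to
the best stringency tier of a focal family among intersecting loci, with
other-family hits and misses reported separately.

## False positive and false discovery rates

Null genomes are simulated per window (default 1 Mb tiles; the stride is
configurable — tiles keep simulation addressable) from an order-1 Markov
chain: each base drawn conditional on its predecessor from the window's
dinucleotide frequencies, window starts from the marginal distribution.
Frequencies are estimated excluding masked positions and Ns (a masked
position also breaks dinucleotide adjacency); a fully masked window
inherits genome-wide frequencies and is flagged. Masked source positions
are *simulated*, not emitted as N: the null is a same-length
non-repetitive background, and N runs would deflate the analyzable bp.
Fifteen replicates share one frequency estimate (frequencies are
deterministic given the source). The simulator's empirical dinucleotide
distribution converges to the target (total-variation distance < 0.01 at
1 Mb, asserted at fixed seed).

The FPR table is indexed by (tier, length): the cumulative fraction of
simulated bp covered at that stringency within null loci whose longest
consecutive same-stringency stretch is that length **or longer**. Beyond
the longest null stretch the tail is exactly 0; for a length absent
within the observed range the nearest shorter length's (larger,
conservative) rate is used. Monotonicity — non-increasing in length,
non-decreasing as tiers relax — follows from the cumulative accounting
and tier nesting and is asserted over whole tables.

A real locus is keyed by its best tier and its longest stretch at that
tier; FDR = (FPR × analyzed bp) / observed cumulative annotated bp at
that setting, capped at 1. The analyzed bp conservatively includes the
real repeat regions (the entire genome is assumed non-SSR when computing
expected false bp). Scoring a pure null corpus against its own table
yields FDR 1 for every locus — the self-consistency check in the tests.

## Synthetic fixtures

The generator emulates the two ingredients the method depends on: a
background with controllable base (or order-1 dinucleotide) composition,
and planted tandem repeats decayed by per-base substitutions and indels —
a single-round caricature of the repeated interrupting-mutation process
that produces real detritus. Plants are inserted left-to-right with
spacers drawn from the background generator (so spacers carry no family
signal above chance); insertions shift downstream coordinates and the
truth table stores final post-indel coordinates plus realized mutation
counts, so interval comparisons are exact. What the fixtures do **not**
model: transposable-element structure (so the asymmetric flank bias of
retroelement poly-A tails has no synthetic analogue), GC heterogeneity,
and multi-round decay with slippage — passing tests demonstrate correct
mechanics and calibration on clean backgrounds, not performance on real
genomes.

## Test-scale choices

The parameter-recovery suite uses 20 seeded genomes of ~1 Mb with 120
plants per decay rate {0, 0.1, 0.2, 0.3} (family AC, 40 bp plants) and
the default scaled thresholds; it runs in well under a minute. At this
training depth the stringency gradient between tiers is modest (most
sensitivity sits in the automatic tier-1 membership), but the acceptance
properties — exact recovery of undecayed plants at the perfect tier,
recall non-increasing in decay, non-decreasing under tier relaxation —
are the scale-free signatures of the mechanism. The held-out check
(training vs test locus annotation lengths, rank-sum at α = 0.01) uses
300 planted loci so the 10% test split retains ~30 loci. Null
self-consistency tests use sparse k = 6 clouds, which hit random sequence
often enough to populate an FPR table from tens of kb of simulation;
k = 16 chance hits are (by design) far too rare for that at desk scale.

## Known limitations

- Exact-membership scanning cannot extend a locus across a 16-mer absent
  from every cloud, however similar; sensitivity is bounded by training
  volume through the count thresholds.
- Default thresholds are a volume-scaled stand-in, not tuned per family.
- FDR assumes the null chain captures the non-repetitive background;
  compositional features beyond dinucleotides (e.g. CpG islands) are not
  simulated and can inflate or deflate local false-positive rates.
- The per-locus FDR is conservative for genomes with a large true repeat
  fraction, since expected false bp is computed over the full genome.
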