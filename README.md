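# ssrclouds

Annotation of simple sequence repeats (SSRs, microsatellites) **and their
decayed, ancient remnants** in genomic sequence, using nested clouds of
16-mer oligonucleotides, with a per-locus false discovery rate estimated on
Markov-simulated null genomes.

Standard tandem-repeat annotators score alignments against a perfect repeat
and therefore miss loci that have accumulated many interrupting mutations.
But the sequence flanking live SSRs is a *detritus field*: it remains
measurably biased toward the repeat motif for 50–100 bp, because repeats
constantly slough off mutated copies and spawn new loci nearby. `ssrclouds`
exploits that bias directly. It is aimed at genome annotators and repeat
biologists who need sensitivity to dead or degenerate repeats and an
explicit error rate for every call.

## Method

1. **Motif families.** Every 1–6 bp motif is reduced to its primitive root
   and grouped with all its rotations and their reverse complements:
   AAC ≡ ACA ≡ CAA ≡ GTT ≡ TGT ≡ TTG. The 501 resulting families partition
   all primitive motifs.
2. **Perfect loci.** Maximal uninterrupted tandem runs of one family
   (no substitution, indel, or phase shift) of at least 12 bp — the
   empirical slippage-threshold length — are annotated for every family
   simultaneously; coordinates are BED-style 0-based half-open.
3. **Nested clouds.** For each family with ≥ 100 loci, 90% of loci are used
   for training: every 16-mer in the 50 bp flanks is counted (loci of the
   same family closer than 100 bp are merged first), and clouds grow from
   the family's perfect-repeat 16-mers by admitting any oligo whose
   strand-folded count exceeds the tier threshold and that sits at Hamming
   distance 1 from an oligo already in the cloud. Decreasing thresholds
   give nested stringency tiers (tier 1 ⊆ tier 2 ⊆ tier 3); every 16-mer
   containing a ≥ 12 bp perfect run is a tier-1 member automatically.
4. **Annotation.** The genome is scanned with all families' clouds at once
   (exact 16-mer membership); covered windows within 5 bp merge into loci,
   each ranked by its most stringent tier and reported with per-family
   mean stringency and coverage.
5. **FDR.** Null genomes are simulated per 1 Mb window from an order-1
   Markov chain fitted to the repeat-masked source (15 replicates).
   Annotating them yields a cumulative false positive rate per
   (tier, length-or-longer), where length is the longest stretch
   consecutively covered at that stringency. Each real locus then receives
   FDR = expected false bp / observed annotated bp at its setting, capped
   at 1.

## Worked example

```python
from ssrclouds import (PlantSpec, make_planted_genome, scan_genome,
                       build_cloudset, annotate, estimate_frequencies,
                       simulate_null_genome, build_fpr_table, assign_fdr)

# 1. toy genome: 200 perfect + 80 decayed (AC)n repeats in 300 kb background
genome, truth = make_planted_genome(
    300_000,
    [PlantSpec("AC", perfect_length=40, copies=200, spacer_length=(600, 1000)),
     PlantSpec("AC", perfect_length=40, copies=80,
               decay_substitution_rate=0.2, spacer_length=(600, 1000))],
    seed=1,
)

# 2. perfect loci and nested clouds for the AC family
loci = scan_genome(genome, families={"AC"})
clouds, held_out = build_cloudset(genome, loci, family="AC", seed=1)
print(f"{len(loci)} perfect loci; tier sizes:",
      [len(t.oligos) for t in clouds.tiers])

# 3. annotate, then attach FDRs from 15 simulated null genomes
annotated = annotate(genome, [clouds], merge_dist=5)
tracks = estimate_frequencies(genome, window=1_000_000)
nulls = simulate_null_genome(tracks, replicates=15, seed=1)
null_loci, sim_bp = [], 0
for g in nulls:
    sim_bp += sum(len(s) for s in g.values())
    null_loci += annotate(g, [clouds], merge_dist=5)
table = build_fpr_table(null_loci, sim_bp)
assign_fdr(annotated, table, analyzed_bp=sum(len(s) for s in genome.values()))

bp = sum(l.length for l in annotated)
confident = [l for l in annotated if l.fdr <= 0.05]
print(f"{len(annotated)} cloud loci covering {bp} bp "
      f"({bp / sum(len(s) for s in genome.values()):.2%} of the genome)")
print(f"{len(confident)} loci at FDR <= 5%; "
      f"{len(null_loci)} null loci in {sim_bp} simulated bp")
```

Output:

```
233 perfect loci; tier sizes: [4096, 4096, 4096]
229 cloud loci covering 10481 bp (3.37% of the genome)
229 loci at FDR <= 5%; 5 null loci in 4668000 simulated bp
```

The 233 perfect loci are the planted perfect repeats plus the uninterrupted
stretches surviving inside the decayed plants. The cloud annotation merges
and extends them into 229 loci; at this training volume the scaled default
thresholds admit no extra oligos beyond the 4096 automatic tier-1 members
(16-mers containing a ≥ 12 bp perfect run), so sensitivity beyond the
perfect repeats comes from those embedded-run oligos. Only 5 chance loci
arise in 4.7 Mb of simulated null sequence, so every real locus clears the
5% FDR bar.

The same pipeline is scriptable from the shell:

```bash
ssrclouds fixture --spec fixture.yaml --out toy.fa --truth truth.bed
ssrclouds scan-perfect toy.fa --out perfect.bed
ssrclouds build --genome toy.fa --perfect perfect.bed --out clouds/
ssrclouds annotate --genome toy.fa --clouds clouds/ --merge 5 --out loci.bed
ssrclouds fdr --genome toy.fa --clouds clouds/ --replicates 15 --seed 1 --out fpr.tsv
```

## Scope notes

Cloud annotation uses exact 16-mer membership — all fuzziness lives in the
cloud contents, keeping genome scanning a hash lookup. Running
RepeatMasker or Tandem Repeats Finder is out of scope: their outputs are
consumed (`.out` masks, BED comparisons) but never produced.
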