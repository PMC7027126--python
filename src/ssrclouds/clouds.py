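"""Construction of nested SSR oligo clouds.

For each motif family, the 50 bp flanks of its perfect loci are used as
training sequence: every 16-mer window fully inside a flank is counted,
and clouds are grown from the family's perfect-repeat 16-mers by
repeatedly admitting any oligo whose (strand-folded) count exceeds the
tier threshold and that lies at Hamming distance 1 from an oligo
already in the cloud.  Decreasing thresholds give nested tiers: tier 1
(highest stringency) is a subset of tier 2, and so on.  Oligos
containing a >= 12 bp perfect run of the family motif are always
members of tier 1.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from ._intervals import merge_intervals
from .motifs import DNA_ALPHABET, family_members, reverse_complement
from .perfect import PerfectLocus, merge_same_family


@dataclass(frozen=True)
class CloudTier:
    """One stringency tier; ``oligos`` includes all higher tiers (nesting)."""

    stringency_rank: int  # 1 = highest stringency
    core_threshold: float
    oligos: frozenset[str] = field(repr=False)


@dataclass
class CloudSet:
    """Per-family nested oligo clouds with build provenance."""

    family: str
    k: int
    tiers: list[CloudTier]
    perfect_oligos: frozenset[str] = field(repr=False)
    training_locus_count: int = 0
    flank_width: int = 50
    train_fraction: float = 0.9
    seed: int | None = None

    def tier_of(self, oligo: str) -> int | None:
        """Most stringent tier rank containing ``oligo`` (None if absent)."""
        for tier in self.tiers:
            if oligo in tier.oligos:
                return tier.stringency_rank
        return None

    @property
    def all_oligos(self) -> frozenset[str]:
        return self.tiers[-1].oligos if self.tiers else self.perfect_oligos


def split_train_test(
    loci: list[PerfectLocus], fraction: float = 0.9, seed: int | None = None
) -> tuple[list[PerfectLocus], list[PerfectLocus]]:
    """Random disjoint train/test split of loci, reproducible by seed."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not loci:
        raise ValueError("no loci to split")
    idx = list(range(len(loci)))
    random.Random(seed).shuffle(idx)
    n_train = int(fraction * len(loci))
    train_idx = set(idx[:n_train])
    train = [l for i, l in enumerate(loci) if i in train_idx]
    test = [l for i, l in enumerate(loci) if i not in train_idx]
    return train, test


def count_flank_kmers(
    genome: dict[str, str],
    train_intervals: list[tuple[str, int, int, str]] | list[PerfectLocus],
    flank_width: int = 50,
    k: int = 16,
    mask: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, int]:
    """Counts of every k-mer window fully inside a training-locus flank.

    ``train_intervals`` should already be merged per family at the
    100 bp training gap so inter-locus sequence is not double counted.
    Windows overlapping a masked interval (e.g. RepeatMasker
    transposable elements) or containing N are skipped; flanks are
    truncated at contig ends.  Counts are of the observed strand;
    strand folding happens at cloud-build time.
    """
    if k > flank_width:
        raise ValueError(f"k={k} exceeds flank_width={flank_width}")
    ivs: list[tuple[str, int, int]] = []
    for item in train_intervals:
        if isinstance(item, PerfectLocus):
            ivs.append((item.chrom, item.start, item.end))
        else:
            ivs.append((item[0], item[1], item[2]))
    masked = {
        chrom: merge_intervals(list(iv_list))
        for chrom, iv_list in (mask or {}).items()
    }
    counts: dict[str, int] = {}
    for chrom, start, end in ivs:
        seq = genome[chrom]
        flanks = [
            (max(0, start - flank_width), start),
            (end, min(len(seq), end + flank_width)),
        ]
        for fs, fe in flanks:
            for i in range(fs, fe - k + 1):
                if masked and _window_masked(chrom, i, i + k, masked):
                    continue
                w = seq[i : i + k]
                if "N" in w:
                    continue
                counts[w] = counts.get(w, 0) + 1
    return counts


def _window_masked(chrom, start, end, masked) -> bool:
    from ._intervals import overlaps_any

    ivs = masked.get(chrom)
    return bool(ivs) and overlaps_any(start, end, ivs)


def perfect_repeat_kmers(family: str, k: int = 16) -> frozenset[str]:
    """All k-mers that are pure tandem repeat of the family (any phase/strand)."""
    out = set()
    for m in family_members(family):
        out.add((m * (k // len(m) + 2))[:k])
    return frozenset(out)


def embedded_run_kmers(
    family: str, k: int = 16, run_length: int = 12
) -> frozenset[str]:
    """k-mers containing a >= ``run_length`` bp perfect run of the family.

    These are the guaranteed tier-1 members: a 16-mer with a 12 bp
    perfect repeat inside it is itself evidence of a perfect locus.
    For run_length >= k this degenerates to the pure tandem k-mers.
    """
    if run_length >= k:
        return perfect_repeat_kmers(family, k)
    out = set()
    rest = k - run_length
    tandems = {
        (m * (run_length // len(m) + 2))[:run_length]
        for m in family_members(family)
    }
    for t in tandems:
        for s in range(rest + 1):
            for fill in itertools.product(DNA_ALPHABET, repeat=rest):
                out.add("".join(fill[:s]) + t + "".join(fill[s:]))
    return frozenset(out)


def hamming1_neighbors(oligo: str):
    """Yield the 3*k strings at Hamming distance exactly 1 from ``oligo``."""
    for i, c in enumerate(oligo):
        for b in DNA_ALPHABET:
            if b != c:
                yield oligo[:i] + b + oligo[i + 1 :]


def fold_counts(counts: dict[str, int]) -> dict[str, int]:
    """Strand-symmetric counts: count(o) + count(revcomp(o)) for each o."""
    folded: dict[str, int] = {}
    for o, c in counts.items():
        rc = reverse_complement(o)
        folded[o] = c + (counts.get(rc, 0) if rc != o else 0)
        if rc not in folded:
            folded[rc] = folded[o]
    return folded


def _expand(seeds: frozenset[str], candidates: dict[str, int]) -> set[str]:
    """Fixed-point Hamming-1 closure of ``seeds`` through ``candidates``.

    The result is the least fixed point of a monotone closure, so it is
    independent of processing order.  Reverse complements are admitted
    with their mates (candidate counts are strand-folded, so the
    candidate set is itself strand-symmetric).
    """
    cloud = set(seeds)
    frontier = list(seeds)
    while frontier:
        o = frontier.pop()
        for nb in hamming1_neighbors(o):
            if nb in candidates and nb not in cloud:
                rc = reverse_complement(nb)
                cloud.add(nb)
                frontier.append(nb)
                if rc not in cloud:
                    cloud.add(rc)
                    frontier.append(rc)
    return cloud


def build_nested_clouds(
    counts: dict[str, int],
    thresholds: list[float],
    family: str,
    k: int = 16,
    perfect_run_length: int = 12,
    **provenance,
) -> CloudSet:
    """Grow the nested cloud tiers for one family from flank k-mer counts.

    ``thresholds`` are strictly decreasing counts, one per tier from
    highest to lowest stringency; an oligo joins a tier's expansion if
    its strand-folded count is strictly above the tier threshold and it
    is Hamming-1 reachable from the family's perfect-repeat oligos
    through in-cloud oligos.  Tier sets are cumulative, so nesting
    holds by construction.
    """
    if not thresholds:
        raise ValueError("at least one tier threshold required")
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly decreasing: {thresholds}")
    perfect = perfect_repeat_kmers(family, k)
    tier1_base = frozenset(
        perfect | embedded_run_kmers(family, k, perfect_run_length)
    )
    folded = fold_counts(counts)
    tiers: list[CloudTier] = []
    prev: set[str] = set()
    for rank, thr in enumerate(thresholds, start=1):
        candidates = {o: c for o, c in folded.items() if c > thr}
        cloud = _expand(tier1_base, candidates) | prev
        if rank == 1:
            cloud |= tier1_base
        tiers.append(
            CloudTier(
                stringency_rank=rank,
                core_threshold=thr,
                oligos=frozenset(cloud),
            )
        )
        prev = cloud
    return CloudSet(
        family=family,
        k=k,
        tiers=tiers,
        perfect_oligos=perfect,
        **provenance,
    )


def default_thresholds(
    total_windows: int,
    fractions: tuple[float, ...] = (1e-2, 1e-3, 1e-4),
    floor: int = 2,
) -> list[float]:
    """Per-family tier thresholds scaled to the training volume.

    Each tier threshold is a fraction of the total number of counted
    flank windows, floored at ``floor``; duplicate values collapse to
    fewer tiers.
    """
    vals = []
    for f in fractions:
        v = max(float(floor), total_windows * f)
        if not vals or v < vals[-1]:
            vals.append(v)
    return vals


def build_cloudset(
    genome: dict[str, str],
    loci: list[PerfectLocus],
    family: str | None = None,
    thresholds: list[float] | None = None,
    k: int = 16,
    flank_width: int = 50,
    train_fraction: float = 0.9,
    train_merge_gap: int = 100,
    min_training_loci: int = 100,
    mask: dict[str, list[tuple[int, int]]] | None = None,
    seed: int | None = None,
) -> tuple[CloudSet | None, list[PerfectLocus]]:
    """Train/test split, flank counting and cloud construction in one call.

    Returns (cloudset, test_loci); the cloudset is None when the family
    has fewer than ``min_training_loci`` training loci.
    """
    if family is not None:
        loci = [l for l in loci if l.family == family]
    else:
        fams = {l.family for l in loci}
        if len(fams) != 1:
            raise ValueError("pass a single family or homogeneous loci")
        family = fams.pop()
    if not loci:
        return None, []
    train, test = split_train_test(loci, train_fraction, seed)
    if len(train) < min_training_loci:
        return None, test
    merged = merge_same_family(train, gap=train_merge_gap)
    counts = count_flank_kmers(genome, merged, flank_width, k, mask)
    if thresholds is None:
        thresholds = default_thresholds(sum(counts.values()))
    cs = build_nested_clouds(
        counts,
        thresholds,
        family,
        k,
        training_locus_count=len(train),
        flank_width=flank_width,
        train_fraction=train_fraction,
        seed=seed,
    )
    return cs, test
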