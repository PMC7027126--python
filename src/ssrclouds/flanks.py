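"""Sequence bias around perfect SSR loci.

The regions flanking live SSRs carry the mutated detritus of past
repeat activity: segments near a locus stay measurably similar to the
repeated motif for tens of bp, and new SSR loci with similar motifs
cluster near existing ones.  This module computes the descriptive
statistics of that bias: per-offset similarity-decay profiles,
enrichment of similar-motif neighbours, separation histograms, and
enrichment of perfect runs over an i.i.d. base-composition expectation.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .motifs import family_members, family_of
from .perfect import PerfectLocus


class EmptyProfileError(ValueError):
    """Raised when a profile is requested for zero loci."""


def similarity(segment: str, motif: str) -> float:
    """Proportion of positions at which two equal-length strings agree.

    E.g. ``similarity("ATAG", "AAAG") == 0.75``.
    """
    if len(segment) != len(motif):
        raise ValueError(
            f"lengths differ: {len(segment)} vs {len(motif)}"
        )
    if not segment:
        raise ValueError("empty strings")
    return sum(a == b for a, b in zip(segment, motif)) / len(segment)


@dataclass
class FlankProfile:
    """Mean per-offset motif similarity around one family's loci.

    Offsets are distances in bp from a locus boundary; offset 1 is the
    first base outside the locus, negative offsets reach ``inset`` bp
    into the locus itself (reported but flagged, since those bases are
    part of the perfect repeat).  Both flanks are pooled: the right
    flank is read leaving the locus; the left flank is compared after
    the same outward reading (segments are compared against every
    family member, which folds in strand and phase).
    """

    family: str
    offsets: np.ndarray
    mean_similarity: np.ndarray
    n_segments: np.ndarray
    background_mean: float
    background_sd: float
    inset: int = 11

    def elevated(self, n_sd: float = 3.0) -> np.ndarray:
        """Boolean mask of offsets above background mean + n_sd * sd."""
        return self.mean_similarity > self.background_mean + n_sd * self.background_sd


def _max_similarity(segment: str, members: frozenset[str]) -> float | None:
    if "N" in segment:
        return None
    return max(similarity(segment, m) for m in members)


def flank_similarity_profile(
    genome: dict[str, str],
    loci: list[PerfectLocus],
    window: int = 200,
    background_range: tuple[int, int] = (300, 1000),
    inset: int = 11,
) -> FlankProfile:
    """Similarity-decay profile for one family's loci.

    At every offset d in ``-inset..window`` from each locus boundary, a
    segment of motif length is taken (moving away from the locus on the
    right flank, mirrored on the left flank) and scored with the
    maximum :func:`similarity` over all family members (all phases and
    the reverse complement).  The background mean/sd come from segments
    in the distal ``background_range`` on both sides.
    """
    if not loci:
        raise EmptyProfileError("no loci supplied")
    fams = {l.family for l in loci}
    if len(fams) != 1:
        raise ValueError(f"loci must be a single family, got {sorted(fams)}")
    family = fams.pop()
    members = family_members(family)
    p = len(family)

    offsets = np.arange(-inset, window + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=int)
    bg_vals: list[float] = []
    b0, b1 = background_range

    for loc in loci:
        seq = genome[loc.chrom]
        for k, d in enumerate(offsets):
            for side in ("left", "right"):
                if side == "right":
                    s = loc.end + d - 1  # d=1 -> first base outside
                else:
                    s = loc.start - d + 1 - p  # segment ending d bp left
                if s < 0 or s + p > len(seq):
                    continue
                val = _max_similarity(seq[s : s + p], members)
                if val is not None:
                    sums[k] += val
                    counts[k] += 1
        # background: one mean per locus side over the distal window, so the
        # band reflects the sampling spread of window means, not of single
        # short segments
        for sign in (+1, -1):
            vals = []
            for d in range(b0, b1 + 1 - p):
                s = loc.end + d if sign > 0 else loc.start - d - p
                if s < 0 or s + p > len(seq):
                    continue
                val = _max_similarity(seq[s : s + p], members)
                if val is not None:
                    vals.append(val)
            if vals:
                bg_vals.append(float(np.mean(vals)))

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if bg_vals:
        bg_mean, bg_sd = float(np.mean(bg_vals)), float(np.std(bg_vals))
    else:  # contigs too short to reach the distal range
        bg_mean = bg_sd = float("nan")
    return FlankProfile(
        family=family,
        offsets=offsets,
        mean_similarity=mean,
        n_segments=counts,
        background_mean=bg_mean,
        background_sd=bg_sd,
        inset=inset,
    )


def motif_difference(family_a: str, family_b: str) -> int | None:
    """Minimum Hamming distance over all phase/strand alignments.

    Defined only for families of equal motif length; returns None
    otherwise.  Two members are compared position-by-position, so a
    1-difference neighbour of a 4 bp motif is 75% similar to it.
    """
    ma, mb = family_members(family_a), family_members(family_b)
    if len(family_a) != len(family_b):
        return None
    best = len(family_a)
    for a in ma:
        for b in mb:
            d = sum(x != y for x, y in zip(a, b))
            if d < best:
                best = d
    return best


@dataclass
class EnrichmentProfile:
    """Observed/expected neighbour-locus counts by distance and difference."""

    focal_family: str
    bins: list[tuple[int, int]]
    difference_classes: tuple[int, ...]
    observed: dict[int, np.ndarray] = field(repr=False)
    expected: dict[int, np.ndarray] = field(repr=False)

    def enrichment(self, diff_class: int) -> np.ndarray:
        exp = self.expected[diff_class]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(exp > 0, self.observed[diff_class] / exp, np.nan)


def nearby_motif_enrichment(
    loci: list[PerfectLocus],
    focal_family: str,
    genome_length: int,
    max_dist: int = 100,
    bin_width: int = 10,
    difference_classes: tuple[int, ...] = (1, 2, 3),
) -> EnrichmentProfile:
    """Enrichment of similar-motif neighbour loci near a focal family.

    For each difference class c, the candidate neighbour families are
    the same-motif-length families at phase-minimised Hamming distance
    c from the focal motif.  Observed counts are (focal locus,
    neighbour locus) pairs whose edge separation falls in each distance
    bin; the expectation is the genome-wide density of class-c loci
    times the bp surveyed (2 flanks x bin width x number of focal
    loci), i.e. enrichment is 1 under uniform random placement.
    """
    focal = [l for l in loci if l.family == focal_family]
    if not focal:
        raise EmptyProfileError(f"no loci of family {focal_family}")
    bins = [(b, b + bin_width) for b in range(0, max_dist, bin_width)]
    class_of: dict[str, int] = {}
    for fam in {l.family for l in loci}:
        d = motif_difference(focal_family, fam)
        if d in difference_classes:
            class_of[fam] = d

    observed = {c: np.zeros(len(bins)) for c in difference_classes}
    counts_by_class = Counter(
        class_of[l.family] for l in loci if l.family in class_of
    )
    by_chrom: dict[str, list[PerfectLocus]] = {}
    for l in loci:
        if l.family in class_of:
            by_chrom.setdefault(l.chrom, []).append(l)

    for f in focal:
        for nb in by_chrom.get(f.chrom, []):
            if nb is f:
                continue
            if nb.start >= f.end:
                dist = nb.start - f.end
            elif nb.end <= f.start:
                dist = f.start - nb.end
            else:
                continue  # overlapping loci carry no separation distance
            if dist >= max_dist:
                continue
            observed[class_of[nb.family]][dist // bin_width] += 1

    expected = {}
    for c in difference_classes:
        density = counts_by_class.get(c, 0) / genome_length
        expected[c] = np.full(len(bins), density * bin_width * 2 * len(focal))
    return EnrichmentProfile(
        focal_family=focal_family,
        bins=bins,
        difference_classes=tuple(difference_classes),
        observed=observed,
        expected=expected,
    )


def separation_histogram(
    loci: list[PerfectLocus], bin_width: int = 5
) -> Counter[int]:
    """Histogram of gaps between consecutive loci (any family), binned.

    Keys are bin lower bounds (gap // bin_width * bin_width); values are
    gap counts.  Gaps are measured between consecutive loci per chrom in
    start order; overlapping loci (negative gap) are not counted.
    """
    hist: Counter[int] = Counter()
    by_chrom: dict[str, list[PerfectLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for ls in by_chrom.values():
        ls = sorted(ls, key=lambda l: (l.start, l.end))
        for a, b in zip(ls, ls[1:]):
            gap = b.start - a.end
            if gap >= 0:
                hist[(gap // bin_width) * bin_width] += 1
    return hist


def base_frequencies(genome: dict[str, str]) -> dict[str, float]:
    counts = Counter()
    for seq in genome.values():
        counts.update(seq.upper())
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        raise ValueError("genome has no ACGT bases")
    return {b: counts[b] / total for b in "ACGT"}


def perfect_repeat_enrichment(
    genome: dict[str, str],
    family_group: list[str],
    repeat_units: int,
) -> float:
    """Observed / expected count of runs of >= ``repeat_units`` motif copies.

    The expectation assumes i.i.d. bases at the genome's single-
    nucleotide frequencies: for each member motif m of each family in
    the group, a maximal run of >= r copies starts at a position with
    probability (1 - f(m[-1])) * prod_j f(m[j mod p]) over r*p bases
    (the leading factor enforces that the run does not extend left).
    """
    freqs = base_frequencies(genome)
    total_len = sum(len(s) for s in genome.values())

    observed = 0
    expected = 0.0
    for fam in family_group:
        p = len(fam)
        need = repeat_units * p
        from .perfect import scan_perfect

        for chrom, seq in genome.items():
            for loc in scan_perfect(seq, min_length=max(need, p + 1),
                                    families={fam}, chrom=chrom):
                if loc.length >= need:
                    observed += 1
        for m in family_members(fam):
            prob = 1.0
            for j in range(need):
                prob *= freqs[m[j % p]]
            expected += (1 - freqs[m[p - 1]]) * prob * total_len
    if expected == 0:
        return float("inf") if observed else float("nan")
    return observed / expected
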