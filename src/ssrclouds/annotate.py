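"""Genome annotation with SSR clouds.

All families' cloud oligos are mapped simultaneously: every k-bp window
of the genome that is an exact member of any cloud contributes its full
window to the covered set.  Covered intervals separated by at most
``merge_dist`` bp are merged into loci, each ranked by the most
stringent tier found in it.  A locus records, per family, the mean
stringency and the fraction of its bp covered by that family's oligos,
plus the longest consecutive stretch covered at each stringency -- the
quantity the false-discovery machinery keys on.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._intervals import intersect_bp, merge_intervals
from .clouds import CloudSet


@dataclass
class FamilyComposition:
    family: str
    mean_tier: float
    best_tier: int
    coverage: float  # fraction of locus bp covered by this family's oligos


@dataclass
class CloudLocus:
    """Merged cloud-annotated interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    best_tier: int
    per_family: list[FamilyComposition]
    longest_perfect_stretch: int
    longest_tier_stretch: dict[int, int]  # tier rank -> longest run (bp)
    tier_covered_bp: dict[int, int]  # tier rank -> covered bp in locus
    fdr: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max())


def build_oligo_index(
    cloudsets: list[CloudSet],
) -> dict[str, list[tuple[str, int, bool]]]:
    """Map oligo -> [(family, tier rank, is perfect-repeat oligo)]."""
    index: dict[str, list[tuple[str, int, bool]]] = {}
    for cs in cloudsets:
        for oligo in cs.all_oligos:
            rank = cs.tier_of(oligo)
            index.setdefault(oligo, []).append(
                (cs.family, rank, oligo in cs.perfect_oligos)
            )
    return index


def annotate(
    genome: dict[str, str],
    cloudsets: list[CloudSet],
    merge_dist: int = 5,
) -> list[CloudLocus]:
    """Annotate a genome with every family's clouds at once.

    Covered intervals within ``merge_dist`` bp of each other collapse
    into one locus (the default 5 bp matches the primary annotation;
    0 and 30 bp are the usual alternative presets).
    """
    if not cloudsets:
        raise ValueError("no cloud sets supplied")
    ks = {cs.k for cs in cloudsets}
    if len(ks) != 1:
        raise ValueError(f"cloud sets disagree on k: {sorted(ks)}")
    k = ks.pop()
    index = build_oligo_index(cloudsets)
    n_tiers = max(len(cs.tiers) for cs in cloudsets)

    loci: list[CloudLocus] = []
    for chrom in genome:
        seq = genome[chrom].upper()
        L = len(seq)
        if L < k:
            continue
        hits: list[tuple[int, str, int, bool]] = []
        for i in range(L - k + 1):
            entry = index.get(seq[i : i + k])
            if entry:
                for fam, rank, perf in entry:
                    hits.append((i, fam, rank, perf))
        if not hits:
            continue
        covered = np.zeros(L, dtype=bool)
        for i, _, _, _ in hits:
            covered[i : i + k] = True
        # merge covered runs with gaps <= merge_dist
        runs = _runs(covered)
        merged = merge_intervals(runs, gap=merge_dist)

        hits.sort()
        hit_pos = [h[0] for h in hits]
        for ls, le in merged:
            lo = bisect.bisect_left(hit_pos, ls - k + 1)
            hi = bisect.bisect_left(hit_pos, le)
            lhits = [h for h in hits[lo:hi] if h[0] + k > ls and h[0] < le]
            loci.append(
                _make_locus(chrom, ls, le, lhits, k, n_tiers)
            )
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    d = np.diff(padded)
    return list(
        zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist())
    )


def _make_locus(
    chrom: str,
    ls: int,
    le: int,
    hits: list[tuple[int, str, int, bool]],
    k: int,
    n_tiers: int,
) -> CloudLocus:
    n = le - ls
    tier_masks = {t: np.zeros(n, dtype=bool) for t in range(1, n_tiers + 1)}
    perfect_mask = np.zeros(n, dtype=bool)
    fam_tiers: dict[str, list[int]] = {}
    fam_masks: dict[str, np.ndarray] = {}
    for pos, fam, rank, perf in hits:
        a = max(pos, ls) - ls
        b = min(pos + k, le) - ls
        for t in range(rank, n_tiers + 1):  # tiers are cumulative
            tier_masks[t][a:b] = True
        if perf:
            perfect_mask[a:b] = True
        fam_tiers.setdefault(fam, []).append(rank)
        if fam not in fam_masks:
            fam_masks[fam] = np.zeros(n, dtype=bool)
        fam_masks[fam][a:b] = True
    per_family = [
        FamilyComposition(
            family=fam,
            mean_tier=float(np.mean(fam_tiers[fam])),
            best_tier=min(fam_tiers[fam]),
            coverage=float(fam_masks[fam].mean()),
        )
        for fam in fam_tiers
    ]
    per_family.sort(key=lambda fc: (-fc.coverage, fc.family))
    best = min(r for _, _, r, _ in hits)
    return CloudLocus(
        chrom=chrom,
        start=ls,
        end=le,
        best_tier=best,
        per_family=per_family,
        longest_perfect_stretch=_longest_run(perfect_mask),
        longest_tier_stretch={
            t: _longest_run(m) for t, m in tier_masks.items()
        },
        tier_covered_bp={t: int(m.sum()) for t, m in tier_masks.items()},
    )


def per_family_report(locus: CloudLocus):
    """Family composition of a locus as a DataFrame, coverage-descending."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "family": fc.family,
                "mean_tier": fc.mean_tier,
                "best_tier": fc.best_tier,
                "coverage": fc.coverage,
            }
            for fc in locus.per_family
        ]
    )


def compare_to_reference(
    cloud_loci: list[CloudLocus],
    reference: list[tuple[str, int, int]],
) -> dict:
    """Recovery statistics of cloud loci against a reference interval set
    (e.g. Tandem Repeats Finder output converted to BED).

    Reports overlap counts and bp in both directions, novel cloud loci,
    and the fraction of overlapping cloud loci that extend beyond the
    reference boundaries on at least one / on both sides.
    """
    cloud_chroms = {l.chrom for l in cloud_loci}
    ref_chroms = {r[0] for r in reference}
    for c in sorted(ref_chroms - cloud_chroms | cloud_chroms - ref_chroms):
        warnings.warn(f"chromosome {c!r} present in only one interval set")

    ref_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in reference:
        ref_by_chrom.setdefault(c, []).append((s, e))
    for c in ref_by_chrom:
        ref_by_chrom[c].sort()

    n_overlap = 0
    bp_overlap_loci = 0
    bp_intersection = 0
    novel = 0
    novel_bp = 0
    extend_one = 0
    extend_both = 0
    for l in cloud_loci:
        refs = ref_by_chrom.get(l.chrom, [])
        over = [r for r in refs if r[0] < l.end and r[1] > l.start]
        if over:
            n_overlap += 1
            bp_overlap_loci += l.length
            bp_intersection += intersect_bp([l.interval], over)
            left = l.start < min(r[0] for r in over)
            right = l.end > max(r[1] for r in over)
            if left and right:
                extend_both += 1
            if left or right:
                extend_one += 1
        else:
            novel += 1
            novel_bp += l.length

    cloud_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for l in cloud_loci:
        cloud_by_chrom.setdefault(l.chrom, []).append(l.interval)
    n_ref = len(reference)
    n_ref_recovered = 0
    ref_bp = 0
    ref_bp_recovered = 0
    for c, s, e in reference:
        ref_bp += e - s
        clouds = cloud_by_chrom.get(c, [])
        over = [iv for iv in clouds if iv[0] < e and iv[1] > s]
        if over:
            n_ref_recovered += 1
            ref_bp_recovered += intersect_bp([(s, e)], over)
    return {
        "n_cloud_loci": len(cloud_loci),
        "n_cloud_overlapping": n_overlap,
        "bp_overlapping_cloud_loci": bp_overlap_loci,
        "bp_intersection": bp_intersection,
        "n_novel": novel,
        "novel_bp": novel_bp,
        "n_reference": n_ref,
        "n_reference_recovered": n_ref_recovered,
        "reference_bp": ref_bp,
        "reference_bp_recovered": ref_bp_recovered,
        "frac_extend_one_side": extend_one / n_overlap if n_overlap else 0.0,
        "frac_extend_both_sides": extend_both / n_overlap if n_overlap else 0.0,
    }


def grouped_intersection(
    targets: list[tuple[str, int, int, str]],
    cloud_loci: list[CloudLocus],
    focal_family: str | None = None,
) -> dict[str, dict[str, int]]:
    """Per-group counts of target windows by best intersecting stringency.

    Each target (chrom, start, end, group) is attributed to the highest
    stringency tier of the focal family found among intersecting loci;
    targets whose loci carry only other families count as
    ``other_family``; targets with no intersecting locus as ``no_hit``.
    With ``focal_family=None`` any family counts toward the tiers.
    """
    by_chrom: dict[str, list[CloudLocus]] = {}
    for l in cloud_loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    result: dict[str, dict[str, int]] = {}
    for chrom, s, e, group in targets:
        bucket = result.setdefault(group, {})
        over = [
            l for l in by_chrom.get(chrom, []) if l.start < e and l.end > s
        ]
        if not over:
            key = "no_hit"
        else:
            best: int | None = None
            for l in over:
                if focal_family is None:
                    cand = l.best_tier
                else:
                    cand = min(
                        (
                            fc.best_tier
                            for fc in l.per_family
                            if fc.family == focal_family
                        ),
                        default=None,
                    )
                if cand is not None and (best is None or cand < best):
                    best = cand
            key = f"tier_{best}" if best is not None else "other_family"
        bucket[key] = bucket.get(key, 0) + 1
    return result
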