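"""Cloud annotation: locus merging, composition, comparison, intersection."""

import numpy as np
import pytest

from ssrclouds.annotate import (
    CloudLocus,
    annotate,
    compare_to_reference,
    grouped_intersection,
    per_family_report,
)
from ssrclouds.clouds import CloudSet, CloudTier, build_cloudset, perfect_repeat_kmers
from ssrclouds.motifs import reverse_complement
from ssrclouds.perfect import scan_genome
from ssrclouds.synth import PlantSpec, make_background, make_planted_genome


def simple_cloudset(family="A", k=16, extra_tiers=()):
    """CloudSet whose tier 1 is just the perfect tandem k-mers, with
    optional extra oligo sets appended as relaxed tiers."""
    perfect = perfect_repeat_kmers(family, k)
    tiers = [CloudTier(1, 10.0, perfect)]
    acc = set(perfect)
    for i, extra in enumerate(extra_tiers, start=2):
        acc |= set(extra) | {reverse_complement(o) for o in extra}
        tiers.append(CloudTier(i, 10.0 / i, frozenset(acc)))
    return CloudSet(family=family, k=k, tiers=tiers, perfect_oligos=perfect)


NO_A = {"C": 1 / 3, "G": 1 / 3, "T": 1 / 3}  # spacers that cannot extend poly-A


class TestAnnotate:
    def test_single_planted_run(self):
        spacer1 = make_background(300, NO_A, seed=1)
        spacer2 = make_background(300, NO_A, seed=2)
        genome = {"c": spacer1 + "A" * 30 + spacer2}
        loci = annotate(genome, [simple_cloudset()], merge_dist=5)
        assert len(loci) == 1
        (l,) = loci
        assert (l.start, l.end) == (300, 330)
        assert l.best_tier == 1
        assert l.longest_perfect_stretch == 30
        assert l.per_family[0].family == "A"
        assert l.per_family[0].coverage == 1.0

    @pytest.mark.parametrize("gap,n_expected", [(6, 2), (5, 1)])
    def test_merge_distance_boundary(self, gap, n_expected):
        spacer = make_background(300, NO_A, seed=3)
        genome = {"c": spacer + "A" * 20 + "C" * gap + "A" * 20 + spacer[::-1]}
        loci = annotate(genome, [simple_cloudset()], merge_dist=5)
        assert len(loci) == n_expected

    def test_decayed_dinucleotide_recovered_at_relaxed_tier(self):
        genome, truth = make_planted_genome(
            60_000,
            [
                PlantSpec("AC", 30, copies=250,
                          decay_substitution_rate=0.0,
                          spacer_length=(120, 200)),
                PlantSpec("AC", 60, copies=80,
                          decay_substitution_rate=0.1,
                          spacer_length=(120, 200)),
            ],
            seed=11,
        )
        loci = scan_genome(genome, families={"AC"})
        cs, _ = build_cloudset(
            genome, loci, family="AC", thresholds=[40, 5, 1],
            min_training_loci=50, seed=5,
        )
        ann = annotate(genome, [cs], merge_dist=5)

        # independent oracle: sliding-window set membership + gap merging
        seq = genome["chr1"]
        oligos = cs.all_oligos
        covered = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - 16 + 1):
            if seq[i : i + 16] in oligos:
                covered[i : i + 16] = True
        idx = np.flatnonzero(covered)
        expected_intervals = []
        if idx.size:
            s = prev = int(idx[0])
            for v in idx[1:]:
                v = int(v)
                if v - prev > 5 + 1:
                    expected_intervals.append((s, prev + 1))
                    s = v
                prev = v
            expected_intervals.append((s, prev + 1))
        assert [(l.start, l.end) for l in ann] == expected_intervals

        decayed = truth[truth.n_sub > 2]
        assert len(decayed) > 20
        hit_tiers = []
        for r in decayed.itertuples():
            over = [l for l in ann if l.start < r.end and l.end > r.start]
            if over:
                hit_tiers.append(min(l.best_tier for l in over))
                fams = {
                    fc.family: fc.coverage for l in over for fc in l.per_family
                }
                assert fams.get("AC", 0) >= 0.5
        assert len(hit_tiers) / len(decayed) > 0.8
        # some decayed plants are detectable only through relaxed tiers
        assert any(t > 1 for t in hit_tiers)

    def test_no_hits_gives_empty_list(self):
        genome = {"c": "G" * 50 + "C" * 50}
        assert annotate(genome, [simple_cloudset("AT")]) == []

    def test_coverage_conservation(self):
        # total locus bp equals union bp of oligo hit windows after merging
        genome, _ = make_planted_genome(
            20_000,
            [PlantSpec("A", 25, copies=40, spacer_length=(100, 300))],
            seed=7,
        )
        cs = simple_cloudset()
        for merge_dist in (0, 5, 30):
            loci = annotate(genome, [cs], merge_dist=merge_dist)
            seq = genome["chr1"]
            covered = np.zeros(len(seq), dtype=bool)
            oligos = cs.all_oligos
            for i in range(len(seq) - 16 + 1):
                if seq[i : i + 16] in oligos:
                    covered[i : i + 16] = True
            union_bp = int(covered.sum())
            merged_bp = sum(l.length for l in loci)
            gap_bp = merged_bp - union_bp  # only merge gaps may be added
            assert gap_bp >= 0
            if merge_dist == 0:
                assert merged_bp == union_bp
            # every covered position is inside exactly one locus
            starts = [l.start for l in loci]
            assert starts == sorted(starts)
            for a, b in zip(loci, loci[1:]):
                assert a.end + merge_dist < b.start or a.chrom != b.chrom

    def test_tier_relaxation_grows_annotation(self):
        # relaxed tiers only extend loci; annotated bp is non-decreasing
        genome, _ = make_planted_genome(
            40_000,
            [PlantSpec("A", 30, copies=150,
                       decay_substitution_rate=0.15,
                       spacer_length=(120, 250))],
            seed=13,
        )
        loci = scan_genome(genome, families={"A"})
        cs, _ = build_cloudset(
            genome, loci, family="A", thresholds=[30, 6, 1],
            min_training_loci=30, seed=9,
        )
        results = {}
        for t in (1, 2, 3):
            truncated = CloudSet(
                family=cs.family, k=cs.k, tiers=cs.tiers[:t],
                perfect_oligos=cs.perfect_oligos,
            )
            results[t] = annotate(genome, [truncated], merge_dist=5)
        bps = {t: sum(l.length for l in r) for t, r in results.items()}
        assert bps[1] <= bps[2] <= bps[3]
        # each stricter-annotation locus is contained in a relaxed locus
        for t in (1, 2):
            for l in results[t]:
                assert any(
                    r.start <= l.start and l.end <= r.end
                    for r in results[t + 1]
                )

    def test_self_recovery_of_training_loci(self):
        genome, truth = make_planted_genome(
            40_000,
            [PlantSpec("A", 30, copies=100, spacer_length=(120, 300))],
            seed=21,
        )
        ann = annotate(genome, [simple_cloudset()], merge_dist=5)
        tier1 = [l for l in ann if l.best_tier == 1]
        recovered = sum(
            any(l.start <= r.start and r.end <= l.end for l in tier1)
            for r in truth.itertuples()
        )
        assert recovered / len(truth) >= 0.99

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError):
            annotate(
                {"c": "A" * 100},
                [simple_cloudset(k=16), simple_cloudset("AC", k=12)],
            )


class TestPerFamilyReport:
    def test_single_family_locus(self):
        genome = {"c": make_background(200, seed=1) + "A" * 40
                  + make_background(200, seed=2)}
        (l,) = annotate(genome, [simple_cloudset()])
        df = per_family_report(l)
        assert df.shape[0] == 1
        row = df.iloc[0]
        assert row["family"] == "A" and row["mean_tier"] == 1.0
        assert row["coverage"] == 1.0

    def test_compound_locus_lists_both_families(self):
        # AAAAAC and AAC runs side by side, as in complex genomic loci
        genome = {
            "c": make_background(200, seed=3)
            + "AAAAAC" * 6 + "AAC" * 12
            + make_background(200, seed=4)
        }
        cloudsets = [simple_cloudset("AAAAAC"), simple_cloudset("AAC")]
        loci = annotate(genome, cloudsets, merge_dist=5)
        assert len(loci) == 1
        df = per_family_report(loci[0])
        assert set(df["family"]) == {"AAAAAC", "AAC"}
        assert list(df["coverage"]) == sorted(df["coverage"], reverse=True)
        # poly-A family absent: no poly-A cloud was supplied
        assert "A" not in set(df["family"])


def _mk_locus(chrom, start, end, tier=1):
    return CloudLocus(
        chrom=chrom, start=start, end=end, best_tier=tier, per_family=[],
        longest_perfect_stretch=0, longest_tier_stretch={}, tier_covered_bp={},
    )


class TestCompareToReference:
    def test_identical_sets(self):
        loci = [_mk_locus("c", 10, 50), _mk_locus("c", 100, 130)]
        ref = [("c", 10, 50), ("c", 100, 130)]
        stats = compare_to_reference(loci, ref)
        assert stats["n_reference_recovered"] == 2
        assert stats["reference_bp_recovered"] == stats["reference_bp"] == 70
        assert stats["n_novel"] == 0
        assert stats["frac_extend_one_side"] == 0.0

    def test_strict_containment_extends_both_sides(self):
        loci = [_mk_locus("c", 5, 60), _mk_locus("c", 90, 140)]
        ref = [("c", 10, 50), ("c", 100, 130)]
        stats = compare_to_reference(loci, ref)
        assert stats["n_reference_recovered"] == 2
        assert stats["frac_extend_both_sides"] == 1.0
        assert stats["frac_extend_one_side"] == 1.0

    def test_hand_built_five_interval_example(self):
        loci = [
            _mk_locus("c", 0, 20),     # overlaps ref (10,30): extends left
            _mk_locus("c", 40, 60),    # novel
            _mk_locus("c", 95, 125),   # contains ref (100,120)
            _mk_locus("c", 200, 210),  # inside ref (190,220)
            _mk_locus("c", 300, 320),  # novel
        ]
        ref = [("c", 10, 30), ("c", 100, 120), ("c", 190, 220)]
        stats = compare_to_reference(loci, ref)
        assert stats["n_cloud_overlapping"] == 3
        assert stats["n_novel"] == 2 and stats["novel_bp"] == 40
        assert stats["bp_intersection"] == 10 + 20 + 10
        assert stats["n_reference_recovered"] == 3
        assert stats["frac_extend_both_sides"] == pytest.approx(1 / 3)
        assert stats["frac_extend_one_side"] == pytest.approx(2 / 3)

    def test_mismatched_chrom_warns(self):
        with pytest.warns(UserWarning):
            stats = compare_to_reference(
                [_mk_locus("c1", 0, 10)], [("c2", 0, 10)]
            )
        assert stats["n_reference_recovered"] == 0


class TestGroupedIntersection:
    def _locus_with_family(self, chrom, start, end, family, tier):
        from ssrclouds.annotate import FamilyComposition

        l = _mk_locus(chrom, start, end, tier)
        l.per_family = [
            FamilyComposition(family=family, mean_tier=tier,
                              best_tier=tier, coverage=1.0)
        ]
        return l

    def test_all_windows_hit_best_tier(self):
        loci = [self._locus_with_family("c", i * 100, i * 100 + 30, "A", 1)
                for i in range(5)]
        targets = [("c", i * 100 + 10, i * 100 + 20, "young") for i in range(5)]
        res = grouped_intersection(targets, loci, focal_family="A")
        assert res == {"young": {"tier_1": 5}}

    def test_no_hits(self):
        res = grouped_intersection(
            [("c", 0, 10, "old")], [], focal_family="A"
        )
        assert res == {"old": {"no_hit": 1}}

    def test_mixed_manual_tally(self):
        loci = [
            self._locus_with_family("c", 100, 130, "A", 1),
            self._locus_with_family("c", 300, 330, "A", 3),
            self._locus_with_family("c", 500, 530, "AC", 2),
        ]
        targets = [
            ("c", 110, 120, "g1"),   # tier 1 poly-A
            ("c", 310, 320, "g1"),   # tier 3 poly-A
            ("c", 510, 520, "g2"),   # other family
            ("c", 700, 710, "g2"),   # nothing
        ]
        res = grouped_intersection(targets, loci, focal_family="A")
        assert res == {
            "g1": {"tier_1": 1, "tier_3": 1},
            "g2": {"other_family": 1, "no_hit": 1},
        }
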