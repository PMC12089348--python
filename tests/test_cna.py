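"""Copy-number analytics: altered fraction, arm events, chromothripsis
scoring, focal filters, two-hit calling."""

import numpy as np
import pandas as pd
import pytest

from sgcohort import cna
from sgcohort.io import CNSegmentProfile, VariantCall


def profile(segments, sample="S1", **kw):
    return CNSegmentProfile(sample_id=sample, segments=segments, **kw)


def random_profile(rng, n_chroms=2, max_segments=30, chrom_len=60_000_000):
    segments = []
    for ci in range(n_chroms):
        n_seg = int(rng.integers(1, max_segments))
        cuts = np.unique(rng.integers(1, chrom_len, size=n_seg - 1)).tolist()
        bounds = [0] + cuts + [chrom_len]
        for s, e in zip(bounds, bounds[1:]):
            cn = int(rng.integers(0, 5))
            segments.append((f"chr{ci + 1}", s, e, cn, min(cn, 1)))
    return profile(segments)


def brute_force_max_switches(segments, window_bp):
    """Independent oracle: scan windows anchored at every breakpoint."""
    points = [
        left[2] for left, right in zip(segments, segments[1:]) if left[3] != right[3]
    ]
    anchors = sorted({s[1] for s in segments} | {s[2] for s in segments})
    best = 0
    for a in anchors:
        best = max(best, sum(1 for p in points if a <= p <= a + window_bp))
    return best


class TestAlteredFraction:
    def test_all_diploid_is_zero(self):
        p = profile([("chr1", 0, 10_000_000, 2, 1)])
        assert cna.altered_genome_fraction(p) == 0.0

    def test_single_loss_fraction(self):
        p = profile([("chr1", 0, 90_000_000, 2, 1), ("chr1", 90_000_000, 100_000_000, 1, 0)])
        assert cna.altered_genome_fraction(p) == pytest.approx(0.10)

    def test_matches_summation_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = random_profile(rng)
            expected_alt = sum(
                e - s for _, s, e, cn, _m in p.segments if cn != 2
            )
            expected_tot = sum(e - s for _, s, e, _cn, _m in p.segments)
            assert cna.altered_genome_fraction(p) == pytest.approx(
                expected_alt / expected_tot
            )

    def test_sex_chromosomes_excluded(self):
        p = profile([("chr1", 0, 10_000_000, 2, 1), ("chrX", 0, 10_000_000, 1, 0)])
        assert cna.altered_genome_fraction(p) == 0.0

    def test_low_fit_profile_rejected(self):
        p = profile([("chr1", 0, 1_000_000, 2, 1)], goodness_of_fit=0.8)
        with pytest.raises(ValueError, match="low_fit"):
            cna.altered_genome_fraction(p)


class TestBroadEvents:
    arm_table = pd.DataFrame(
        [{"chrom": "chr1", "arm": "p", "start": 0, "end": 100_000_000}]
    )

    @pytest.mark.parametrize(
        "loss_end,expected",
        [(60_000_000, "loss"), (50_000_000, "loss"), (49_000_000, "neutral")],
    )
    def test_loss_requires_half_the_arm(self, loss_end, expected):
        p = profile(
            [("chr1", 0, loss_end, 1, 0), ("chr1", loss_end, 100_000_000, 2, 1)]
        )
        assert cna.call_broad_events(p, self.arm_table)["chr1p"] == expected

    def test_whole_arm_gain(self):
        p = profile([("chr1", 0, 100_000_000, 3, 1)])
        assert cna.call_broad_events(p, self.arm_table)["chr1p"] == "gain"

    def test_missing_arm_rejected(self):
        p = profile([("chr1", 0, 100_000_000, 2, 1)])
        with pytest.raises(ValueError, match="absent"):
            cna.arm_call(p, self.arm_table, "chr5q")


class TestSwitchCounting:
    def test_alternating_segments(self):
        segs = [
            ("chr1", i * 4_000_000, (i + 1) * 4_000_000, 1 + i % 2, 1) for i in range(11)
        ]
        count, window = cna.count_cn_switches(profile(segs), "chr1")
        assert count == 10

    def test_uniform_profile_has_no_switches(self):
        p = profile([("chr1", 0, 10_000_000, 2, 1), ("chr1", 10_000_000, 30_000_000, 2, 1)])
        assert cna.count_cn_switches(p, "chr1")[0] == 0

    def test_window_limits_the_count(self):
        # 11 alternating 10 Mb segments: only 5 breakpoints fit in 50 Mb
        segs = [
            ("chr1", i * 10_000_000, (i + 1) * 10_000_000, 1 + i % 2, 1)
            for i in range(11)
        ]
        count, _ = cna.count_cn_switches(profile(segs), "chr1")
        assert count == 6  # breakpoints at 10..60 Mb from anchor 10 Mb inclusive

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_profile(rng, n_chroms=1)
            segs = p.chrom_segments("chr1")
            ours, _ = cna.count_cn_switches(p, "chr1")
            assert ours == brute_force_max_switches(segs, 50_000_000)

    def test_absent_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            cna.count_cn_switches(profile([("chr1", 0, 1000, 2, 1)]), "chr9")


class TestClassification:
    def test_chr21_style_scaling(self):
        assert cna.scaling_factor(46.709) == pytest.approx(0.934, abs=5e-4)
        assert cna.scaled_thresholds(46.709) == {"high": 9, "intermediate": 7, "low": 6}

    def test_full_length_thresholds(self):
        assert cna.scaled_thresholds(50.0) == {"high": 10, "intermediate": 8, "low": 6}
        assert cna.scaled_thresholds(250.0) == {"high": 10, "intermediate": 8, "low": 6}

    @pytest.mark.parametrize(
        "switches,n_states,length,tier,canon",
        [
            (10, 3, 60.0, "high", "canonical"),
            (10, 2, 50.0, "high", "canonical"),
            (9, 2, 46.709, "high", "canonical"),
            (8, 2, 46.709, "intermediate", "canonical"),
            (8, 4, 60.0, "intermediate", "non_canonical"),
            (6, 4, 60.0, "low", "non_canonical"),
            (5, 2, 60.0, "none", "not_applicable"),
            (0, 1, 60.0, "none", "not_applicable"),
        ],
    )
    def test_tier_and_canonicity(self, switches, n_states, length, tier, canon):
        assert cna.classify_chromothripsis(switches, n_states, length) == (tier, canon)

    def test_tier_monotone_in_switch_count(self):
        order = cna.TIER_ORDER
        for length in (20.0, 46.709, 50.0, 80.0):
            prev = -1
            for k in range(0, 15):
                tier, _ = cna.classify_chromothripsis(k, 2, length)
                assert order[tier] >= prev
                prev = order[tier]


class TestFocalFilters:
    mask = [("chr1", 0, 410_000)]

    def make_events(self):
        return [
            cna.FocalEvent("chr1", 0, 100_000, "loss"),             # boundary: small
            cna.FocalEvent("chr1", 0, 1_000_000, "loss"),           # 41% difficult overlap
            cna.FocalEvent("chr1", 2_000_000, 3_000_000, "loss",
                           concordant_fraction=0.74),
            cna.FocalEvent("chr1", 2_000_000, 3_000_000, "loss",
                           concordant_fraction=0.75),               # boundary: kept
        ]

    def test_status_cascade_and_boundaries(self):
        out = cna.filter_focal_events(self.make_events(), self.mask)
        assert [e.status for e in out] == [
            "removed_small", "removed_difficult", "removed_discordant", "kept"
        ]
        assert out[1].difficult_overlap_fraction == pytest.approx(0.41)

    def test_statuses_partition_and_refilter_is_stable(self):
        out = cna.filter_focal_events(self.make_events(), self.mask)
        assert all(e.status is not None for e in out)
        kept = [e for e in out if e.status == "kept"]
        again = cna.filter_focal_events(kept, self.mask)
        assert [e.status for e in again] == ["kept"] * len(kept)

    def test_concordance_from_profiles(self):
        ev = cna.FocalEvent("chr1", 0, 1_000_000, "loss",
                            supporting_samples=["A", "B", "C", "D"])
        concordant = profile([("chr1", 0, 2_000_000, 1, 0)], sample="x")
        discordant = profile([("chr1", 0, 2_000_000, 2, 1)], sample="x")
        profiles = {"A": concordant, "B": concordant, "C": concordant, "D": discordant}
        (out,) = cna.filter_focal_events([ev], [], profiles)
        assert out.concordant_fraction == pytest.approx(0.75)
        assert out.status == "kept"


class TestTwoHit:
    gene_models = {"G": ("chr1", 1_000_000, 1_050_000)}

    def call(self, consequence, pos=1_000_500, sample="S1"):
        return VariantCall(sample_id=sample, chrom="chr1", pos=pos, ref="A", alt="G",
                           t_depth=50, t_alt=25, n_depth=50, n_alt=0,
                           gene="G", consequence=consequence)

    def test_variant_plus_loh(self):
        p = profile([("chr1", 0, 60_000_000, 1, 0)])
        out = cna.call_two_hit([self.call("splice_acceptor")], p, self.gene_models)
        assert [(c.gene, c.evidence) for c in out] == [("G", "variant_plus_loh")]

    def test_two_truncating_variants_diploid(self):
        p = profile([("chr1", 0, 60_000_000, 2, 1)])
        calls = [self.call("frameshift", pos=1_000_500),
                 self.call("frameshift", pos=1_001_500)]
        out = cna.call_two_hit(calls, p, self.gene_models)
        assert [(c.gene, c.evidence) for c in out] == [("G", "two_variants")]

    def test_single_missense_diploid_no_call(self):
        p = profile([("chr1", 0, 60_000_000, 2, 1)])
        assert cna.call_two_hit([self.call("missense")], p, self.gene_models) == []

    def test_loh_must_cover_half_the_gene(self):
        # minor CN 0 over only 40% of the gene body
        p = profile([
            ("chr1", 0, 1_020_000, 1, 0),
            ("chr1", 1_020_000, 60_000_000, 2, 1),
        ])
        out = cna.call_two_hit([self.call("frameshift")], p, self.gene_models)
        assert out == []

    def test_planted_two_hits_recovered(self, bundle, results):
        found = {(t.sample_id, t.gene, t.evidence) for t in results.two_hits}
        for planted in bundle.truth.planted_two_hits:
            assert tuple(planted) in found


class TestPlantedChromothripsisAndArms:
    def test_planted_event_detected_at_tier(self, bundle, results):
        sample, chrom, n_switches, n_states = bundle.truth.chromothripsis_plant
        match = [
            c for c in results.chromothripsis
            if c.sample_id == sample and c.chrom == chrom
        ]
        assert len(match) == 1
        assert match[0].tier == "high"
        assert match[0].canonicity == "canonical"

    def test_no_high_tier_on_sparse_null_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_profile(rng, n_chroms=1, max_segments=4)
            count, _ = cna.count_cn_switches(p, "chr1")
            tier, _ = cna.classify_chromothripsis(count, 2, 60.0)
            assert tier != "high"

    def test_planted_arm_losses_called(self, bundle):
        arm_table = bundle.genome.arm_table()
        by_sample = {p.sample_id: p for p in bundle.profiles}
        for sample, arm in bundle.truth.planted_arm_losses:
            assert cna.call_broad_events(by_sample[sample], arm_table)[arm] == "loss"
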