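"""Refinement cascade: rules, boundaries, contracts."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgcohort import refinery
from sgcohort.io import TargetSpace
from sgcohort.refinery import RefinementConfig


@pytest.fixture
def cfg():
    return RefinementConfig()


@pytest.fixture
def targets():
    return TargetSpace.from_intervals([("chr1", 1000, 2000)], flank_bp=2)


class TestCommonSnps:
    @pytest.mark.parametrize(
        "pop_af,kept",
        [(0.02, False), (0.01, False), (0.0099, True), (None, True), (0.0, True)],
    )
    def test_threshold_boundary(self, make_call, cfg, pop_af, kept):
        calls = refinery.exclude_common_snps([make_call(pop_af=pop_af)], cfg)
        assert bool(calls) is kept


class TestMnvMerging:
    def test_adjacent_pair_merges(self, make_call, cfg):
        pair = [
            make_call(pos=100, ref="A", alt="G", t_depth=40, t_alt=18, phase_set="ps"),
            make_call(pos=101, ref="C", alt="T", t_depth=36, t_alt=15, phase_set="ps"),
        ]
        out = refinery.merge_adjacent_snvs(pair, cfg)
        assert len(out) == 1
        mnv = out[0]
        assert (mnv.vclass, mnv.ref, mnv.alt) == ("MNV", "AC", "GT")
        # merged support is the minimum over constituents
        assert (mnv.t_depth, mnv.t_alt) == (36, 15)

    def test_run_longer_than_max_left_unmerged(self, make_call, cfg):
        run = [
            make_call(pos=100 + i, ref="A", alt="G", phase_set="ps") for i in range(4)
        ]
        out = refinery.merge_adjacent_snvs(run, cfg)
        assert sorted(c.pos for c in out) == [100, 101, 102, 103]
        assert all(c.vclass == "SNV" for c in out)

    def test_different_phase_sets_not_merged(self, make_call, cfg):
        calls = [
            make_call(pos=100, phase_set="a"),
            make_call(pos=101, ref="C", alt="T", phase_set="b"),
        ]
        assert len(refinery.merge_adjacent_snvs(calls, cfg)) == 2

    def test_phase_set_spanning_chromosomes_rejected(self, make_call, cfg):
        calls = [
            make_call(pos=100, chrom="chr1", phase_set="ps"),
            make_call(pos=101, chrom="chr2", ref="C", alt="T", phase_set="ps"),
        ]
        with pytest.raises(ValueError, match="chromosome"):
            refinery.merge_adjacent_snvs(calls, cfg)


class TestCascade:
    @pytest.mark.parametrize(
        "ref_len,alt_len,vaf,t_depth,n_depth,expected_rule",
        [
            (2, 1, 0.05, 60, 60, "low_vaf"),        # indel below the VAF floor
            (12, 11, 0.15, 30, 25, "complex_low_support"),  # both alleles > 10 bp
            (12, 11, 0.30, 30, 25, None),            # complex but well supported
            (12, 11, 0.30, 30, 15, "complex_low_support"),  # normal too shallow
            (26, 1, 0.30, 30, 25, None),             # > 25 bp one-sided: complex, rescued
            (26, 1, 0.15, 30, 25, "complex_low_support"),
            (25, 1, 0.15, 30, 25, None),             # simple: within 25 bp, not both long
            (1, 1, 0.10, 30, 30, None),              # VAF exactly at floor retained
        ],
    )
    def test_rule_table(self, make_call, cfg, ref_len, alt_len, vaf, t_depth, n_depth,
                        expected_rule):
        call = make_call(
            ref="A" * ref_len, alt="G" * alt_len,
            t_depth=t_depth, t_alt=round(vaf * t_depth), n_depth=n_depth,
        )
        assert refinery.cascade_rule(call, cfg) == expected_rule

    def test_rule_table_matches_enumeration_oracle(self, make_call, cfg):
        # independent restatement of the cascade over a grid of cases
        for ref_len in (1, 5, 11, 25, 26):
            for alt_len in (1, 11, 26):
                if ref_len == alt_len == 1:
                    continue
                for vaf in (0.05, 0.15, 0.3):
                    for depth in (15, 30):
                        call = make_call(
                            ref="A" * ref_len, alt="G" * alt_len,
                            t_depth=depth, t_alt=round(vaf * depth),
                            n_depth=depth,
                        )
                        vaf_obs = call.t_alt / call.t_depth
                        simple = max(ref_len, alt_len) <= 25 and not (
                            ref_len > 10 and alt_len > 10
                        )
                        if ref_len == alt_len and ref_len > 3:
                            want = "long_mnv"  # over-long MNVs always removed
                        elif vaf_obs < 0.1:
                            want = "low_vaf"
                        elif simple:
                            want = None
                        elif vaf_obs > 0.25 and depth >= 20:
                            want = None
                        else:
                            want = "complex_low_support"
                        assert refinery.cascade_rule(call, cfg) == want

    def test_zero_depth_is_malformed(self, make_call, cfg):
        call = make_call(t_depth=0, t_alt=0)
        assert refinery.cascade_rule(call, cfg) == "malformed"

    def test_long_mnv_always_removed(self, make_call, cfg):
        call = make_call(ref="ACGT", alt="TGCA", t_alt=25)
        assert call.vclass == "MNV"
        assert refinery.cascade_rule(call, cfg) == "long_mnv"


class TestTargetProximity:
    @pytest.mark.parametrize(
        "pos,kept",
        [
            (1500, True),   # inside an interval
            (898, True),    # exactly 100 bp from the flanked edge (998)
            (897, False),   # 101 bp away
            (2103, True),   # 100 bp right of flanked end (2002)
            (2104, False),
        ],
    )
    def test_proximity_boundary(self, make_call, cfg, targets, pos, kept):
        out = refinery.restrict_to_target_space([make_call(pos=pos)], targets, cfg)
        assert bool(out) is kept


class TestHotspotRescue:
    def hotspot_call(self, make_call, cfg, **kw):
        chrom, pos, ref, alt = cfg.hotspot_sites[0]
        return make_call(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)

    def test_low_vaf_hotspot_reinstated(self, make_call, cfg):
        raw = [self.hotspot_call(make_call, cfg, t_depth=70, t_alt=4, n_alt=0)]
        audit = [refinery.AuditEntry(raw[0].key, "low_vaf", "removed")]
        out = refinery.rescue_hotspots(raw, [], cfg, audit)
        assert len(out) == 1
        assert "rescued:low_vaf" in out[0].filters

    def test_insufficient_alt_reads_stay_removed(self, make_call, cfg):
        raw = [self.hotspot_call(make_call, cfg, t_depth=70, t_alt=1)]
        assert refinery.rescue_hotspots(raw, [], cfg) == []

    def test_contaminated_normal_stays_removed(self, make_call, cfg):
        raw = [self.hotspot_call(make_call, cfg, t_depth=70, t_alt=5, n_alt=5)]
        assert refinery.rescue_hotspots(raw, [], cfg) == []

    def test_non_hotspot_never_rescued(self, make_call, cfg):
        raw = [make_call(pos=999_999, t_depth=70, t_alt=5)]
        assert refinery.rescue_hotspots(raw, [], cfg) == []


class TestPipelineContracts:
    def test_idempotence_on_synthetic_cohort(self, bundle):
        cfg = RefinementConfig()
        once, _ = refinery.refine(bundle.calls, bundle.targets, cfg)
        twice, _ = refinery.refine(once, bundle.targets, cfg)
        assert twice == once

    def test_order_invariance(self, bundle):
        cfg = RefinementConfig()
        ordered, _ = refinery.refine(bundle.calls, bundle.targets, cfg)
        shuffled = list(bundle.calls)
        random.Random(7).shuffle(shuffled)
        reshuffled, _ = refinery.refine(shuffled, bundle.targets, cfg)
        assert reshuffled == ordered

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30), st.data())
    def test_monotone_in_min_vaf(self, vafs, data):
        targets = TargetSpace.from_intervals([("chr1", 0, 10_000)], flank_bp=2)
        from sgcohort.io import VariantCall

        calls = [
            VariantCall(
                sample_id="S", chrom="chr1", pos=100 + 3 * i, ref="A", alt="G",
                t_depth=100, t_alt=int(round(v * 100)), n_depth=50, n_alt=0,
            )
            for i, v in enumerate(vafs)
        ]
        lo = data.draw(st.floats(0.0, 0.5))
        hi = data.draw(st.floats(lo, 0.5))
        keep = lambda thr: {
            c.key
            for c in refinery.refine(
                calls, targets,
                RefinementConfig(min_vaf=thr, rescue_vaf_floor=max(thr, 0.25),
                                 hotspot_sites=[]),
            )[0]
        }
        assert keep(hi) <= keep(lo)

    def test_audit_partitions_removals(self, bundle):
        cfg = RefinementConfig()
        retained, audit = refinery.refine(bundle.calls, bundle.targets, cfg)
        removed = [e for e in audit if e.action == "removed"]
        removed_keys = [e.key for e in removed]
        # each removed record is logged exactly once, with one rule
        assert len(removed_keys) == len(set(removed_keys))
        retained_keys = {c.key for c in retained}
        rescued_keys = {e.key for e in audit if e.action == "rescued"}
        raw_keys = {c.key for c in bundle.calls}
        # every raw call is retained, merged into an MNV, or audited as removed
        merged_constituents = {
            k for k in raw_keys
            if k not in retained_keys and k not in set(removed_keys)
        }
        for k in merged_constituents:
            call = next(c for c in bundle.calls if c.key == k)
            assert call.phase_set is not None
        assert rescued_keys <= set(removed_keys)
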