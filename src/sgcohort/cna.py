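"""Copy-number analytics.

Covers the altered-genome fraction, broad (arm-level) event calling,
chromothripsis-like scoring by copy-number state switches in a 50 Mb
window with chromosome-length scaling, post-filters for focal candidate
events, and two-hit (biallelic inactivation) calling from damaging
variants plus loss of heterozygosity.

Chromothripsis scoring follows the tiered state-switch definition:
high confidence at 10 or more switches within 50 Mb, intermediate at
8-9, low at 6-7; events oscillating among 2-3 distinct total copy
number states are canonical, more than 3 states non-canonical.  For
chromosomes shorter than the window the thresholds are scaled by
length/50 Mb and rounded to the nearest whole number (halves away from
zero), e.g. a 46.709 Mb chromosome scales the high-confidence
threshold to 9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CNSegmentProfile, VariantCall, merge_intervals

TIER_ORDER = {"none": 0, "low": 1, "intermediate": 2, "high": 3}

#: Base switch-count thresholds for a full 50 Mb window.
BASE_THRESHOLDS = {"high": 10, "intermediate": 8, "low": 6}
BASE_WINDOW_MB = 50.0

#: Variant consequences treated as gene-damaging for two-hit calling.
DAMAGING_CLASSES = frozenset(
    {"stop_gained", "frameshift", "splice_acceptor", "splice_donor", "start_lost"}
)

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


# ---------------------------------------------------------------------------
# altered genome fraction


def altered_genome_fraction(profile: CNSegmentProfile, baseline: str = "diploid") -> float:
    """Fraction of the segmented autosomal genome off-baseline.

    ``baseline`` is ``"diploid"`` (total CN != 2 counts as altered) or
    ``"ploidy"`` (total CN != round(ploidy)).
    """
    if "low_fit" in profile.flags:
        raise ValueError(f"{profile.sample_id}: profile flagged low_fit")
    if baseline == "diploid":
        neutral = 2
    elif baseline == "ploidy":
        neutral = int(round(profile.ploidy))
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    total = 0
    altered = 0
    for chrom, start, end, total_cn, _minor in profile.segments:
        if chrom in SEX_CHROMS:
            continue
        length = end - start
        total += length
        if total_cn != neutral:
            altered += length
    if total == 0:
        raise ValueError(f"{profile.sample_id}: empty profile")
    return altered / total


# ---------------------------------------------------------------------------
# broad events


def call_broad_events(
    profile: CNSegmentProfile, arm_table: pd.DataFrame
) -> dict[str, str]:
    """Per-arm {loss, gain, neutral} calls.

    An arm is lost (gained) when at least half its length is at total
    CN below (above) 2.  If the lost and gained lengths tie at exactly
    half an arm each, loss takes precedence.
    """
    required = {"chrom", "arm", "start", "end"}
    if not required <= set(arm_table.columns):
        raise ValueError(f"arm table needs columns {sorted(required)}")
    calls: dict[str, str] = {}
    for row in arm_table.itertuples():
        arm_len = row.end - row.start
        lost = gained = 0
        for chrom, start, end, total_cn, _minor in profile.chrom_segments(row.chrom):
            ov = min(end, row.end) - max(start, row.start)
            if ov <= 0:
                continue
            if total_cn < 2:
                lost += ov
            elif total_cn > 2:
                gained += ov
        name = f"{row.chrom}{row.arm}"
        if lost * 2 >= arm_len and lost >= gained:
            calls[name] = "loss"
        elif gained * 2 >= arm_len:
            calls[name] = "gain"
        else:
            calls[name] = "neutral"
    return calls


def arm_call(profile: CNSegmentProfile, arm_table: pd.DataFrame, arm: str) -> str:
    calls = call_broad_events(profile, arm_table)
    if arm not in calls:
        raise ValueError(f"arm {arm!r} absent from arm table")
    return calls[arm]


# ---------------------------------------------------------------------------
# chromothripsis


def _switch_breakpoints(segments: Sequence[tuple]) -> list[int]:
    """Positions of adjacent-segment total-CN changes (the left segment's
    end coordinate marks the breakpoint)."""
    points = []
    for left, right in zip(segments, segments[1:]):
        if left[3] != right[3]:
            points.append(left[2])
    return points


def count_cn_switches(
    profile: CNSegmentProfile, chrom: str, window_mb: float = BASE_WINDOW_MB
) -> tuple[int, tuple[int, int]]:
    """Maximum number of CN state switches within any ``window_mb`` window.

    Candidate windows are anchored at every switch breakpoint; any
    window's switch count is achieved by some breakpoint-anchored
    window, so the maximum is exact.  Returns the count and the
    achieving window (0-based coordinates).
    """
    segments = profile.chrom_segments(chrom)
    if not segments:
        raise ValueError(f"{profile.sample_id}: chromosome {chrom!r} absent from profile")
    window_bp = int(round(window_mb * 1e6))
    points = _switch_breakpoints(segments)
    if not points:
        return 0, (segments[0][1], segments[0][1] + window_bp)
    best_count, best_window = 0, (points[0], points[0] + window_bp)
    pts = np.asarray(points)
    for anchor in points:
        inside = int(((pts >= anchor) & (pts <= anchor + window_bp)).sum())
        if inside > best_count:
            best_count, best_window = inside, (anchor, anchor + window_bp)
    return best_count, best_window


def scaled_thresholds(chrom_length_mb: float, window_mb: float = BASE_WINDOW_MB) -> dict[str, int]:
    """Tier thresholds scaled to a chromosome shorter than the window.

    The scaling factor is min(1, length/window); scaled thresholds are
    rounded to the nearest whole number, halves away from zero.
    """
    if chrom_length_mb <= 0:
        raise ValueError("chromosome length must be positive")
    factor = scaling_factor(chrom_length_mb, window_mb)
    return {tier: int(math.floor(base * factor + 0.5)) for tier, base in BASE_THRESHOLDS.items()}


def scaling_factor(chrom_length_mb: float, window_mb: float = BASE_WINDOW_MB) -> float:
    return min(1.0, chrom_length_mb / window_mb)


@dataclass
class ChromothripsisCall:
    sample_id: str
    chrom: str
    window: tuple[int, int]
    switch_count: int
    tier: str
    canonicity: str
    n_states: int


def classify_chromothripsis(
    switch_count: int, n_states: int, chrom_length_mb: float,
    window_mb: float = BASE_WINDOW_MB,
) -> tuple[str, str]:
    """Tier and canonicity from a switch count and state count."""
    if switch_count < 0:
        raise ValueError("switch_count must be non-negative")
    th = scaled_thresholds(chrom_length_mb, window_mb)
    if switch_count >= th["high"]:
        tier = "high"
    elif switch_count >= th["intermediate"]:
        tier = "intermediate"
    elif switch_count >= th["low"]:
        tier = "low"
    else:
        tier = "none"
    if tier == "none":
        canonicity = "not_applicable"
    else:
        canonicity = "canonical" if 2 <= n_states <= 3 else "non_canonical"
    return tier, canonicity


def detect_chromothripsis(
    profile: CNSegmentProfile,
    chrom_lengths_mb: Mapping[str, float],
    window_mb: float = BASE_WINDOW_MB,
) -> list[ChromothripsisCall]:
    """Score every chromosome of a profile for chromothripsis-like CN
    oscillation; chromosomes without any tier are reported as 'none'."""
    calls = []
    for chrom in profile.chromosomes:
        if chrom not in chrom_lengths_mb:
            raise ValueError(f"no length for chromosome {chrom!r}")
        count, window = count_cn_switches(profile, chrom, window_mb)
        states = {
            seg[3]
            for seg in profile.chrom_segments(chrom)
            if seg[1] < window[1] and seg[2] > window[0]
        }
        tier, canonicity = classify_chromothripsis(
            count, len(states), chrom_lengths_mb[chrom], window_mb
        )
        calls.append(
            ChromothripsisCall(
                sample_id=profile.sample_id, chrom=chrom, window=window,
                switch_count=count, tier=tier, canonicity=canonicity,
                n_states=len(states),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# focal event post-filters


@dataclass
class FocalEvent:
    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    supporting_samples: list[str] = field(default_factory=list)
    difficult_overlap_fraction: float | None = None
    concordant_fraction: float | None = None
    status: str | None = None

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def _overlap_fraction(event: FocalEvent, mask: dict[str, np.ndarray]) -> float:
    ivs = mask.get(event.chrom)
    if ivs is None or len(ivs) == 0:
        return 0.0
    ov = np.minimum(ivs[:, 1], event.end) - np.maximum(ivs[:, 0], event.start)
    return float(np.clip(ov, 0, None).sum() / event.size_bp)


def _sample_concurs(
    profile: CNSegmentProfile, event: FocalEvent
) -> bool:
    """A sample concurs when at least half the event length in its own
    profile is at CN consistent with the event direction."""
    consistent = 0
    for chrom, start, end, total_cn, _minor in profile.chrom_segments(event.chrom):
        ov = min(end, event.end) - max(start, event.start)
        if ov <= 0:
            continue
        if (event.direction == "loss" and total_cn < 2) or (
            event.direction == "gain" and total_cn > 2
        ):
            consistent += ov
    return consistent * 2 >= event.size_bp


def filter_focal_events(
    events: Iterable[FocalEvent],
    difficult_mask: Iterable[tuple[str, int, int]],
    profiles: Mapping[str, CNSegmentProfile] | None = None,
    max_small_bp: int = 100_000,
    max_difficult_fraction: float = 0.40,
    min_concordance: float = 0.75,
) -> list[FocalEvent]:
    """Assign each focal candidate one status.

    Cascade: events of at most ``max_small_bp`` are removed as small;
    then events overlapping the difficult-region mask by more than
    ``max_difficult_fraction`` are removed; then events where fewer
    than ``min_concordance`` of the supporting samples' own profiles
    concur with the event are removed; the rest are kept.
    """
    mask = merge_intervals(difficult_mask) if difficult_mask else {}
    out = []
    for ev in events:
        ev.difficult_overlap_fraction = _overlap_fraction(ev, mask)
        if ev.concordant_fraction is None and profiles is not None and ev.supporting_samples:
            concur = sum(
                _sample_concurs(profiles[s], ev) for s in ev.supporting_samples
            )
            ev.concordant_fraction = concur / len(ev.supporting_samples)
        if ev.size_bp <= max_small_bp:
            ev.status = "removed_small"
        elif ev.difficult_overlap_fraction > max_difficult_fraction:
            ev.status = "removed_difficult"
        elif ev.concordant_fraction is not None and ev.concordant_fraction < min_concordance:
            ev.status = "removed_discordant"
        else:
            ev.status = "kept"
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# two-hit calling


@dataclass
class TwoHitCall:
    sample_id: str
    gene: str
    evidence: str  # "two_variants" | "variant_plus_loh"
    details: dict


def loh_fraction(profile: CNSegmentProfile, chrom: str, start: int, end: int) -> float:
    """Fraction of the interval covered by segments with minor CN 0."""
    length = end - start
    covered = 0
    for c, s, e, _total, minor in profile.chrom_segments(chrom):
        if minor != 0:
            continue
        ov = min(e, end) - max(s, start)
        if ov > 0:
            covered += ov
    return covered / length


def call_two_hit(
    calls: Iterable[VariantCall],
    profile: CNSegmentProfile,
    gene_models: Mapping[str, tuple[str, int, int]],
    damaging_classes: frozenset[str] = DAMAGING_CLASSES,
    min_loh_fraction: float = 0.5,
) -> list[TwoHitCall]:
    """Biallelic inactivation calls for one sample.

    A gene is called with ``two_variants`` evidence when it carries at
    least two distinct damaging variants, else with ``variant_plus_loh``
    when it carries at least one damaging variant and minor CN 0 over at
    least half the gene interval.
    """
    calls = [c for c in calls if c.sample_id == profile.sample_id]
    out = []
    for gene, (chrom, start, end) in gene_models.items():
        damaging = [
            c
            for c in calls
            if c.consequence in damaging_classes
            and c.chrom == chrom
            and c.span[1] > start
            and c.span[0] < end
        ]
        damaging = list({c.key: c for c in damaging}.values())
        if len(damaging) >= 2:
            out.append(
                TwoHitCall(
                    sample_id=profile.sample_id, gene=gene, evidence="two_variants",
                    details={"variants": [c.key for c in damaging]},
                )
            )
        elif len(damaging) == 1:
            frac = loh_fraction(profile, chrom, start, end)
            if frac >= min_loh_fraction:
                out.append(
                    TwoHitCall(
                        sample_id=profile.sample_id, gene=gene, evidence="variant_plus_loh",
                        details={"variants": [damaging[0].key], "loh_fraction": frac},
                    )
                )
    return out
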