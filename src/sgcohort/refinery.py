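"""Post-calling somatic variant refinement.

The cascade mirrors standard FFPE-exome practice: common germline
polymorphisms are excluded on population allele frequency, adjacent
in-cis SNVs are merged into multinucleotide variants, indels and other
long alleles pass an allele-length/VAF/depth retention cascade, calls
are restricted to the proximity of the exome target space, and calls at
recurrent hotspot sites removed by any filter can be rescued when they
retain adequate tumour read support and a clean matched normal (the
automated analogue of manual alignment inspection at hotspots, which
guards against false negatives from low tumour purity or contaminating
tumour cells in the normal).

The allele-length retention rule is deliberately isolated in
:func:`_is_simple_allele` so an alternative reading is a one-line
change: an allele pair is *simple* when both alleles are <= 25 bp and
not both are > 10 bp; anything else is *complex* and is retained only
with VAF > 0.25 and >= 20x coverage in both tumour and normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import TargetSpace, VariantCall, sort_calls

#: Default hotspot sites (chrom, pos, ref, alt) — the beta-catenin and
#: FBXW11 hotspot coordinates used by the synthetic cohort generator.
DEFAULT_HOTSPOTS = [
    ("chr1", 10_000_101, "T", "C"),   # CTNNB1 p.I35T analogue
    ("chr2", 30_000_101, "A", "G"),   # FBXW11 p.F517S analogue
]


@dataclass
class RefinementConfig:
    """Thresholds for the refinement cascade.

    Defaults follow the cascade applied to the salivary-gland cohort:
    VAF >= 0.1, MNVs of <= 3 bp, alleles <= 25 bp (not both > 10 bp),
    complex alleles rescued at VAF > 0.25 with >= 20x in both samples,
    common SNPs at population AF >= 0.01 excluded, and calls within
    100 bp of the targeted regions retained.  Hotspot rescue is
    automated with explicit evidence thresholds (>= 3 tumour alt reads,
    normal VAF <= 0.01).
    """

    common_af_threshold: float = 0.01
    min_vaf: float = 0.1
    rescue_vaf_floor: float = 0.25
    min_depth: int = 20
    max_allele_len: int = 25
    both_long_len: int = 10
    max_mnv_len: int = 3
    target_proximity_bp: int = 100
    hotspot_sites: list[tuple[str, int, str, str]] = field(
        default_factory=lambda: list(DEFAULT_HOTSPOTS)
    )
    rescue_min_t_alt: int = 3
    rescue_max_n_vaf: float = 0.01

    def __post_init__(self) -> None:
        if self.min_vaf > self.rescue_vaf_floor:
            raise ValueError("min_vaf must not exceed rescue_vaf_floor")
        for name in ("common_af_threshold", "min_vaf", "rescue_vaf_floor",
                     "min_depth", "max_allele_len", "both_long_len",
                     "max_mnv_len", "target_proximity_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AuditEntry:
    key: tuple
    rule: str
    action: str  # "removed" | "rescued"


# ---------------------------------------------------------------------------
# individual rules


def exclude_common_snps(
    calls: Iterable[VariantCall], cfg: RefinementConfig, audit: list[AuditEntry] | None = None
) -> list[VariantCall]:
    """Drop calls whose population allele frequency is at least the
    common-SNP threshold; absent pop_af never removes a call."""
    kept = []
    for c in calls:
        if c.pop_af is not None and c.pop_af >= cfg.common_af_threshold:
            if audit is not None:
                audit.append(AuditEntry(c.key, "common_snp", "removed"))
        else:
            kept.append(c)
    return kept


def merge_adjacent_snvs(
    calls: Iterable[VariantCall], cfg: RefinementConfig
) -> list[VariantCall]:
    """Merge maximal runs of in-cis SNVs at consecutive positions into MNVs.

    Runs share sample, chromosome and phase set.  Runs longer than
    ``max_mnv_len`` are left unmerged (the constituents stay SNVs, and
    are not retained as an over-long MNV later in the cascade).  The
    merged record's read support is the minimum over constituents.
    """
    calls = list(calls)
    phased: dict[tuple[str, str], list[VariantCall]] = {}
    rest: list[VariantCall] = []
    for c in calls:
        if c.vclass == "SNV" and c.phase_set is not None:
            phased.setdefault((c.sample_id, c.phase_set), []).append(c)
        else:
            rest.append(c)
    out = list(rest)
    for (sample, phase_set), group in phased.items():
        chroms = {c.chrom for c in group}
        if len(chroms) > 1:
            raise ValueError(
                f"phase set {phase_set!r} of sample {sample} spans chromosomes {sorted(chroms)}"
            )
        group.sort(key=lambda c: c.pos)
        run: list[VariantCall] = []
        for c in group + [None]:  # type: ignore[list-item]
            if run and (c is None or c.pos != run[-1].pos + 1):
                if 2 <= len(run) <= cfg.max_mnv_len:
                    out.append(_merge_run(run))
                else:
                    out.extend(run)
                run = []
            if c is not None:
                run.append(c)
    return sort_calls(out)


def _merge_run(run: Sequence[VariantCall]) -> VariantCall:
    first = run[0]
    merged = VariantCall(
        sample_id=first.sample_id,
        chrom=first.chrom,
        pos=first.pos,
        ref="".join(c.ref for c in run),
        alt="".join(c.alt for c in run),
        vclass="MNV",
        t_depth=min(c.t_depth for c in run),
        t_alt=min(c.t_alt for c in run),
        n_depth=min(c.n_depth for c in run),
        n_alt=min(c.n_alt for c in run),
        phase_set=first.phase_set,
        gene=first.gene,
        consequence=first.consequence,
        filters=frozenset().union(*(c.filters for c in run)),
    )
    return merged


def _is_simple_allele(ref: str, alt: str, cfg: RefinementConfig) -> bool:
    """Adopted reading of the allele-length retention rule."""
    within = max(len(ref), len(alt)) <= cfg.max_allele_len
    both_long = len(ref) > cfg.both_long_len and len(alt) > cfg.both_long_len
    return within and not both_long


def cascade_rule(call: VariantCall, cfg: RefinementConfig) -> str | None:
    """Name of the first cascade rule removing the call, or None if retained."""
    if call.t_depth <= 0:
        return "malformed"
    if call.vclass == "MNV" and len(call.ref) > cfg.max_mnv_len:
        return "long_mnv"
    if call.vaf < cfg.min_vaf:
        return "low_vaf"
    if _is_simple_allele(call.ref, call.alt, cfg):
        return None
    # complex allele: needs high VAF and adequate coverage in both samples
    if (
        call.vaf > cfg.rescue_vaf_floor
        and call.t_depth >= cfg.min_depth
        and call.n_depth >= cfg.min_depth
    ):
        return None
    return "complex_low_support"


def apply_refinement_cascade(
    calls: Iterable[VariantCall], cfg: RefinementConfig, audit: list[AuditEntry] | None = None
) -> list[VariantCall]:
    kept = []
    for c in calls:
        rule = cascade_rule(c, cfg)
        if rule is None:
            kept.append(c)
        elif audit is not None:
            audit.append(AuditEntry(c.key, rule, "removed"))
    return kept


def restrict_to_target_space(
    calls: Iterable[VariantCall],
    targets: TargetSpace,
    cfg: RefinementConfig,
    audit: list[AuditEntry] | None = None,
) -> list[VariantCall]:
    """Keep calls whose reference span lies within ``target_proximity_bp``
    of the flanked target territory (a gap equal to the threshold counts)."""
    if not targets.intervals:
        raise ValueError("target space is empty")
    kept = []
    for c in calls:
        if targets.gap_to(c.chrom, *c.span) <= cfg.target_proximity_bp:
            kept.append(c)
        elif audit is not None:
            audit.append(AuditEntry(c.key, "off_target", "removed"))
    return kept


def rescue_hotspots(
    raw_calls: Iterable[VariantCall],
    retained_calls: Iterable[VariantCall],
    cfg: RefinementConfig,
    audit: list[AuditEntry] | None = None,
) -> list[VariantCall]:
    """Reinstate filtered calls at configured hotspot sites.

    A raw call at a hotspot site removed by any earlier rule is brought
    back when its tumour alt-read count is at least ``rescue_min_t_alt``
    and its normal VAF is at most ``rescue_max_n_vaf``; the reinstated
    record carries a ``rescued:<rule>`` flag naming the overridden rule.
    """
    retained = list(retained_calls)
    retained_keys = {c.key for c in retained}
    hotspot_sites = {tuple(site) for site in cfg.hotspot_sites}
    removed_rule = {e.key: e.rule for e in (audit or []) if e.action == "removed"}
    out = list(retained)
    seen_any = False
    for c in raw_calls:
        if (c.chrom, c.pos, c.ref, c.alt) not in hotspot_sites:
            continue
        seen_any = True
        if c.key in retained_keys:
            continue
        if c.t_alt >= cfg.rescue_min_t_alt and c.n_vaf <= cfg.rescue_max_n_vaf:
            rule = removed_rule.get(c.key, "unknown")
            out.append(c.with_flags(f"rescued:{rule}"))
            if audit is not None:
                audit.append(AuditEntry(c.key, rule, "rescued"))
    if not seen_any:
        import logging

        logging.getLogger(__name__).info("no raw calls at configured hotspot sites")
    return sort_calls(out)


# ---------------------------------------------------------------------------
# orchestration


def refine(
    calls: Iterable[VariantCall],
    targets: TargetSpace,
    cfg: RefinementConfig | None = None,
) -> tuple[list[VariantCall], list[AuditEntry]]:
    """Run the full refinement pipeline; returns retained calls and the
    audit log (each removed record appears once, with the first rule
    that removed it)."""
    cfg = cfg or RefinementConfig()
    raw = sort_calls(calls)
    audit: list[AuditEntry] = []
    stage = exclude_common_snps(raw, cfg, audit)
    stage = merge_adjacent_snvs(stage, cfg)
    stage = apply_refinement_cascade(stage, cfg, audit)
    stage = restrict_to_target_space(stage, targets, cfg, audit)
    stage = rescue_hotspots(raw, stage, cfg, audit)
    return stage, audit


def write_audit(path: str | Path, audit: Sequence[AuditEntry]) -> None:
    rows = [
        {
            "sample_id": e.key[0], "chrom": e.key[1], "pos": e.key[2],
            "ref": e.key[3], "alt": e.key[4], "rule": e.rule, "action": e.action,
        }
        for e in audit
    ]
    pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "rule", "action"]).to_csv(
        path, sep="\t", index=False
    )
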