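"""Readers and writers for every external format the pipeline touches.

Coordinate conventions are fixed at this boundary and nowhere else:
variants are 1-based inclusive (VCF style), intervals are 0-based
half-open (BED style).  Chromosome names are normalised to a single
style per file; mixing ``chr1`` and ``1`` in one file is an error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "vclass",
    "t_depth", "t_alt", "n_depth", "n_alt",
    "pop_af", "phase_set", "gene", "consequence", "filters",
]

SEGMENT_COLUMNS = [
    "sample", "chrom", "start", "end", "total_cn", "minor_cn",
    "ploidy", "goodness_of_fit",
]

MINIMIZER_COLUMNS = ["taxon_id", "m", "M", "n", "N"]

#: ASCAT-style profiles below this goodness of fit are too noisy to use.
LOW_FIT_THRESHOLD = 0.9


# ---------------------------------------------------------------------------
# chromosome-name normalisation


def normalize_chroms(names: Iterable[str], style: str = "keep") -> list[str]:
    """Normalise chromosome names to one style.

    ``style`` is ``"keep"`` (accept whatever single style the file uses),
    ``"chr"`` (force the ``chr`` prefix) or ``"bare"`` (strip it).
    A mixture of prefixed and bare names in one file is an error.
    """
    names = list(names)
    prefixed = {n.startswith("chr") for n in names}
    if len(prefixed) > 1:
        raise ValueError("mixed chromosome naming styles ('chr1' and '1') in one file")
    if style == "keep":
        return names
    if style == "chr":
        return [n if n.startswith("chr") else "chr" + n for n in names]
    if style == "bare":
        return [n[3:] if n.startswith("chr") else n for n in names]
    raise ValueError(f"unknown chromosome style {style!r}")


# ---------------------------------------------------------------------------
# VariantCall


def classify_alleles(ref: str, alt: str) -> str:
    """Variant class implied by allele lengths (SNV/MNV/INS/DEL/COMPLEX)."""
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    if len(ref) < len(alt):
        return "INS" if len(ref) == 1 else "COMPLEX"
    return "DEL" if len(alt) == 1 else "COMPLEX"


@dataclass
class VariantCall:
    """One somatic call with read support and filter provenance.

    ``pos`` is the 1-based position of the first reference base.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    t_depth: int
    t_alt: int
    n_depth: int
    n_alt: int
    vclass: str | None = None
    pop_af: float | None = None
    phase_set: str | None = None
    gene: str | None = None
    consequence: str | None = None
    filters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.vclass is None:
            self.vclass = classify_alleles(self.ref, self.alt)
        self.filters = frozenset(self.filters)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span covered by the call."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    @property
    def vaf(self) -> float:
        """Tumour variant allele fraction; 0 when depth is 0."""
        return self.t_alt / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth > 0 else 0.0

    def with_flags(self, *flags: str) -> "VariantCall":
        return replace(self, filters=self.filters | set(flags))

    def validate(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref equals alt")
        if not (0 <= self.t_alt <= self.t_depth):
            raise ValueError(f"{self.key}: t_alt {self.t_alt} exceeds t_depth {self.t_depth}")
        if not (0 <= self.n_alt <= self.n_depth):
            raise ValueError(f"{self.key}: n_alt {self.n_alt} exceeds n_depth {self.n_depth}")
        if self.pos < 1:
            raise ValueError(f"{self.key}: position must be 1-based")
        expected = classify_alleles(self.ref, self.alt)
        if self.vclass == "SNV" and expected != "SNV":
            raise ValueError(f"{self.key}: vclass SNV inconsistent with allele lengths")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"{self.key}: pop_af outside [0, 1]")


def sort_calls(calls: Iterable[VariantCall]) -> list[VariantCall]:
    return sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.pos, c.ref, c.alt))


# ---------------------------------------------------------------------------
# TargetSpace


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Merge 0-based half-open intervals per chromosome (overlaps counted once)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start:
            raise ValueError(f"interval end {end} <= start {start} on {chrom}")
        per_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


@dataclass
class TargetSpace:
    """Merged genomic intervals defining the assayable territory.

    Intervals are stored already extended by ``flank_bp`` on both sides
    and merged, so ``total_mb`` counts every base exactly once.
    """

    intervals: dict[str, np.ndarray]
    flank_bp: int = 0

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], flank_bp: int = 0
    ) -> "TargetSpace":
        if flank_bp < 0:
            raise ValueError("flank_bp must be non-negative")
        flanked = [
            (chrom, max(0, start - flank_bp), end + flank_bp)
            for chrom, start, end in intervals
        ]
        return cls(intervals=merge_intervals(flanked), flank_bp=flank_bp)

    @property
    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6

    def gap_to(self, chrom: str, start: int, end: int) -> float:
        """Distance in bp from the 0-based half-open span to the nearest
        interval; 0 if they overlap, ``inf`` if the chromosome is absent."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return math.inf
        starts, ends = ivs[:, 0], ivs[:, 1]
        i = int(np.searchsorted(starts, end))
        best = math.inf
        if i > 0:  # interval starting at or before the span end
            left = ivs[i - 1]
            if left[1] > start:
                return 0.0
            best = start - left[1]
        if i < len(ivs):
            best = min(best, float(starts[i] - end))
        return float(max(best, 0.0))

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return self.gap_to(chrom, start, end) == 0.0


def read_targets(path: str | Path, flank_bp: int = 0, chrom_style: str = "keep") -> TargetSpace:
    """Read a BED3 file into a :class:`TargetSpace`.

    Input intervals are extended by ``flank_bp`` on both sides and merged;
    unsorted input is accepted.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected at least 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end {end} <= start {start}")
            rows.append((chrom, start, end))
    chroms = normalize_chroms([r[0] for r in rows], chrom_style)
    rows = [(c, s, e) for c, (_, s, e) in zip(chroms, rows)]
    return TargetSpace.from_intervals(rows, flank_bp=flank_bp)


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# CNSegmentProfile


@dataclass
class CNSegmentProfile:
    """Ordered allele-specific copy-number segments for one sample.

    ``segments`` is a list of ``(chrom, start, end, total_cn, minor_cn)``
    with 0-based half-open coordinates, sorted and non-overlapping per
    chromosome.  Profiles whose goodness of fit is below 0.9 carry the
    ``low_fit`` flag and are excluded from downstream CN stages.
    """

    sample_id: str
    segments: list[tuple[str, int, int, int, int]]
    ploidy: float = 2.0
    goodness_of_fit: float = 1.0
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s[0], s[1]))
        if self.goodness_of_fit < LOW_FIT_THRESHOLD:
            self.flags = frozenset(self.flags) | {"low_fit"}
        else:
            self.flags = frozenset(self.flags)
        self.validate()

    def validate(self) -> None:
        prev: dict[str, int] = {}
        for chrom, start, end, total_cn, minor_cn in self.segments:
            if end <= start:
                raise ValueError(f"{self.sample_id}: empty segment on {chrom}")
            if total_cn < 0 or minor_cn < 0 or minor_cn > total_cn:
                raise ValueError(
                    f"{self.sample_id}: minor_cn {minor_cn} exceeds total_cn {total_cn} on {chrom}"
                )
            if chrom in prev and start < prev[chrom]:
                raise ValueError(f"{self.sample_id}: overlapping segments on {chrom}")
            prev[chrom] = end
        if not (0.0 <= self.goodness_of_fit <= 1.0):
            raise ValueError(f"{self.sample_id}: goodness_of_fit outside [0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"{self.sample_id}: ploidy must be positive")

    def chrom_segments(self, chrom: str) -> list[tuple[str, int, int, int, int]]:
        return [s for s in self.segments if s[0] == chrom]

    @property
    def chromosomes(self) -> list[str]:
        return sorted({s[0] for s in self.segments})


def read_segments(path: str | Path, chrom_style: str = "keep") -> list[CNSegmentProfile]:
    """Read an allele-specific segment table into per-sample profiles."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str},
                     float_precision="round_trip")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["chrom"] = normalize_chroms(df["chrom"], chrom_style)
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        segments = [
            (r.chrom, int(r.start), int(r.end), int(r.total_cn), int(r.minor_cn))
            for r in grp.itertuples()
        ]
        profiles.append(
            CNSegmentProfile(
                sample_id=str(sample),
                segments=segments,
                ploidy=float(grp["ploidy"].iloc[0]),
                goodness_of_fit=float(grp["goodness_of_fit"].iloc[0]),
            )
        )
    return profiles


def write_segments(path: str | Path, profiles: Sequence[CNSegmentProfile]) -> None:
    rows = []
    for p in profiles:
        for chrom, start, end, total_cn, minor_cn in p.segments:
            rows.append(
                (p.sample_id, chrom, start, end, total_cn, minor_cn,
                 p.ploidy, p.goodness_of_fit)
            )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TaxonMinimizerRecord


@dataclass
class TaxonMinimizerRecord:
    """Distinct-minimizer evidence for one taxon in one sample.

    ``m`` of ``M`` database minimizers for the taxon were observed, in
    ``n`` reads assigned to the taxon out of ``N`` reads evaluated.
    """

    taxon_id: str
    m: int
    M: int
    n: int
    N: int
    p_value: float | None = None
    q_value: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if self.M <= 0 or self.N <= 0:
            raise ValueError(f"{self.taxon_id}: M and N must be positive")
        if not (0 <= self.m <= self.M):
            raise ValueError(f"taxon {self.taxon_id}: m {self.m} exceeds M {self.M}")
        if not (0 <= self.n <= self.N):
            raise ValueError(f"taxon {self.taxon_id}: n {self.n} exceeds N {self.N}")

    @property
    def proportion(self) -> float:
        return self.m / self.M


def read_minimizer_report(path: str | Path) -> list[TaxonMinimizerRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str}, float_precision="round_trip")
    missing = set(MINIMIZER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TaxonMinimizerRecord(
            taxon_id=str(r.taxon_id), m=int(r.m), M=int(r.M), n=int(r.n), N=int(r.N)
        )
        for r in df.itertuples()
    ]


def write_minimizer_report(path: str | Path, records: Sequence[TaxonMinimizerRecord]) -> None:
    rows = [
        {
            "taxon_id": r.taxon_id, "m": r.m, "M": r.M, "n": r.n, "N": r.N,
            "proportion": f"{r.proportion:.12g}",
            "p_value": "" if r.p_value is None else f"{r.p_value:.6g}",
            "q_value": "" if r.q_value is None else f"{r.q_value:.6g}",
            "significant": "" if r.significant is None else str(r.significant),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant tables


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    chrom_style: str = "keep",
    **vcf_kwargs,
) -> list[VariantCall]:
    """Read somatic calls from a tab-separated table or a minimal VCF.

    Records are validated and returned sorted by (sample, chrom, pos).
    A malformed row raises an error naming its line number.
    """
    if dialect == "tsv":
        return _read_variant_tsv(path, chrom_style)
    if dialect == "vcf_minimal":
        return _read_variant_vcf(path, chrom_style=chrom_style, **vcf_kwargs)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _read_variant_tsv(path: str | Path, chrom_style: str) -> list[VariantCall]:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str},
        float_precision="round_trip",
    )
    required = {"sample_id", "chrom", "pos", "ref", "alt", "t_depth", "t_alt", "n_depth", "n_alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return []
    df["chrom"] = normalize_chroms(df["chrom"], chrom_style)
    calls = []
    for i, r in enumerate(df.itertuples()):
        lineno = i + 2  # header is line 1
        try:
            call = VariantCall(
                sample_id=str(r.sample_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                vclass=_opt_str(getattr(r, "vclass", None)),
                t_depth=int(r.t_depth),
                t_alt=int(r.t_alt),
                n_depth=int(r.n_depth),
                n_alt=int(r.n_alt),
                pop_af=None if pd.isna(getattr(r, "pop_af", float("nan"))) else float(r.pop_af),
                phase_set=_opt_str(getattr(r, "phase_set", None)),
                gene=_opt_str(getattr(r, "gene", None)),
                consequence=_opt_str(getattr(r, "consequence", None)),
                filters=frozenset(
                    f for f in str(_opt_str(getattr(r, "filters", None)) or "").split(";") if f
                ),
            )
            call.validate()
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        calls.append(call)
    return sort_calls(calls)


def _read_variant_vcf(
    path: str | Path,
    sample_id: str | None = None,
    tumour_sample: str = "TUMOUR",
    normal_sample: str = "NORMAL",
    chrom_style: str = "keep",
) -> list[VariantCall]:
    """Minimal VCF reader: CHROM/POS/REF/ALT plus per-sample AD depths.

    Symbolic or breakend alternate alleles are skipped with a warning.
    No other VCF semantics (multi-allelic genotypes, phasing format
    fields, structural variants) are interpreted.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    if sample_id is None:
        sample_id = Path(path).stem
    samples = list(vf.header.samples)
    for name in (tumour_sample, normal_sample):
        if name not in samples:
            raise ValueError(f"{path}: sample {name!r} not in VCF header {samples}")
    calls = []
    chrom_seen: list[str] = []
    for i, rec in enumerate(vf, start=1):
        if rec.alts is None:
            continue
        for alt in rec.alts:
            if not alt or not alt.isalpha():
                log.warning("%s: record %d: skipping symbolic allele %r", path, i, alt)
                continue
            t_ad = rec.samples[tumour_sample].get("AD")
            n_ad = rec.samples[normal_sample].get("AD")
            if t_ad is None or n_ad is None:
                raise ValueError(f"{path}: record {i}: missing AD field")
            t_depth, t_alt = int(sum(x or 0 for x in t_ad)), int(t_ad[1] or 0)
            n_depth, n_alt = int(sum(x or 0 for x in n_ad)), int(n_ad[1] or 0)
            chrom_seen.append(rec.chrom)
            try:
                call = VariantCall(
                    sample_id=sample_id, chrom=rec.chrom, pos=rec.pos,
                    ref=rec.ref, alt=alt,
                    t_depth=t_depth, t_alt=t_alt, n_depth=n_depth, n_alt=n_alt,
                    phase_set=str(rec.samples[tumour_sample].get("PS"))
                    if rec.samples[tumour_sample].get("PS") is not None else None,
                )
                call.validate()
            except ValueError as exc:
                raise ValueError(f"{path}: record {i}: {exc}") from exc
            calls.append(call)
    styles = normalize_chroms(chrom_seen, chrom_style)
    for call, chrom in zip(calls, styles):
        call.chrom = chrom
    return sort_calls(calls)


def write_variant_table(path: str | Path, calls: Sequence[VariantCall]) -> None:
    rows = [
        {
            "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "vclass": c.vclass,
            "t_depth": c.t_depth, "t_alt": c.t_alt,
            "n_depth": c.n_depth, "n_alt": c.n_alt,
            "pop_af": "" if c.pop_af is None else repr(c.pop_af),
            "phase_set": c.phase_set or "",
            "gene": c.gene or "",
            "consequence": c.consequence or "",
            "filters": ";".join(sorted(c.filters)),
        }
        for c in sort_calls(calls)
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_run_metadata(path: str | Path, **fields) -> None:
    """Write the JSON sidecar emitted next to every table this package writes."""
    payload = {"package": "sgcohort", **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
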