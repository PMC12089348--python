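"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a salivary-gland tumour cohort: 32 benign
tumours of which 25 carry a fixed CTNNB1-like hotspot substitution and
5 a mutually exclusive FBXW11-like hotspot, 11 malignant tumours with
one mismatch-repair-deficient hypermutator (indel-rich, ~7.5
mutations/Mb), recurrent driver mutations and two-hit events, planted
chromosome-arm losses (the 16q and 5q analogues), one chromothripsis-
like chromosome, and one enriched taxon in one sample's minimizer
report.  Everything downstream of sequencing and calling is generated;
reads, alignments and caller error models are not simulated.

The genome model is synthetic: three chromosomes of 60/50/47 Mb with
2 kb target tiles every 25 kb (an exome-like territory of ~12.6 Mb
once the 2 bp splice flank is added).  Driver genes live at fixed
coordinates inside target tiles; background mutations are placed
uniformly over the target space but outside driver genes, so planted
prevalences are exact.  Background per-sample mutation rates are
lognormal (benign median 0.32/Mb, malignant 0.56/Mb) with Poisson
counts; the indel:SNV ratio is 1:9 except for the hypermutator (1:3).

A single seeded stream drives the run; each sample's data comes from a
substream forked by stable hashing of the sample id, so adding a
sample does not perturb the others.  Fixed (config, seed) gives
byte-identical output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CNSegmentProfile,
    TargetSpace,
    TaxonMinimizerRecord,
    VariantCall,
    sort_calls,
    write_bed,
    write_minimizer_report,
    write_run_metadata,
    write_segments,
    write_variant_table,
)

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome model


@dataclass(frozen=True)
class GenomeModel:
    """Small synthetic genome: chromosome lengths, centromeres, target
    tiling and driver-gene coordinates."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 47_000_000}
    )
    centromeres: dict[str, int] = field(
        default_factory=lambda: {"chr1": 25_000_000, "chr2": 20_000_000, "chr3": 18_000_000}
    )
    tile_bp: int = 2_000
    tile_period_bp: int = 25_000
    flank_bp: int = 2
    #: gene -> (chrom, start, end), 0-based half-open; starts are tile-aligned
    genes: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: {
            "CTNNB1": ("chr1", 10_000_000, 10_040_000),
            "MLH1": ("chr1", 12_000_000, 12_050_000),
            "KMT2D": ("chr1", 30_000_000, 30_040_000),
            "HRAS": ("chr1", 40_000_000, 40_010_000),
            "DICER1": ("chr2", 10_000_000, 10_060_000),
            "FBXW11": ("chr2", 30_000_000, 30_080_000),
            "PIK3CA": ("chr2", 40_000_000, 40_050_000),
            "CYLD": ("chr3", 30_000_000, 30_060_000),
            "IKBKB": ("chr3", 10_000_000, 10_040_000),
        }
    )
    #: hotspot sites (chrom, 1-based pos, ref, alt)
    hotspots: dict[str, tuple[str, int, str, str]] = field(
        default_factory=lambda: {
            "CTNNB1": ("chr1", 10_000_101, "T", "C"),
            "FBXW11": ("chr2", 30_000_101, "A", "G"),
        }
    )

    def target_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, length in self.chrom_lengths.items():
            for start in range(0, length - self.tile_bp, self.tile_period_bp):
                out.append((chrom, start, start + self.tile_bp))
        return out

    def target_space(self) -> TargetSpace:
        return TargetSpace.from_intervals(self.target_intervals(), flank_bp=self.flank_bp)

    def arm_table(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chrom_lengths.items():
            cen = self.centromeres[chrom]
            rows.append({"chrom": chrom, "arm": "p", "start": 0, "end": cen})
            rows.append({"chrom": chrom, "arm": "q", "start": cen, "end": length})
        return pd.DataFrame(rows)

    def chrom_lengths_mb(self) -> dict[str, float]:
        return {c: l / 1e6 for c, l in self.chrom_lengths.items()}

    def difficult_regions(self) -> list[tuple[str, int, int]]:
        """A fixed low-mappability-style mask used by the focal filters."""
        return [
            ("chr1", 54_000_000, 56_000_000),
            ("chr2", 44_000_000, 45_500_000),
            ("chr3", 2_000_000, 3_000_000),
        ]


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    The defaults mirror the cohort the package emulates: 32 benign and
    11 malignant samples; 25 benign CTNNB1-hotspot and 5 benign
    FBXW11-hotspot carriers (disjoint) plus one malignant FBXW11
    carrier; one dMMR hypermutator at 7.5 mutations/Mb with an elevated
    indel fraction; arm losses of the 16q analogue in 4 and the 5q
    analogue in 2 malignant samples; one chromothripsis-like chromosome
    (10 switches, 2 states); one 10-fold enriched taxon.
    """

    n_benign: int = 32
    n_malignant: int = 11
    n_ctnnb1: int = 25
    n_fbxw11_benign: int = 5
    n_fbxw11_malignant: int = 1
    benign_label: str = "BCA"
    malignant_label: str = "BCAC"
    # background burden (mutations/Mb): lognormal per-sample rates
    benign_rate_median: float = 0.32
    benign_rate_sigma: float = 0.35
    malignant_rate_median: float = 0.56
    malignant_rate_sigma: float = 0.5
    hypermutator_rate: float = 7.5
    indel_fraction: float = 0.1
    hypermutator_indel_fraction: float = 0.25
    # raw-call noise exercising the refinement cascade
    n_common_snps: int = 2
    n_low_vaf: int = 2
    off_target_fraction: float = 0.10
    # low-purity hotspot carriers exercising hotspot rescue
    n_low_purity_hotspot: int = 2
    low_purity_vaf: float = 0.06
    #: background (passenger) mutations are binned into this many
    #: recurrently hit positional gene labels, giving samples realistic
    #: multi-gene rows in the alteration matrix
    n_passenger_genes: int = 10
    # minimizer reports
    n_taxa: int = 150
    total_reads: int = 1_000_000
    taxon_enrichment: float = 10.0
    genome: GenomeModel = field(default_factory=GenomeModel)

    def validate(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.n_ctnnb1 + self.n_fbxw11_benign > self.n_benign:
            raise ValueError(
                "infeasible prevalence: hotspot carriers exceed the benign cohort size"
            )
        if self.n_fbxw11_malignant > self.n_malignant:
            raise ValueError("infeasible prevalence: malignant hotspot carriers exceed cohort")


@dataclass
class SyntheticTruth:
    seed: int
    cohort_sizes: tuple[int, int]
    hotspot_assignment: dict[str, str]  # sample -> CTNNB1_hotspot | FBXW11_hotspot | none
    hypermutator_sample: str
    planted_arm_losses: list[tuple[str, str]]  # (sample, arm e.g. "chr3q")
    chromothripsis_plant: tuple[str, str, int, int]  # (sample, chrom, n_switches, n_states)
    planted_taxon: tuple[str, float, str]  # (taxon_id, enrichment, sample)
    planted_two_hits: list[tuple[str, str, str]]  # (sample, gene, evidence)
    background_tmb_params: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: everything the pipeline consumes."""

    calls: list[VariantCall]
    profiles: list[CNSegmentProfile]
    minimizer_reports: dict[str, list[TaxonMinimizerRecord]]
    manifest: pd.DataFrame
    targets: TargetSpace
    genome: GenomeModel
    truth: SyntheticTruth

    @property
    def labels(self) -> dict[str, str]:
        return dict(zip(self.manifest["sample_id"], self.manifest["cohort"]))


def _fork(seed: int, name: str) -> np.random.Generator:
    """Stable per-sample substream: hash the name, mix with the run seed."""
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed % (2**31), sub])


# ---------------------------------------------------------------------------
# copy-number helpers


def _replace_region(
    segments: list[tuple[str, int, int, int, int]],
    chrom: str,
    new: list[tuple[str, int, int, int, int]],
) -> list[tuple[str, int, int, int, int]]:
    """Splice ``new`` segments into a profile, truncating any existing
    segments of ``chrom`` that overlap the replaced region."""
    region_start = min(s[1] for s in new)
    region_end = max(s[2] for s in new)
    out = []
    for seg in segments:
        c, s, e, tot, mi = seg
        if c != chrom or e <= region_start or s >= region_end:
            out.append(seg)
            continue
        if s < region_start:
            out.append((c, s, region_start, tot, mi))
        if e > region_end:
            out.append((c, region_end, e, tot, mi))
    out.extend(new)
    return sorted(out, key=lambda x: (x[0], x[1]))


def plant_chromothripsis(
    profile: CNSegmentProfile,
    chrom: str,
    n_switches: int,
    n_states: int,
    rng: np.random.Generator,
    chrom_length: int | None = None,
    max_region_bp: int = 40_000_000,
) -> CNSegmentProfile:
    """Plant an oscillating copy-number region with exactly
    ``n_switches`` adjacent total-CN changes among ``n_states`` states.

    The planted region spans at most 50 Mb; outside it the profile is
    unchanged.  States cycle 2, 3, ..., so an even switch count starts
    and ends at the diploid baseline.
    """
    if n_switches < 1:
        raise ValueError("n_switches must be >= 1")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if n_switches + 1 < n_states:
        raise ValueError("need n_switches + 1 segments >= n_states states")
    segs = profile.chrom_segments(chrom)
    if not segs:
        raise ValueError(f"chromosome {chrom!r} absent from profile")
    chrom_len = chrom_length if chrom_length is not None else max(s[2] for s in segs)
    n_seg = n_switches + 1
    region_bp = min(max_region_bp, chrom_len - 2)
    if region_bp < n_seg:
        raise ValueError(f"chromosome {chrom!r} too short for requested region")
    start = int(rng.integers(0, chrom_len - region_bp))
    seg_len = region_bp // n_seg
    states = [2 + k for k in range(n_states)]
    new = []
    for i in range(n_seg):
        s = start + i * seg_len
        e = start + (i + 1) * seg_len if i < n_seg - 1 else start + region_bp
        cn = states[i % n_states]
        new.append((chrom, s, e, cn, min(1, cn)))
    return CNSegmentProfile(
        sample_id=profile.sample_id,
        segments=_replace_region(list(profile.segments), chrom, new),
        ploidy=profile.ploidy,
        goodness_of_fit=profile.goodness_of_fit,
    )


def _baseline_profile(
    sample: str, genome: GenomeModel, rng: np.random.Generator
) -> CNSegmentProfile:
    """Diploid profile with a few random (CN-neutral) breakpoints per
    chromosome, as a segmentation of real data would show."""
    segments = []
    for chrom, length in genome.chrom_lengths.items():
        n_break = int(rng.integers(0, 3))
        cuts = np.unique(rng.integers(1_000_000, length - 1_000_000, size=n_break)).tolist()
        bounds = [0] + cuts + [length]
        for s, e in zip(bounds, bounds[1:]):
            segments.append((chrom, int(s), int(e), 2, 1))
    gof = float(0.95 + 0.04 * rng.random())
    return CNSegmentProfile(sample_id=sample, segments=segments, ploidy=2.0, goodness_of_fit=gof)


def _plant_arm_loss(
    profile: CNSegmentProfile, genome: GenomeModel, arm: str
) -> CNSegmentProfile:
    chrom, which = arm[:-1], arm[-1]
    cen = genome.centromeres[chrom]
    length = genome.chrom_lengths[chrom]
    start, end = (0, cen) if which == "p" else (cen, length)
    new = [(chrom, start, end, 1, 0)]
    return CNSegmentProfile(
        sample_id=profile.sample_id,
        segments=_replace_region(list(profile.segments), chrom, new),
        ploidy=profile.ploidy,
        goodness_of_fit=profile.goodness_of_fit,
    )


def _plant_focal_loss(
    profile: CNSegmentProfile, chrom: str, start: int, end: int
) -> CNSegmentProfile:
    new = [(chrom, start, end, 1, 0)]
    return CNSegmentProfile(
        sample_id=profile.sample_id,
        segments=_replace_region(list(profile.segments), chrom, new),
        ploidy=profile.ploidy,
        goodness_of_fit=profile.goodness_of_fit,
    )


# ---------------------------------------------------------------------------
# minimizer reports


def simulate_null_minimizer_report(
    n_taxa: int,
    rng: np.random.Generator,
    total_reads: int = 1_000_000,
    prefix: str = "T",
) -> list[TaxonMinimizerRecord]:
    """Null classifier report: each taxon's observed distinct minimizers
    are Binomial(M, n/N) draws, i.e. exactly the test's null model."""
    M = (10 ** rng.uniform(4.0, 5.0, size=n_taxa)).astype(np.int64)
    n = rng.integers(1_000, 10_000, size=n_taxa)
    p0 = n / total_reads
    m = rng.binomial(M, p0)
    return [
        TaxonMinimizerRecord(
            taxon_id=f"{prefix}{i:04d}", m=int(m[i]), M=int(M[i]), n=int(n[i]), N=total_reads
        )
        for i in range(n_taxa)
    ]


def plant_taxon(
    records: Sequence[TaxonMinimizerRecord],
    taxon_id: str,
    enrichment: float,
    rng: np.random.Generator | None = None,
) -> list[TaxonMinimizerRecord]:
    """Raise one taxon's observed minimizers to ``enrichment`` times its
    null expectation (capped at M)."""
    if enrichment <= 1.0:
        raise ValueError("enrichment must be > 1")
    ids = [r.taxon_id for r in records]
    if taxon_id not in ids:
        raise ValueError(f"taxon {taxon_id!r} not in report")
    out = []
    for r in records:
        if r.taxon_id == taxon_id:
            expected = r.M * r.n / r.N
            m = min(r.M, int(round(enrichment * expected)))
            r = TaxonMinimizerRecord(taxon_id=r.taxon_id, m=m, M=r.M, n=r.n, N=r.N)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# variants


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(BASES[ref]), str(BASES[alt])


def _random_indel_alleles(rng: np.random.Generator) -> tuple[str, str]:
    k = int(rng.integers(1, 6))
    anchor = str(BASES[rng.integers(4)])
    extra = "".join(BASES[rng.integers(0, 4, size=k)])
    if rng.random() < 0.5:
        return anchor + extra, anchor  # deletion
    return anchor, anchor + extra  # insertion


class _TargetSampler:
    """Uniform positions within the merged flanked target space."""

    def __init__(self, targets: TargetSpace):
        self.chroms: list[str] = []
        starts, lens = [], []
        for chrom, ivs in sorted(targets.intervals.items()):
            for s, e in ivs:
                self.chroms.append(chrom)
                starts.append(s)
                lens.append(e - s)
        self.starts = np.asarray(starts)
        self.lens = np.asarray(lens)
        self.cum = np.cumsum(self.lens)

    def draw(self, rng: np.random.Generator) -> tuple[str, int, int]:
        u = int(rng.integers(0, self.cum[-1]))
        i = int(np.searchsorted(self.cum, u, side="right"))
        offset = u - (self.cum[i - 1] if i > 0 else 0)
        pos0 = int(self.starts[i] + offset)
        return self.chroms[i], pos0 + 1, i  # 1-based position, interval index


def _in_any_gene(genome: GenomeModel, chrom: str, pos: int) -> str | None:
    for gene, (c, s, e) in genome.genes.items():
        if c == chrom and s < pos <= e:
            return gene
    return None


def _read_support(
    rng: np.random.Generator, vaf: float, mean_depth: int = 80
) -> tuple[int, int, int, int]:
    t_depth = max(20, int(rng.poisson(mean_depth)))
    t_alt = int(rng.binomial(t_depth, vaf))
    n_depth = max(20, int(rng.poisson(mean_depth)))
    return t_depth, t_alt, n_depth, 0


def _background_calls(
    sample: str,
    rate_per_mb: float,
    indel_fraction: float,
    genome: GenomeModel,
    sampler: _TargetSampler,
    targets: TargetSpace,
    rng: np.random.Generator,
    n_passenger_genes: int = 10,
) -> list[VariantCall]:
    n = int(rng.poisson(rate_per_mb * targets.total_mb))
    calls = []
    for _ in range(n):
        for _attempt in range(100):
            chrom, pos, tile = sampler.draw(rng)
            if _in_any_gene(genome, chrom, pos) is None:
                break
        is_indel = rng.random() < indel_fraction
        ref, alt = _random_indel_alleles(rng) if is_indel else _random_snv_alleles(rng)
        vaf = float(rng.uniform(0.15, 0.5))
        t_depth, t_alt, n_depth, n_alt = _read_support(rng, vaf)
        t_alt = max(t_alt, int(np.ceil(0.12 * t_depth)))  # clonal somatic support
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                t_depth=t_depth, t_alt=t_alt, n_depth=n_depth, n_alt=n_alt,
                gene=f"PG{tile % n_passenger_genes:02d}" if n_passenger_genes else None,
                consequence="missense" if rng.random() < 0.7 else "synonymous",
            )
        )
    return calls


def _noise_calls(
    sample: str,
    cfg: CohortConfig,
    genome: GenomeModel,
    sampler: _TargetSampler,
    targets: TargetSpace,
    rng: np.random.Generator,
) -> list[VariantCall]:
    """Raw-call noise that the refinement cascade must remove: common
    SNPs, sub-threshold-VAF artefacts and off-target calls."""
    calls = []
    for _ in range(cfg.n_common_snps):
        chrom, pos, _tile = sampler.draw(rng)
        ref, alt = _random_snv_alleles(rng)
        t_depth, t_alt, n_depth, _ = _read_support(rng, 0.5)
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                t_depth=t_depth, t_alt=max(t_alt, 1), n_depth=n_depth,
                n_alt=int(n_depth * 0.5), pop_af=float(rng.uniform(0.01, 0.4)),
                consequence="missense",
            )
        )
    for _ in range(cfg.n_low_vaf):
        chrom, pos, _tile = sampler.draw(rng)
        ref, alt = _random_snv_alleles(rng)
        t_depth = max(20, int(rng.poisson(80)))
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                t_depth=t_depth, t_alt=max(1, int(t_depth * 0.04)), n_depth=80, n_alt=0,
                consequence="missense",
            )
        )
    n_off = max(1, int(round(cfg.off_target_fraction * 5)))
    for _ in range(n_off):
        for _attempt in range(200):
            chrom = str(rng.choice(list(genome.chrom_lengths)))
            pos = int(rng.integers(1, genome.chrom_lengths[chrom]))
            span = (pos - 1, pos)
            if (
                targets.gap_to(chrom, *span) > 150
                and _in_any_gene(genome, chrom, pos) is None
            ):
                break
        ref, alt = _random_snv_alleles(rng)
        t_depth, t_alt, n_depth, n_alt = _read_support(rng, 0.3)
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                t_depth=t_depth, t_alt=max(t_alt, 3), n_depth=n_depth, n_alt=n_alt,
                consequence="missense",
            )
        )
    return calls


def _planted_call(
    sample: str,
    genome: GenomeModel,
    gene: str,
    rng: np.random.Generator,
    consequence: str,
    offset: int = 101,
    vaf: float | None = None,
    indel: bool = False,
) -> VariantCall:
    chrom, start, _end = genome.genes[gene]
    pos = start + offset  # inside the gene's first target tile
    ref, alt = _random_indel_alleles(rng) if indel else _random_snv_alleles(rng)
    vaf = float(rng.uniform(0.25, 0.5)) if vaf is None else vaf
    t_depth, t_alt, n_depth, n_alt = _read_support(rng, vaf)
    t_alt = max(t_alt, max(3, int(np.ceil(vaf * 0.8 * t_depth))))
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        t_depth=t_depth, t_alt=min(t_alt, t_depth), n_depth=n_depth, n_alt=n_alt,
        gene=gene, consequence=consequence,
    )


def _hotspot_call(
    sample: str, genome: GenomeModel, gene: str, rng: np.random.Generator,
    low_purity: bool, low_purity_vaf: float,
) -> VariantCall:
    chrom, pos, ref, alt = genome.hotspots[gene]
    if low_purity:
        t_depth = max(40, int(rng.poisson(80)))
        t_alt = max(3, int(rng.binomial(t_depth, low_purity_vaf)))
    else:
        vaf = float(rng.uniform(0.25, 0.5))
        t_depth = max(20, int(rng.poisson(80)))
        t_alt = max(3, int(rng.binomial(t_depth, vaf)))
    return VariantCall(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        t_depth=t_depth, t_alt=min(t_alt, t_depth),
        n_depth=max(20, int(rng.poisson(80))), n_alt=0,
        gene=gene, consequence="missense",
    )


def _phased_pair(
    sample: str, sampler: _TargetSampler, rng: np.random.Generator
) -> list[VariantCall]:
    """Two adjacent in-cis SNVs sharing a phase set (merged to an MNV)."""
    chrom, pos, _tile = sampler.draw(rng)
    refs = rng.choice(4, size=2)
    t_depth = max(30, int(rng.poisson(80)))
    t_alt = int(t_depth * rng.uniform(0.3, 0.45))
    calls = []
    for i in range(2):
        ref = str(BASES[refs[i]])
        alt = str(BASES[(refs[i] + 1) % 4])
        calls.append(
            VariantCall(
                sample_id=sample, chrom=chrom, pos=pos + i, ref=ref, alt=alt,
                t_depth=t_depth, t_alt=t_alt, n_depth=80, n_alt=0,
                phase_set=f"{sample}_ps1", consequence="missense",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortBundle:
    """Generate the full synthetic cohort in memory.

    Deterministic given (config, seed).  Raises before generating
    anything if the configured prevalences are infeasible.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    genome = cfg.genome
    targets = genome.target_space()
    sampler = _TargetSampler(targets)

    benign = [f"{cfg.benign_label}{i + 1:02d}" for i in range(cfg.n_benign)]
    malignant = [f"{cfg.malignant_label}{i + 1:02d}" for i in range(cfg.n_malignant)]

    hotspot_assignment: dict[str, str] = {}
    for i, s in enumerate(benign):
        if i < cfg.n_ctnnb1:
            hotspot_assignment[s] = "CTNNB1_hotspot"
        elif i < cfg.n_ctnnb1 + cfg.n_fbxw11_benign:
            hotspot_assignment[s] = "FBXW11_hotspot"
        else:
            hotspot_assignment[s] = "none"
    for i, s in enumerate(malignant):
        hotspot_assignment[s] = (
            "FBXW11_hotspot" if i >= cfg.n_malignant - cfg.n_fbxw11_malignant else "none"
        )

    # deterministic per-sample roles in the malignant cohort
    hyper = malignant[0]
    kmt2d_two_hit = malignant[1:3] if cfg.n_malignant >= 3 else []
    dicer1_two_hit = malignant[2] if cfg.n_malignant >= 3 else None
    arm16q = malignant[3:7] if cfg.n_malignant >= 7 else []
    cyld_two_hit = arm16q[:2]
    arm5q = malignant[7:9] if cfg.n_malignant >= 9 else []
    hras = malignant[7:10] if cfg.n_malignant >= 10 else []
    ikbkb = malignant[5:7] if cfg.n_malignant >= 7 else []
    chromo_sample = malignant[9] if cfg.n_malignant >= 10 else malignant[-1]
    taxon_sample = malignant[-1]
    phased_samples = set(benign[1:3] + malignant[1:2])

    # choose a low-purity subset of hotspot carriers to exercise rescue
    low_purity_candidates = []
    if cfg.n_ctnnb1 >= 1:
        low_purity_candidates.append(benign[0])
    if cfg.n_fbxw11_benign >= 1:
        low_purity_candidates.append(benign[cfg.n_ctnnb1])
    low_purity = frozenset(low_purity_candidates[: cfg.n_low_purity_hotspot])

    calls: list[VariantCall] = []
    profiles: list[CNSegmentProfile] = []
    reports: dict[str, list[TaxonMinimizerRecord]] = {}
    planted_two_hits: list[tuple[str, str, str]] = []
    planted_arm_losses: list[tuple[str, str]] = []
    chromo_plant = (chromo_sample, "chr1", 10, 2)
    planted_taxon_id = f"T{cfg.n_taxa // 2:04d}"

    for sample in benign + malignant:
        rng = _fork(seed, sample)
        is_malignant = sample in malignant
        if sample == hyper:
            rate, indel_frac = cfg.hypermutator_rate, cfg.hypermutator_indel_fraction
        elif is_malignant:
            rate = float(
                np.exp(rng.normal(np.log(cfg.malignant_rate_median), cfg.malignant_rate_sigma))
            )
            indel_frac = cfg.indel_fraction
        else:
            rate = float(
                np.exp(rng.normal(np.log(cfg.benign_rate_median), cfg.benign_rate_sigma))
            )
            indel_frac = cfg.indel_fraction

        calls.extend(
            _background_calls(sample, rate, indel_frac, genome, sampler, targets, rng,
                              n_passenger_genes=cfg.n_passenger_genes)
        )
        calls.extend(_noise_calls(sample, cfg, genome, sampler, targets, rng))
        if sample in phased_samples:
            calls.extend(_phased_pair(sample, sampler, rng))

        assignment = hotspot_assignment[sample]
        if assignment == "CTNNB1_hotspot":
            calls.append(
                _hotspot_call(sample, genome, "CTNNB1", rng, sample in low_purity,
                              cfg.low_purity_vaf)
            )
        elif assignment == "FBXW11_hotspot":
            calls.append(
                _hotspot_call(sample, genome, "FBXW11", rng, sample in low_purity,
                              cfg.low_purity_vaf)
            )

        profile = _baseline_profile(sample, genome, rng)

        if sample == hyper:
            # dMMR narrative: splice disruption of the mismatch-repair gene
            # plus copy loss over it; also a PIK3CA-like hotspot and one
            # KMT2D truncating call.
            calls.append(_planted_call(sample, genome, "MLH1", rng, "splice_acceptor"))
            calls.append(_planted_call(sample, genome, "PIK3CA", rng, "missense"))
            calls.append(_planted_call(sample, genome, "KMT2D", rng, "stop_gained"))
            c, s, e = genome.genes["MLH1"]
            profile = _plant_focal_loss(profile, c, s - 100_000, e + 100_000)
            planted_two_hits.append((sample, "MLH1", "variant_plus_loh"))
        if sample in kmt2d_two_hit:
            calls.append(_planted_call(sample, genome, "KMT2D", rng, "frameshift",
                                       offset=101, indel=True))
            calls.append(_planted_call(sample, genome, "KMT2D", rng, "stop_gained", offset=301))
            planted_two_hits.append((sample, "KMT2D", "two_variants"))
        if sample == dicer1_two_hit:
            calls.append(_planted_call(sample, genome, "DICER1", rng, "frameshift",
                                       offset=101, indel=True))
            calls.append(_planted_call(sample, genome, "DICER1", rng, "stop_gained", offset=301))
            planted_two_hits.append((sample, "DICER1", "two_variants"))
        if sample in cyld_two_hit:
            calls.append(_planted_call(sample, genome, "CYLD", rng, "stop_gained"))
        if sample in ikbkb:
            calls.append(_planted_call(sample, genome, "IKBKB", rng, "missense"))
        if sample in hras:
            calls.append(_planted_call(sample, genome, "HRAS", rng, "missense"))
        if cfg.n_malignant >= 2 and sample == malignant[1]:
            calls.append(_planted_call(sample, genome, "PIK3CA", rng, "missense", offset=301))

        if sample in arm16q:
            profile = _plant_arm_loss(profile, genome, "chr3q")
            planted_arm_losses.append((sample, "chr3q"))
            if sample in cyld_two_hit:
                planted_two_hits.append((sample, "CYLD", "variant_plus_loh"))
        if sample in arm5q:
            profile = _plant_arm_loss(profile, genome, "chr2q")
            planted_arm_losses.append((sample, "chr2q"))
        if sample == chromo_sample:
            profile = plant_chromothripsis(
                profile, chromo_plant[1], chromo_plant[2], chromo_plant[3], rng,
                chrom_length=genome.chrom_lengths[chromo_plant[1]],
            )
        profiles.append(profile)

        report = simulate_null_minimizer_report(cfg.n_taxa, rng, cfg.total_reads)
        if sample == taxon_sample:
            report = plant_taxon(report, planted_taxon_id, cfg.taxon_enrichment, rng)
        reports[sample] = report

    manifest = pd.DataFrame(
        {
            "sample_id": benign + malignant,
            "cohort": [cfg.benign_label] * len(benign) + [cfg.malignant_label] * len(malignant),
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        cohort_sizes=(cfg.n_benign, cfg.n_malignant),
        hotspot_assignment=hotspot_assignment,
        hypermutator_sample=hyper,
        planted_arm_losses=planted_arm_losses,
        chromothripsis_plant=chromo_plant,
        planted_taxon=(planted_taxon_id, cfg.taxon_enrichment, taxon_sample),
        planted_two_hits=planted_two_hits,
        background_tmb_params={
            "benign_rate_median": cfg.benign_rate_median,
            "benign_rate_sigma": cfg.benign_rate_sigma,
            "malignant_rate_median": cfg.malignant_rate_median,
            "malignant_rate_sigma": cfg.malignant_rate_sigma,
            "hypermutator_rate": cfg.hypermutator_rate,
        },
    )
    return CohortBundle(
        calls=sort_calls(calls),
        profiles=profiles,
        minimizer_reports=reports,
        manifest=manifest,
        targets=targets,
        genome=genome,
        truth=truth,
    )


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0, outdir: str | Path = "cohort"
) -> tuple[Path, SyntheticTruth]:
    """Generate the cohort and write the file bundle cohort_io reads."""
    cfg = config or CohortConfig()
    cfg.validate()  # fail before writing anything
    bundle = simulate_cohort(cfg, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_variant_table(outdir / "variants.tsv", bundle.calls)
    write_segments(outdir / "segments.tsv", bundle.profiles)
    write_bed(outdir / "targets.bed", bundle.genome.target_intervals())
    write_bed(outdir / "difficult_regions.bed", bundle.genome.difficult_regions())
    bundle.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    mins = outdir / "minimizers"
    mins.mkdir(exist_ok=True)
    for sample, records in bundle.minimizer_reports.items():
        write_minimizer_report(mins / f"{sample}.tsv", records)
    with open(outdir / "truth.json", "w") as fh:
        fh.write(bundle.truth.to_json())
        fh.write("\n")
    write_run_metadata(outdir / "run_metadata.json", seed=seed,
                       config={k: v for k, v in dataclasses.asdict(cfg).items()
                               if not isinstance(v, dict)})
    return outdir, bundle.truth
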