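"""End-to-end cohort analysis: refinement through cohort report.

Ties the stage modules together for a whole cohort (synthetic bundle or
files read through :mod:`sgcohort.io`).  Each stage remains usable on
its own; this module only sequences them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import burden, cna, refinery, summary, taxa
from .simulate import CohortBundle


@dataclass
class CohortResults:
    refined_calls: list
    audit: list
    burden_records: list
    burden_summary: dict
    matrix: summary.CohortAlterationMatrix
    benign_frequencies: pd.DataFrame
    either_hotspot: tuple[int, int, float]
    chromothripsis: list
    two_hits: list
    taxa_flagged: dict
    exclusivity: pd.DataFrame | None


def analyze_cohort(
    bundle: CohortBundle,
    refine_cfg: refinery.RefinementConfig | None = None,
    taxon_cfg: taxa.TaxonTestConfig | None = None,
    exclusivity_permutations: int | None = None,
    exclusivity_seed: int = 0,
) -> CohortResults:
    """Run the full pipeline on a cohort bundle.

    The mutual-exclusivity screen is the only expensive stage; pass
    ``exclusivity_permutations`` to enable it.
    """
    refine_cfg = refine_cfg or refinery.RefinementConfig(
        hotspot_sites=[site for site in bundle.genome.hotspots.values()]
    )
    labels = bundle.labels
    benign_label = bundle.manifest["cohort"].iloc[0]
    malignant_label = bundle.manifest["cohort"].iloc[-1]

    refined, audit = refinery.refine(bundle.calls, bundle.targets, refine_cfg)

    records = burden.compute_tmb(refined, bundle.targets, samples=list(labels))
    burden_summary = burden.summarize_cohort_burden(
        records, labels, benign_label, malignant_label
    )

    matrix = summary.build_alteration_matrix(refined, labels)
    freqs = summary.hotspot_frequencies(matrix, benign_label)
    either = summary.either_hotspot_fraction(
        matrix, list(bundle.genome.hotspots), benign_label
    )

    lengths_mb = bundle.genome.chrom_lengths_mb()
    chromo = []
    for profile in bundle.profiles:
        if "low_fit" in profile.flags:
            continue
        chromo.extend(
            c for c in cna.detect_chromothripsis(profile, lengths_mb) if c.tier != "none"
        )

    two_hits = []
    for profile in bundle.profiles:
        if "low_fit" in profile.flags:
            continue
        two_hits.extend(
            cna.call_two_hit(refined, profile, bundle.genome.genes)
        )

    flagged = {
        sample: taxa.flag_significant(report, taxon_cfg)
        for sample, report in bundle.minimizer_reports.items()
    }

    exclusivity = None
    if exclusivity_permutations:
        exclusivity = summary.mutual_exclusivity_test(
            matrix, n_permutations=exclusivity_permutations, seed=exclusivity_seed,
            test_genes=list(bundle.genome.genes),
        )

    return CohortResults(
        refined_calls=refined,
        audit=audit,
        burden_records=records,
        burden_summary=burden_summary,
        matrix=matrix,
        benign_frequencies=freqs,
        either_hotspot=either,
        chromothripsis=chromo,
        two_hits=two_hits,
        taxa_flagged=flagged,
        exclusivity=exclusivity,
    )
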