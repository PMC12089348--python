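"""Cohort-level integration.

Builds the samples x genes binary non-silent alteration matrix, reports
hotspot frequencies, screens gene pairs for mutual exclusivity with a
margin-preserving permutation test, compares hotspot proportions
between cohorts with a two-proportion chi-square, and assembles the
cohort report bundle.

The mutual-exclusivity screen generates null matrices by checkerboard
swaps that conserve every row and column sum (the alteration count of
every sample and every gene), so the null respects both per-sample
mutation load and per-gene frequency.  Exclusivity of a pair is scored
by how rarely a null matrix shows as few or fewer co-occurrences than
observed; this is a deliberately simple permutation stand-in for more
elaborate published background models, and its q-values are not
expected to match any specific external tool numerically.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import VariantCall
from .taxa import bh_adjust

log = logging.getLogger(__name__)

SILENT_CLASSES = frozenset({"synonymous", "silent"})


# ---------------------------------------------------------------------------
# alteration matrix


@dataclass
class CohortAlterationMatrix:
    """Binary non-silent alteration matrix with cohort labels.

    ``data`` is a samples x genes 0/1 DataFrame; ``labels`` maps each
    sample (the DataFrame index) to its cohort label.  Genes enter only
    when altered in at least ``min_recurrence`` samples.
    """

    data: pd.DataFrame
    labels: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.labels[self.labels == cohort].index)


def build_alteration_matrix(
    calls: Iterable[VariantCall],
    labels: Mapping[str, str],
    min_recurrence: int = 2,
    silent_classes: frozenset[str] = SILENT_CLASSES,
) -> CohortAlterationMatrix:
    """Binarise non-silent calls into a samples x genes matrix.

    Samples come from ``labels`` (a sample with no qualifying call keeps
    a zero row); genes altered in fewer than ``min_recurrence`` samples
    are dropped.
    """
    samples = list(labels)
    df = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=[], dtype=int)
    for c in calls:
        if c.gene is None or (c.consequence or "") in silent_classes:
            continue
        if c.sample_id not in df.index:
            continue
        if c.gene not in df.columns:
            df[c.gene] = 0
        df.loc[c.sample_id, c.gene] = 1
    keep = [g for g in df.columns if df[g].sum() >= min_recurrence]
    if not keep:
        log.warning("no gene altered in >= %d samples; matrix is empty", min_recurrence)
    df = df[sorted(keep)]
    return CohortAlterationMatrix(data=df, labels=pd.Series(dict(labels), name="cohort"))


# ---------------------------------------------------------------------------
# hotspot frequencies


def percent_nearest_int(x: float) -> int:
    """Round half away from zero, as in cohort-frequency reporting."""
    return int(math.floor(x + 0.5))


def format_percent(x: float, mode: str = "round") -> str:
    """One-decimal percent display; ``mode='truncate'`` reproduces the
    truncating style some reports use (93.75 -> '93.7')."""
    if mode == "round":
        return f"{x:.1f}"
    if mode == "truncate":
        return f"{math.floor(x * 10) / 10:.1f}"
    raise ValueError(f"unknown percent mode {mode!r}")


def hotspot_frequencies(matrix: CohortAlterationMatrix, cohort: str) -> pd.DataFrame:
    """Per-gene altered count and percent within one cohort.

    Percent is reported both to the nearest integer and at one decimal.
    """
    samples = matrix.cohort_samples(cohort)
    if not samples:
        raise ValueError(f"cohort {cohort!r} is empty")
    sub = matrix.data.loc[samples]
    rows = []
    for gene in matrix.genes:
        count = int(sub[gene].sum())
        pct = 100.0 * count / len(samples)
        rows.append(
            {
                "gene": gene, "count": count, "n": len(samples),
                "percent_int": percent_nearest_int(pct),
                "percent_1dp": round(pct, 1),
            }
        )
    return pd.DataFrame(rows)


def either_hotspot_fraction(
    matrix: CohortAlterationMatrix, genes: Sequence[str], cohort: str
) -> tuple[int, int, float]:
    """Count and percent of cohort samples altered in any of ``genes``."""
    samples = matrix.cohort_samples(cohort)
    if not samples:
        raise ValueError(f"cohort {cohort!r} is empty")
    present = [g for g in genes if g in matrix.data.columns]
    count = int((matrix.data.loc[samples, present].sum(axis=1) > 0).sum()) if present else 0
    return count, len(samples), 100.0 * count / len(samples)


# ---------------------------------------------------------------------------
# mutual exclusivity


def _swap_chain_python(mat: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> None:
    n = rr.shape[0] // 2
    for k in range(n):
        r1, r2 = rr[2 * k], rr[2 * k + 1]
        c1, c2 = cc[2 * k], cc[2 * k + 1]
        a, b = mat[r1, c1], mat[r1, c2]
        c, d = mat[r2, c1], mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0; mat[r1, c2] = 1; mat[r2, c1] = 1; mat[r2, c2] = 0
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1; mat[r1, c2] = 0; mat[r2, c1] = 0; mat[r2, c2] = 1


_swap_chain = None


def _get_swap_chain():
    """Checkerboard-swap kernel, JIT-compiled on first use."""
    global _swap_chain
    if _swap_chain is None:
        try:
            from numba import njit

            _swap_chain = njit(cache=False)(_swap_chain_python)
        except Exception:  # pragma: no cover - numba always present in practice
            _swap_chain = _swap_chain_python
    return _swap_chain


def mutual_exclusivity_test(
    matrix: CohortAlterationMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    swap_factor: int = 10,
    check_margins: bool = False,
    test_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Margin-preserving permutation screen for mutual exclusivity.

    For every gene pair the observed co-occurrence count is compared to
    its distribution over null matrices generated by checkerboard swaps
    (both row and column sums conserved).  Exclusivity p is
    ``(1 + #{null <= observed}) / (n_permutations + 1)``; a
    co-occurrence p using the opposite tail is reported alongside.
    q-values are BH-adjusted across pairs.  Deterministic given seed.

    ``test_genes`` optionally restricts the reported (and BH-corrected)
    pairs to a curated panel; the permutation null still conserves the
    margins of the whole matrix, so per-sample alteration load is
    conditioned on even for genes outside the panel.
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive")
    df = matrix.data
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("matrix must have at least 2 genes and 2 samples")
    degenerate = [
        g for g in df.columns if df[g].sum() in (0, df.shape[0])
    ]
    if degenerate:
        log.warning("excluding degenerate (all-0/all-1) genes: %s", degenerate)
        df = df.drop(columns=degenerate)
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 non-degenerate genes")
    genes = list(df.columns)
    mat = df.to_numpy(dtype=np.int8).copy()
    row_sums, col_sums = mat.sum(axis=1), mat.sum(axis=0)
    n_ones = int(mat.sum())
    n_swaps = swap_factor * n_ones
    rng = np.random.default_rng(seed)
    swap = _get_swap_chain()

    def chain():
        rr = rng.integers(0, mat.shape[0], size=2 * n_swaps).astype(np.int64)
        cc = rng.integers(0, mat.shape[1], size=2 * n_swaps).astype(np.int64)
        swap(mat, rr, cc)

    if test_genes is not None:
        panel = [g for g in genes if g in set(test_genes)]
        idx = [genes.index(g) for g in panel]
        pairs = list(itertools.combinations(sorted(idx), 2))
    else:
        pairs = list(itertools.combinations(range(len(genes)), 2))
    if not pairs:
        raise ValueError("no testable gene pairs")
    observed = (mat.T.astype(np.int32) @ mat.astype(np.int32))
    le_counts = np.zeros_like(observed)
    ge_counts = np.zeros_like(observed)
    chain()  # burn-in
    for _ in range(n_permutations):
        chain()
        if check_margins:
            assert (mat.sum(axis=1) == row_sums).all()
            assert (mat.sum(axis=0) == col_sums).all()
        cooc = mat.T.astype(np.int32) @ mat.astype(np.int32)
        le_counts += cooc <= observed
        ge_counts += cooc >= observed
    rows = []
    for (i, j) in pairs:
        p_excl = (1 + int(le_counts[i, j])) / (n_permutations + 1)
        p_cooc = (1 + int(ge_counts[i, j])) / (n_permutations + 1)
        rows.append(
            {
                "gene_a": genes[i], "gene_b": genes[j],
                "n_a": int(col_sums[i]), "n_b": int(col_sums[j]),
                "co_occurrence": int(observed[i, j]),
                "p_exclusive": p_excl, "p_cooccur": p_cooc,
            }
        )
    out = pd.DataFrame(rows)
    out["q_exclusive"] = bh_adjust(out["p_exclusive"].tolist())
    out["q_cooccur"] = bh_adjust(out["p_cooccur"].tolist())
    return out


# ---------------------------------------------------------------------------
# two-proportion comparison


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (df=1) on the 2x2 table of two proportions.

    With ``yates=True`` each |O - E| is reduced by 0.5 and clamped at
    zero before squaring, so near-perfectly expected tables give a
    statistic of exactly 0.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n and n >= 1 in both groups")
    observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("an expected cell is 0; use an exact test instead")
    diff = np.abs(observed - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    stat = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# report assembly


def assemble_report(
    matrix: CohortAlterationMatrix,
    hotspot_genes: Sequence[str],
    cohorts: Sequence[str],
    burden_summary: dict | None = None,
    exclusivity: pd.DataFrame | None = None,
    chromothripsis: Sequence | None = None,
    two_hits: Sequence | None = None,
    percent_mode: str = "round",
) -> dict:
    """Single cohort report: per-cohort hotspot frequencies, the
    either-hotspot fraction, and whichever stage outputs are present
    (absent stages are recorded as explicit gaps)."""
    if matrix.data.shape[0] == 0:
        raise ValueError("empty cohort input")
    report: dict = {"cohorts": {}, "gaps": []}
    for cohort in cohorts:
        freq = hotspot_frequencies(matrix, cohort)
        count, n, pct = either_hotspot_fraction(matrix, hotspot_genes, cohort)
        report["cohorts"][cohort] = {
            "n_samples": n,
            "gene_frequencies": freq.to_dict(orient="records"),
            "either_hotspot": {
                "count": count, "n": n,
                "percent_int": percent_nearest_int(pct),
                "percent_1dp": format_percent(pct, percent_mode),
            },
        }
    if burden_summary is not None:
        report["burden"] = burden_summary
    else:
        report["gaps"].append("burden")
    if exclusivity is not None:
        report["mutual_exclusivity"] = exclusivity.to_dict(orient="records")
    else:
        report["gaps"].append("mutual_exclusivity")
    if chromothripsis is not None:
        report["chromothripsis"] = [
            {
                "sample_id": c.sample_id, "chrom": c.chrom,
                "switch_count": c.switch_count, "tier": c.tier,
                "canonicity": c.canonicity, "n_states": c.n_states,
            }
            for c in chromothripsis
        ]
    else:
        report["gaps"].append("chromothripsis")
    if two_hits is not None:
        report["two_hit"] = [
            {"sample_id": t.sample_id, "gene": t.gene, "evidence": t.evidence}
            for t in two_hits
        ]
    else:
        report["gaps"].append("two_hit")
    return report


def write_report(outdir: str | Path, report: dict, matrix: CohortAlterationMatrix) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(outdir / "alteration_matrix.tsv", sep="\t")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_alteration_matrix(matrix: CohortAlterationMatrix, path: str | Path) -> None:
    """Basic oncoplot-style rendering of the binary matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = matrix.data.sum(axis=1).sort_values(ascending=False).index
    data = matrix.data.loc[order].T
    fig, ax = plt.subplots(figsize=(max(6, 0.18 * len(order)), max(2, 0.4 * len(matrix.genes))))
    ax.imshow(data.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_yticks(range(len(matrix.genes)), data.index)
    ax.set_xticks([])
    ax.set_xlabel("samples")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
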