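"""Two-group characterization of MRDS vs MRDIS genes.

Feature comparisons (motif length and composition, DNA-binding-domain counts
and sizes, activator/repressor proportions, expression profiles, CDS length,
dN/dS, PPI degree) use Mann-Whitney U tests for continuous features and the
same chi-square/Fisher switch as the enrichment module for proportions.
Each comparison drops genes missing the needed field and reports the
effective sample sizes, so denominators vary by feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import EXPRESSION_LEVELS, Motif, as_frame
from .classifier import MRDIS, MRDS, DosageLabel
from .enrichment import ContingencyTable, fisher_exact, pearson_chi2

BASES = "ACGT"

#: feature names accepted by :func:`compare_feature`
FEATURE_NAMES = (
    "cds_length",
    "dn",
    "ds",
    "dnds",
    "ppi_degree",
    "ppi_tf_fraction",
    "mrna_level",
    "dbd_size",
)


@dataclass(frozen=True)
class MotifStats:
    """Length and mean base composition of one binding-site motif."""

    length: int
    base_fraction: dict[str, float]


@dataclass
class ComparisonResult:
    """A two-group feature comparison (group a = MRDS, group b = MRDIS)."""

    feature: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p: float


@dataclass
class ExpressionSummary:
    """Per-group mean number of samples at each expression level."""

    n_genes: int
    mean_counts: dict[str, float]  # level -> mean sample count


def motif_stats(motif: Motif) -> MotifStats:
    """Length and composition of a motif.

    Composition is the mean of the per-position probability columns, which is
    well-defined for every position frequency matrix (including fully
    degenerate positions) and sums to 1 by column normalisation.
    """
    fractions = motif.matrix.mean(axis=0)
    return MotifStats(
        length=motif.length,
        base_fraction={b: float(f) for b, f in zip(BASES, fractions)},
    )


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    The exact null distribution is used when the samples are tie-free and
    n_a * n_b <= 400; otherwise the normal approximation with tie and
    continuity corrections.  Degenerate input (all pooled values identical)
    yields U = n_a * n_b / 2 and p = 1.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and a.size * b.size <= 400:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def proportion_compare(
    k_a: int, n_a: int, k_b: int, n_b: int
) -> tuple[float, float, float | None, float]:
    """Compare two proportions; returns (percent_a, percent_b, statistic, p).

    The 2x2 test follows the expected <= 5 switch applied to the expected
    in-group-a-positive cell; the statistic is None for Fisher tests.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("positive counts must lie within group sizes")
    percent_a = 100.0 * k_a / n_a
    percent_b = 100.0 * k_b / n_b
    table = ContingencyTable(a=k_a, b=n_a - k_a, c=k_b, d=n_b - k_b)
    expected_a = n_a * (k_a + k_b) / (n_a + n_b)
    if expected_a > 5:
        statistic, p = pearson_chi2(table)
    else:
        statistic, p = None, fisher_exact(table)
    return percent_a, percent_b, statistic, p


# ---------------------------------------------------------------------------
# catalog-level comparisons
# ---------------------------------------------------------------------------

def _feature_values(frame: pd.DataFrame, feature: str) -> pd.Series:
    """Per-gene feature values; NaN where the feature is missing/undefined."""
    if feature == "dnds":
        dn = pd.to_numeric(frame["dn"], errors="coerce")
        ds = pd.to_numeric(frame["ds"], errors="coerce")
        values = dn / ds
        values[~(ds > 0)] = np.nan  # dN/dS undefined when dS = 0 or missing
        return values
    if feature == "dbd_size":
        # mean DBD size per protein when several domains are annotated
        return frame["dbd_sizes"].map(
            lambda v: float(np.mean(v)) if isinstance(v, (list, tuple)) and v else np.nan
        )
    if feature not in frame.columns:
        raise ValueError(f"unknown feature {feature!r}")
    return pd.to_numeric(frame[feature], errors="coerce")


def _split_by_label(frame: pd.DataFrame, labels: Iterable[DosageLabel], tf_only: bool):
    label_map = {l.gene_id: l.label for l in labels}
    lab = frame["gene_id"].map(label_map)
    mask_a = (lab == MRDS).to_numpy()
    mask_b = (lab == MRDIS).to_numpy()
    if tf_only:
        is_tf = frame["is_tf"].astype(bool).to_numpy()
        mask_a &= is_tf
        mask_b &= is_tf
    return mask_a, mask_b


def compare_feature(
    catalog,
    labels: Iterable[DosageLabel],
    feature: str,
    restrict: str = "all_genes",
) -> ComparisonResult:
    """Compare one numeric feature between the MRDS and MRDIS classes.

    ``restrict`` is ``"all_genes"`` or ``"tf_only"``.  Genes missing the
    feature are dropped; if either class empties, a ValueError names the
    feature.  SDs are sample standard deviations (ddof = 1, 0 for n = 1).
    """
    if restrict not in ("all_genes", "tf_only"):
        raise ValueError(f"restrict must be all_genes or tf_only, got {restrict!r}")
    frame = as_frame(catalog)
    labels = list(labels)
    values = _feature_values(frame, feature).to_numpy(dtype=float)
    mask_a, mask_b = _split_by_label(frame, labels, restrict == "tf_only")
    a = values[mask_a & ~np.isnan(values)]
    b = values[mask_b & ~np.isnan(values)]
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"feature {feature!r}: a class has no genes with this feature"
            f" (MRDS n={a.size}, MRDIS n={b.size})"
        )
    u, p = mann_whitney(a, b)
    return ComparisonResult(
        feature=feature,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        u_statistic=u,
        p=p,
    )


def compare_motifs(
    motif_list: Iterable[Motif], labels: Iterable[DosageLabel]
) -> list[ComparisonResult]:
    """Compare motif length and mean base fractions between classes.

    One motif per TF is assumed; motifs whose TF is not labelled MRDS or
    MRDIS are ignored.  Returns five comparisons: length then A, C, G, T
    percentage (per-motif fractions x 100, averaged across TFs).
    """
    label_map = {l.gene_id: l.label for l in labels}
    per_class: dict[str, list[MotifStats]] = {MRDS: [], MRDIS: []}
    for motif in motif_list:
        lab = label_map.get(motif.tf_gene_id)
        if lab in per_class:
            per_class[lab].append(motif_stats(motif))
    if not per_class[MRDS] or not per_class[MRDIS]:
        raise ValueError("each class needs at least one motif")
    out = []
    a_stats, b_stats = per_class[MRDS], per_class[MRDIS]
    length_a = [s.length for s in a_stats]
    length_b = [s.length for s in b_stats]
    u, p = mann_whitney(length_a, length_b)
    out.append(
        ComparisonResult(
            "motif_length",
            len(length_a), len(length_b),
            float(np.mean(length_a)), float(np.std(length_a, ddof=1)),
            float(np.mean(length_b)), float(np.std(length_b, ddof=1)),
            u, p,
        )
    )
    for base in BASES:
        frac_a = [100.0 * s.base_fraction[base] for s in a_stats]
        frac_b = [100.0 * s.base_fraction[base] for s in b_stats]
        u, p = mann_whitney(frac_a, frac_b)
        out.append(
            ComparisonResult(
                f"motif_{base}_percent",
                len(frac_a), len(frac_b),
                float(np.mean(frac_a)), float(np.std(frac_a, ddof=1)),
                float(np.mean(frac_b)), float(np.std(frac_b, ddof=1)),
                u, p,
            )
        )
    return out


def expression_counts(levels: dict[str, str], samples: list[str]) -> dict[str, int] | None:
    """Count samples per expression level; None if any sample is unprofiled."""
    counts = {level: 0 for level in EXPRESSION_LEVELS}
    for sample in samples:
        level = levels.get(sample) if levels else None
        if level is None:
            return None
        counts[level] += 1
    return counts


def summarize_expression(
    catalog,
    labels: Iterable[DosageLabel],
    samples: list[str],
    tf_only: bool = False,
) -> tuple[dict[str, ExpressionSummary], list[ComparisonResult]]:
    """Per-class protein-expression profiles over a fixed sample panel.

    Only genes profiled in *every* listed sample are kept, so each gene's
    four level counts sum to ``len(samples)``.  Returns the per-class mean
    counts and one Mann-Whitney comparison per level category.
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    frame = as_frame(catalog)
    labels = list(labels)
    mask_a, mask_b = _split_by_label(frame, labels, tf_only)

    counts: dict[str, list[dict[str, int]]] = {MRDS: [], MRDIS: []}
    for idx, levels in enumerate(frame["expression_levels"]):
        if not (mask_a[idx] or mask_b[idx]):
            continue
        if not isinstance(levels, dict):
            continue
        gene_counts = expression_counts(levels, samples)
        if gene_counts is None:
            continue
        counts[MRDS if mask_a[idx] else MRDIS].append(gene_counts)

    if not counts[MRDS] or not counts[MRDIS]:
        raise ValueError("a class has no gene profiled in all listed samples")

    summaries = {}
    for cls, rows in counts.items():
        summaries[cls] = ExpressionSummary(
            n_genes=len(rows),
            mean_counts={
                level: float(np.mean([r[level] for r in rows]))
                for level in EXPRESSION_LEVELS
            },
        )
    comparisons = []
    for level in EXPRESSION_LEVELS:
        a = [r[level] for r in counts[MRDS]]
        b = [r[level] for r in counts[MRDIS]]
        u, p = mann_whitney(a, b)
        comparisons.append(
            ComparisonResult(
                f"expression_{level}",
                len(a), len(b),
                float(np.mean(a)), float(np.std(a, ddof=1)) if len(a) > 1 else 0.0,
                float(np.mean(b)), float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
                u, p,
            )
        )
    return summaries, comparisons
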