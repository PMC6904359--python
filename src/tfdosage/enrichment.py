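"""Family-by-class 2x2 enrichment with FDR control.

Each TF family (plus the pooled small-family categories and the all-TF group)
is crossed against a target gene set (e.g. the MRDS class) in a 2x2 table.
The expected in-family-in-set count under independence,

    expected = n_family * n_set / n_universe,

selects the test: Pearson chi-square (df = 1) when expected > 5, Fisher's
exact test when expected <= 5.  Benjamini-Hochberg adjustment is applied
across all family tests against one target set (one target set = one
adjustment family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tfdosage")

#: pooled small-family category cutoffs (families with <= k members)
DEFAULT_SMALL_FAMILY_CUTOFFS = (5, 7, 9, 11)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = in-group & in-set, b = in-group & out, c, d accordingly."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected_cells(self) -> np.ndarray:
        n = self.n
        rows = np.array([self.a + self.b, self.c + self.d], dtype=float)
        cols = np.array([self.a + self.c, self.b + self.d], dtype=float)
        return np.outer(rows, cols) / n


@dataclass
class EnrichmentResult:
    group_name: str
    n_group: int
    observed: int
    expected: float
    statistic: float | None  # chi-square statistic; None for Fisher tests
    test_used: str  # "chi_square" | "fisher_exact"
    p: float
    p_adj: float
    direction: str  # "over" | "under" | "none"


def expected_count(n_group: int, n_set: int, n_universe: int) -> float:
    """Expected in-group-in-set count under independence."""
    if n_universe <= 0:
        raise ValueError("universe size must be positive")
    if not (0 <= n_group <= n_universe and 0 <= n_set <= n_universe):
        raise ValueError("group and set sizes must lie within the universe")
    return n_group * n_set / n_universe


def pearson_chi2(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test (df = 1) on a 2x2 table.

    With ``yates`` the continuity correction reduces |ad - bc| by N/2
    (floored at zero) before squaring.  Any zero expected cell is an error:
    use :func:`fisher_exact` for such tables.
    """
    expected = table.expected_cells()
    if (expected == 0).any():
        raise ValueError(
            "zero expected cell; chi-square is undefined — use fisher_exact"
        )
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    statistic = n * diff * diff / denom
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the same
    margins whose point probability does not exceed the observed table's.
    """
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(p)


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adjusted]


def build_family_groups(catalog_frame, include_unknown: bool = True) -> dict[str, set[str]]:
    """Map each TF family name to its member gene-id set."""
    tf = catalog_frame[catalog_frame["is_tf"].astype(bool)]
    groups: dict[str, set[str]] = {}
    for family, sub in tf.groupby("tf_family"):
        if family is None:
            continue
        if not include_unknown and family == "Unknown":
            continue
        groups[str(family)] = set(sub["gene_id"])
    return groups


def small_family_groups(families: dict[str, set[str]], cutoffs=DEFAULT_SMALL_FAMILY_CUTOFFS) -> dict[str, set[str]]:
    """Pool families with <= k members into one category per cutoff k."""
    out: dict[str, set[str]] = {}
    for k in cutoffs:
        pooled: set[str] = set()
        for name, members in families.items():
            if len(members) <= k:
                pooled |= members
        out[f"<={k} members"] = pooled
    return out


def enrich_group_vs_set(
    group: set[str],
    target_set: set[str],
    n_universe: int,
    group_name: str = "",
    yates: bool = False,
) -> EnrichmentResult:
    """One 2x2 enrichment test of a gene group against a target set.

    The test is chosen by the expected in-group-in-set count: chi-square when
    it exceeds 5, Fisher's exact otherwise.  ``p_adj`` is initialised to the
    raw p; callers adjust across their own family of tests.
    """
    n_group = len(group)
    observed = len(group & target_set)
    expected = expected_count(n_group, len(target_set), n_universe)
    table = ContingencyTable(
        a=observed,
        b=n_group - observed,
        c=len(target_set) - observed,
        d=n_universe - n_group - len(target_set) + observed,
    )
    if expected > 5 and table.expected_cells().min() > 0:
        statistic, p = pearson_chi2(table, yates=yates)
        test_used = "chi_square"
    else:  # small expected count, or a degenerate margin (e.g. group = universe)
        statistic, p = None, fisher_exact(table)
        test_used = "fisher_exact"
    if observed > expected:
        direction = "over"
    elif observed < expected:
        direction = "under"
    else:
        direction = "none"
    return EnrichmentResult(
        group_name=group_name,
        n_group=n_group,
        observed=observed,
        expected=expected,
        statistic=statistic,
        test_used=test_used,
        p=p,
        p_adj=p,
        direction=direction,
    )


def run_enrichment(
    target_set: set[str],
    families: dict[str, set[str]],
    universe: set[str],
    small_family_cutoffs=DEFAULT_SMALL_FAMILY_CUTOFFS,
    all_tf_group: bool = True,
    yates: bool = False,
) -> list[EnrichmentResult]:
    """Test every family (plus pooled categories) against one target set.

    BH adjustment spans all tests produced by this call — one target set is
    one adjustment family.  Empty groups are skipped with a warning.
    """
    target_set = set(target_set) & set(universe)
    n_universe = len(universe)
    groups: list[tuple[str, set[str]]] = []
    for name in sorted(families):
        groups.append((name, families[name]))
    if small_family_cutoffs:
        for name, members in small_family_groups(families, small_family_cutoffs).items():
            groups.append((name, members))
    if all_tf_group:
        all_tf = set().union(*families.values()) if families else set()
        groups.append(("All TFs", all_tf))

    results = []
    for name, members in groups:
        if not members:
            logger.warning("skipping empty group %s", name)
            continue
        results.append(
            enrich_group_vs_set(members, target_set, n_universe, name, yates=yates)
        )
    adjusted = bh_adjust([r.p for r in results])
    for result, p_adj in zip(results, adjusted):
        result.p_adj = p_adj
    return results
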