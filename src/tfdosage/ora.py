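"""Hypergeometric over-representation analysis of a study set against GMT terms.

For each term with K annotated genes in an N-gene universe, a study set of n
genes overlapping the term in k genes gets the upper-tail probability
P(X >= k) with X ~ Hypergeom(N, K, n); BH adjustment spans all tested terms.
The default universe is the annotated universe (genes appearing in at least
one term), the common ORA convention; the full catalog can be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .enrichment import bh_adjust


@dataclass
class TermResult:
    term_id: str
    term_size: int
    overlap: int
    expected_overlap: float
    p: float
    p_adj: float

    @property
    def significant_at(self):
        return self.p_adj


def run_ora(
    study_set: set[str],
    terms: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    min_term_size: int = 10,
    max_term_size: int = 500,
    universe_mode: str = "annotated",
) -> list[TermResult]:
    """Test every annotation term for over-representation in the study set.

    Parameters
    ----------
    study_set, terms, universe
        Study gene ids, term -> member map, and the background gene ids.
        With ``universe_mode="annotated"`` the background is restricted to
        genes carried by at least one term; ``"catalog"`` uses ``universe``
        as given.  The study set is intersected with the background; term
        members outside the background are ignored.
    alpha
        Significance level applied to BH-adjusted p (recorded only; all
        results are returned, sorted by raw p).
    min_term_size, max_term_size
        Terms outside this size range (after background intersection) are
        not tested.
    """
    if not study_set:
        raise ValueError("study set is empty")
    if universe_mode not in ("annotated", "catalog"):
        raise ValueError(f"unknown universe_mode {universe_mode!r}")
    universe = set(universe)
    if universe_mode == "annotated":
        annotated = set()
        for members in terms.values():
            annotated |= members
        universe = universe & annotated
    study = set(study_set) & universe
    if not study:
        raise ValueError("study set does not intersect the background universe")
    n_universe = len(universe)
    n_study = len(study)

    results = []
    for term_id in sorted(terms):
        members = terms[term_id] & universe
        size = len(members)
        if size < min_term_size or size > max_term_size:
            continue
        overlap = len(members & study)
        expected = size * n_study / n_universe
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, size, n_study))
        results.append(
            TermResult(
                term_id=term_id,
                term_size=size,
                overlap=overlap,
                expected_overlap=expected,
                p=p,
                p_adj=p,
            )
        )
    adjusted = bh_adjust([r.p for r in results])
    for result, p_adj in zip(results, adjusted):
        result.p_adj = p_adj
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def significant_terms(results: list[TermResult], alpha: float = 0.05) -> list[TermResult]:
    """Terms with BH-adjusted p below ``alpha``."""
    return [r for r in results if r.p_adj < alpha]
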