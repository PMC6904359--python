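"""Consensus dosage-sensitivity classification.

A gene is called MRDS (most reliable dosage-sensitive) when all four
independent dosage-evidence sets contain it, and MRDIS (most reliable
dosage-insensitive) when none of the four contains it *and* both
haploinsufficiency scores (pLI and the HIPred probability) are at or below
the threshold (default 0.5).  Everything else — partial evidence, or absence
from all sets but an elevated or missing score — is UNCLASSIFIED.

A gene lacking either score cannot be cleared of haploinsufficiency, so it is
UNCLASSIFIED rather than MRDIS.  The threshold is a strictly-greater
exclusion: a score exactly at the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import EvidenceSets, as_frame

MRDS = "MRDS"
MRDIS = "MRDIS"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class DosageLabel:
    """The consensus call for one gene."""

    gene_id: str
    label: str  # MRDS | MRDIS | UNCLASSIFIED
    n_evidence_sets: int  # 0..4


@dataclass
class VennPartition:
    """Counts of the 16 membership regions of the four evidence sets.

    Keys are 4-character bit strings in the order (conserved_cnv, ohnolog,
    hi_exac, hi_hipred); ``"1111"`` is the MRDS region and ``"0000"`` the
    all-absent region.
    """

    region_counts: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.region_counts.values())


def classify(catalog, evidence: EvidenceSets, score_threshold: float = 0.5) -> list[DosageLabel]:
    """Assign every catalog gene exactly one of MRDS / MRDIS / UNCLASSIFIED.

    Parameters
    ----------
    catalog : list of GeneRecord or DataFrame
        The gene universe; must carry ``pli`` and ``hipred`` columns.
    evidence : EvidenceSets
        The four dosage-evidence sets, already reconciled to the universe.
    score_threshold : float in [0, 1]
        Genes in no evidence set qualify as MRDIS only if both scores are
        <= this value (scores strictly above it are excluded).
    """
    if not (0.0 <= score_threshold <= 1.0):
        raise ValueError(f"score_threshold {score_threshold} outside [0, 1]")
    frame = as_frame(catalog)

    gene_ids = frame["gene_id"].to_numpy()
    n_sets = np.zeros(len(frame), dtype=int)
    for name in EvidenceSets.EVIDENCE_NAMES:
        members = getattr(evidence, name)
        n_sets += frame["gene_id"].isin(members).to_numpy()

    pli = pd.to_numeric(frame["pli"], errors="coerce").to_numpy(dtype=float)
    hipred = pd.to_numeric(frame["hipred"], errors="coerce").to_numpy(dtype=float)
    scores_ok = (
        ~np.isnan(pli) & ~np.isnan(hipred)
        & (pli <= score_threshold) & (hipred <= score_threshold)
    )

    labels = np.full(len(frame), UNCLASSIFIED, dtype=object)
    labels[n_sets == 4] = MRDS
    labels[(n_sets == 0) & scores_ok] = MRDIS

    return [
        DosageLabel(gene_id=g, label=l, n_evidence_sets=int(k))
        for g, l, k in zip(gene_ids, labels, n_sets)
    ]


def label_sets(labels: Iterable[DosageLabel]) -> tuple[set[str], set[str]]:
    """Return the (MRDS, MRDIS) gene-id sets from a label list."""
    mrds = {l.gene_id for l in labels if l.label == MRDS}
    mrdis = {l.gene_id for l in labels if l.label == MRDIS}
    return mrds, mrdis


def venn_partition(evidence: EvidenceSets) -> VennPartition:
    """Partition the universe by the 4-bit evidence-membership signature."""
    counts = {f"{i:04b}": 0 for i in range(16)}
    sets = [getattr(evidence, n) for n in EvidenceSets.EVIDENCE_NAMES]
    for gene_id in evidence.universe:
        signature = "".join("1" if gene_id in s else "0" for s in sets)
        counts[signature] += 1
    return VennPartition(region_counts=counts)


def labels_to_frame(labels: Iterable[DosageLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.gene_id, l.label, l.n_evidence_sets) for l in labels],
        columns=["gene_id", "label", "n_evidence_sets"],
    )


def labels_from_frame(frame: pd.DataFrame) -> list[DosageLabel]:
    return [
        DosageLabel(str(r.gene_id), str(r.label), int(r.n_evidence_sets))
        for r in frame.itertuples(index=False)
    ]
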