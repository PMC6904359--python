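"""Gene catalog data model and readers/writers for the pipeline's file formats.

The in-memory universe is a list of :class:`GeneRecord` (one per gene); all
analysis stages also accept the equivalent :class:`pandas.DataFrame` produced
by :func:`records_to_frame`.  External formats are deliberately plain text:

* gene catalog — TSV with the canonical header (:data:`CATALOG_COLUMNS`);
* gene sets — one identifier per line, ``#`` comments allowed;
* motifs — JASPAR-style position frequency matrices (count matrices, one
  4-row block per motif, normalised per column on read);
* annotation terms — GMT (term, description, member ids, tab-separated).

Identifiers are opaque strings; no accession resolution is attempted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

logger = logging.getLogger("tfdosage")

EXPRESSION_LEVELS = ("high", "medium", "low", "not_detected")

#: Canonical column order of the gene-catalog TSV.
CATALOG_COLUMNS = (
    "gene_id",
    "symbol",
    "is_tf",
    "tf_family",
    "is_kzfp",
    "cds_length",
    "dn",
    "ds",
    "pli",
    "hipred",
    "pnull",
    "ppi_degree",
    "ppi_tf_fraction",
    "mrna_level",
    "expression_levels",
    "dbd_sizes",
    "has_activation_domain",
    "has_repressor_domain",
)

_SCORE_FIELDS = ("pli", "hipred", "pnull", "ppi_tf_fraction")


class CatalogError(ValueError):
    """Raised when a catalog file or record violates the data model."""


@dataclass
class GeneRecord:
    """Annotations, scores and features of a single gene.

    Optional fields are ``None`` when the underlying datum is unknown;
    downstream comparisons drop genes missing the field they need and
    report the effective sample size.
    """

    gene_id: str
    symbol: str | None = None
    is_tf: bool = False
    tf_family: str | None = None
    is_kzfp: bool = False
    cds_length: int | None = None
    dn: float | None = None
    ds: float | None = None
    pli: float | None = None
    hipred: float | None = None
    pnull: float | None = None
    ppi_degree: int | None = None
    ppi_tf_fraction: float | None = None
    mrna_level: float | None = None
    expression_levels: dict[str, str] | None = None
    dbd_sizes: list[int] | None = None
    has_activation_domain: bool = False
    has_repressor_domain: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise CatalogError("gene_id must be a non-empty string")
        if self.is_kzfp and not self.is_tf:
            raise CatalogError(f"{self.gene_id}: is_kzfp implies is_tf")
        if self.is_tf and not self.tf_family:
            raise CatalogError(
                f"{self.gene_id}: a TF must carry a family (use 'Unknown')"
            )
        if not self.is_tf and self.tf_family:
            raise CatalogError(f"{self.gene_id}: tf_family set on a non-TF")
        if self.cds_length is not None:
            if self.cds_length <= 0 or self.cds_length % 3 != 0:
                raise CatalogError(
                    f"{self.gene_id}: cds_length must be a positive multiple of 3,"
                    f" got {self.cds_length}"
                )
        for name in _SCORE_FIELDS:
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise CatalogError(
                    f"{self.gene_id}: {name}={value} outside [0, 1]"
                )
        for name in ("dn", "ds"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise CatalogError(f"{self.gene_id}: {name} must be non-negative")
        if self.ppi_degree is not None and self.ppi_degree < 0:
            raise CatalogError(f"{self.gene_id}: ppi_degree must be non-negative")
        if self.dbd_sizes is not None:
            if any(s <= 0 for s in self.dbd_sizes):
                raise CatalogError(f"{self.gene_id}: dbd_sizes must be positive")
        if self.expression_levels is not None:
            for sample, level in self.expression_levels.items():
                if level not in EXPRESSION_LEVELS:
                    raise CatalogError(
                        f"{self.gene_id}: unknown expression level {level!r}"
                        f" for sample {sample!r}"
                    )


@dataclass
class EvidenceSets:
    """The four dosage-evidence gene sets plus the two HLOF-tolerant sets.

    Every set is stored reconciled against the universe (the gene catalog);
    identifiers absent from the universe are either dropped with a logged
    count or, with ``strict=True`` at construction, rejected.
    """

    universe: set[str]
    conserved_cnv: set[str] = field(default_factory=set)
    ohnolog: set[str] = field(default_factory=set)
    hi_exac: set[str] = field(default_factory=set)
    hi_hipred: set[str] = field(default_factory=set)
    hlof_pnull: set[str] = field(default_factory=set)
    hlof_consang: set[str] = field(default_factory=set)

    #: names of the four dosage-evidence sets, in Venn-signature order
    EVIDENCE_NAMES = ("conserved_cnv", "ohnolog", "hi_exac", "hi_hipred")
    HLOF_NAMES = ("hlof_pnull", "hlof_consang")

    def __post_init__(self) -> None:
        for name in self.EVIDENCE_NAMES + self.HLOF_NAMES:
            extra = getattr(self, name) - self.universe
            if extra:
                raise CatalogError(
                    f"evidence set {name!r} contains {len(extra)} ids outside"
                    f" the universe (e.g. {sorted(extra)[:3]})"
                )

    @classmethod
    def from_sets(cls, universe, strict=False, **sets) -> "EvidenceSets":
        """Build evidence sets reconciled against ``universe``.

        Unknown set names are rejected.  Ids not in the universe are dropped
        (with a logged count) unless ``strict`` is true.
        """
        universe = set(universe)
        clean: dict[str, set[str]] = {}
        for name, ids in sets.items():
            if name not in cls.EVIDENCE_NAMES + cls.HLOF_NAMES:
                raise CatalogError(f"unknown evidence-set name {name!r}")
            ids = set(ids)
            extra = ids - universe
            if extra:
                if strict:
                    raise CatalogError(
                        f"evidence set {name!r}: {len(extra)} ids not in universe"
                    )
                logger.warning(
                    "evidence set %s: dropping %d ids not in the universe",
                    name, len(extra),
                )
            clean[name] = ids & universe
        return cls(universe=universe, **clean)

    def evidence_membership(self, gene_id: str) -> tuple[bool, bool, bool, bool]:
        return tuple(gene_id in getattr(self, n) for n in self.EVIDENCE_NAMES)


@dataclass
class Motif:
    """A position probability matrix over {A, C, G, T} for one TF."""

    tf_gene_id: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or len(self.matrix) < 1:
            raise CatalogError(
                f"motif {self.tf_gene_id}: matrix must be L x 4 with L >= 1"
            )
        if (self.matrix < 0).any():
            raise CatalogError(f"motif {self.tf_gene_id}: negative probability")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise CatalogError(
                f"motif {self.tf_gene_id}: position probabilities do not sum to 1"
            )

    @property
    def length(self) -> int:
        return len(self.matrix)


# ---------------------------------------------------------------------------
# gene-catalog TSV
# ---------------------------------------------------------------------------

def _fmt_real(x: float) -> str:
    # canonical 4-significant-digit formatting
    if x == 0:
        return "0"
    return f"{x:.4g}"


def _format_field(name: str, value) -> str:
    if value is None:
        return ""
    if name in ("is_tf", "is_kzfp", "has_activation_domain", "has_repressor_domain"):
        return "1" if value else "0"
    if name in ("cds_length", "ppi_degree"):
        return str(int(value))
    if name == "expression_levels":
        return ",".join(f"{s}:{lv}" for s, lv in sorted(value.items()))
    if name == "dbd_sizes":
        return ",".join(str(int(s)) for s in value)
    if isinstance(value, float):
        return _fmt_real(value)
    return str(value)


def _parse_field(name: str, text: str, line_no: int):
    if text == "":
        return None
    try:
        if name in ("is_tf", "is_kzfp", "has_activation_domain", "has_repressor_domain"):
            if text not in ("0", "1", "true", "false", "True", "False"):
                raise ValueError(f"bad boolean {text!r}")
            return text in ("1", "true", "True")
        if name in ("cds_length", "ppi_degree"):
            return int(text)
        if name == "expression_levels":
            out = {}
            for item in text.split(","):
                sample, _, level = item.partition(":")
                if not level:
                    raise ValueError(f"bad expression entry {item!r}")
                out[sample] = level
            return out
        if name == "dbd_sizes":
            return [int(s) for s in text.split(",")]
        if name in ("dn", "ds", "pli", "hipred", "pnull", "ppi_tf_fraction", "mrna_level"):
            return float(text)
        return text
    except ValueError as exc:
        raise CatalogError(f"line {line_no}: field {name!r}: {exc}") from exc


def read_gene_table(path, dialect: dict[str, str] | None = None) -> list[GeneRecord]:
    """Read a tab-separated gene catalog into validated records.

    Parameters
    ----------
    path : str or file-like
        TSV with a header row; a ``gene_id`` column is required.
    dialect : dict, optional
        Maps file column names to canonical field names, for catalogs whose
        headers differ from :data:`CATALOG_COLUMNS`.

    Duplicate gene ids and malformed rows raise :class:`CatalogError` naming
    the offending id or line.  Fields absent from the file stay absent in the
    records — parsing never invents values.
    """
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "rt", encoding="utf-8")
        close = True
    try:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            raise CatalogError("empty catalog file: missing header")
        columns = header_line.split("\t")
        if dialect:
            columns = [dialect.get(c, c) for c in columns]
        known = set(CATALOG_COLUMNS)
        unknown = [c for c in columns if c not in known]
        if unknown:
            raise CatalogError(f"unknown catalog columns: {unknown}")
        if "gene_id" not in columns:
            raise CatalogError("catalog is missing the gene_id column")
        records: list[GeneRecord] = []
        seen: set[str] = set()
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise CatalogError(
                    f"line {line_no}: expected {len(columns)} fields,"
                    f" got {len(cells)}"
                )
            kwargs = {}
            for name, text in zip(columns, cells):
                value = _parse_field(name, text, line_no)
                if value is not None:
                    kwargs[name] = value
            try:
                record = GeneRecord(**kwargs)
            except CatalogError as exc:
                raise CatalogError(f"line {line_no}: {exc}") from exc
            if record.gene_id in seen:
                raise CatalogError(f"duplicate gene_id {record.gene_id!r}")
            seen.add(record.gene_id)
            records.append(record)
        return records
    finally:
        if close:
            handle.close()


def write_gene_table(records: list[GeneRecord], path) -> None:
    """Write records as canonical TSV (fixed column order, 4-sig-digit reals)."""
    buf = io.StringIO()
    buf.write("\t".join(CATALOG_COLUMNS) + "\n")
    for record in records:
        cells = [_format_field(c, getattr(record, c)) for c in CATALOG_COLUMNS]
        buf.write("\t".join(cells) + "\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "wt", encoding="utf-8", newline="") as handle:
            handle.write(text)


def records_to_frame(records: list[GeneRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame (one row per gene, canonical columns)."""
    rows = []
    for record in records:
        row = {c: getattr(record, c) for c in CATALOG_COLUMNS}
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[GeneRecord]:
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for name in CATALOG_COLUMNS:
            value = getattr(row, name)
            if value is None or (np.isscalar(value) and pd.isna(value)):
                continue
            kwargs[name] = value
        records.append(GeneRecord(**kwargs))
    return records


def as_frame(catalog) -> pd.DataFrame:
    """Coerce a catalog (records or DataFrame) to the canonical DataFrame."""
    if isinstance(catalog, pd.DataFrame):
        return catalog
    return records_to_frame(catalog)


# ---------------------------------------------------------------------------
# gene sets, motifs, GMT
# ---------------------------------------------------------------------------

def read_gene_set(path) -> set[str]:
    """Read a one-id-per-line gene set; ``#`` comments and blanks ignored.

    An empty result logs a warning rather than raising — an empty gene set
    is legal input (it just makes every overlap zero).
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    out: set[str] = set()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.add(line)
    if not out:
        logger.warning("gene set %s is empty", getattr(path, "name", path))
    return out


def write_gene_set(ids, path) -> None:
    text = "\n".join(sorted(ids)) + ("\n" if ids else "")
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "wt", encoding="utf-8", newline="") as handle:
            handle.write(text)


def read_motifs(path) -> list[Motif]:
    """Read JASPAR-style PFMs and normalise counts to probabilities.

    Count columns are normalised position-wise; a position whose four counts
    sum to zero is rejected.  The motif name (the text after ``>``) is taken
    as the TF gene id.
    """
    close = False
    if hasattr(path, "read"):
        handle = path
    else:
        handle = open(path, "rt", encoding="utf-8")
        close = True
    try:
        try:
            parsed = bio_motifs.parse(handle, "jaspar")
        except Exception as exc:  # Bio raises bare ValueError on bad numbers
            raise CatalogError(f"cannot parse motif file: {exc}") from exc
        out = []
        for motif in parsed:
            name = motif.name or motif.matrix_id
            counts = np.array(
                [motif.counts[base] for base in "ACGT"], dtype=float
            ).T  # (L, 4)
            if (counts < 0).any():
                raise CatalogError(f"motif {name}: negative count")
            sums = counts.sum(axis=1)
            if (sums == 0).any():
                raise CatalogError(f"motif {name}: zero-count column")
            out.append(Motif(tf_gene_id=str(name), matrix=counts / sums[:, None]))
        return out
    finally:
        if close:
            handle.close()


def write_motifs(motif_list: list[Motif], path, counts_scale: int = 100) -> None:
    """Write motifs in the JASPAR PFM dialect (integer-ish count rows)."""
    buf = io.StringIO()
    for motif in motif_list:
        buf.write(f">{motif.tf_gene_id}\n")
        scaled = motif.matrix * counts_scale
        for j, base in enumerate("ACGT"):
            row = " ".join(_fmt_real(v) for v in scaled[:, j])
            buf.write(f"{base} [ {row} ]\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "wt", encoding="utf-8", newline="") as handle:
            handle.write(text)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT annotation file: term -> set of member gene ids."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path, "rt", encoding="utf-8") as handle:
            lines = handle.read().splitlines()
    terms: dict[str, set[str]] = {}
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise CatalogError(
                f"line {line_no}: GMT rows need term, description and >= 1 member"
            )
        term = cells[0]
        if term in terms:
            raise CatalogError(f"line {line_no}: duplicate term {term!r}")
        terms[term] = {c for c in cells[2:] if c}
    return terms


def write_gmt(terms: dict[str, set[str]], path, descriptions=None) -> None:
    buf = io.StringIO()
    for term in terms:
        desc = (descriptions or {}).get(term, "na")
        members = "\t".join(sorted(terms[term]))
        buf.write(f"{term}\t{desc}\t{members}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "wt", encoding="utf-8", newline="") as handle:
            handle.write(text)
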