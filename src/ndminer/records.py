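"""Publication records and corpus I/O.

Reads PubMed XML (``PubmedArticleSet``) and flat CSV/JSON record tables,
writes gene-specific publication profiles (GSPPs) as CSV, and builds
per-gene Entrez query strings.  Each record carries the five fields the
pipeline mines: PMID, title, abstract, year and journal name.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

from .errors import CorpusParseError, DuplicatePmidError, RecordValidationError, SchemaError

__all__ = [
    "PublicationRecord",
    "Corpus",
    "GSPP_COLUMNS",
    "read_pubmed_xml",
    "read_records_table",
    "write_records_csv",
    "write_gspp_csv",
    "build_gene_query",
    "fetch_pubmed_corpus",
]

logger = logging.getLogger(__name__)

#: Bit-exact column order of GSPP CSV files.
GSPP_COLUMNS = ("pmid", "year", "title", "abstract", "journal")

_MEDLINE_YEAR_RE = re.compile(r"^\s*(\d{4})")


def _current_year() -> int:
    return datetime.date.today().year


@dataclass(frozen=True)
class PublicationRecord:
    """One publication: pmid, title, abstract, year, journal.

    ``year == 0`` marks a record whose publication date could not be
    determined; such records are kept in profiles but excluded from the
    yearly trend.
    """

    pmid: str
    title: str
    abstract: str = ""
    year: int = 0
    journal: str = ""

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise RecordValidationError(f"pmid must be a non-empty digit string, got {self.pmid!r}")
        if not self.title:
            raise RecordValidationError(f"record {self.pmid}: title must be non-empty")
        if self.year != 0 and not (1800 <= self.year <= _current_year() + 1):
            raise RecordValidationError(
                f"record {self.pmid}: year {self.year} outside [1800, {_current_year() + 1}]"
            )

    @property
    def text(self) -> str:
        """Title and abstract joined at a token boundary."""
        return f"{self.title} {self.abstract}" if self.abstract else self.title


class Corpus:
    """An ordered, pmid-unique collection of publication records."""

    def __init__(self, records: Iterable[PublicationRecord] = ()) -> None:
        self._records: list[PublicationRecord] = []
        self._index: dict[str, int] = {}
        for rec in records:
            if rec.pmid in self._index:
                raise DuplicatePmidError(f"duplicate pmid {rec.pmid!r} in corpus")
            self._index[rec.pmid] = len(self._records)
            self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> PublicationRecord:
        return self._records[i]

    def __contains__(self, pmid: object) -> bool:
        return pmid in self._index

    def get(self, pmid: str) -> PublicationRecord:
        return self._records[self._index[pmid]]

    @property
    def records(self) -> tuple[PublicationRecord, ...]:
        return tuple(self._records)

    @property
    def pmids(self) -> tuple[str, ...]:
        return tuple(r.pmid for r in self._records)


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------


def _node_text(node: etree._Element | None) -> str:
    if node is None:
        return ""
    return "".join(node.itertext()).strip()


def _byte_offset(path: Path, line: int, column: int) -> int:
    """Byte offset of (1-based line, 1-based column) in a file."""
    try:
        data = path.read_bytes()
    except OSError:
        return -1
    offset = 0
    for _ in range(line - 1):
        nl = data.find(b"\n", offset)
        if nl < 0:
            break
        offset = nl + 1
    return offset + max(column - 1, 0)


def read_pubmed_xml(path: str | Path) -> Corpus:
    """Parse a ``PubmedArticleSet`` XML file into a :class:`Corpus`.

    The abstract is the concatenation of all ``AbstractText`` blocks in
    document order, joined by single spaces (structured-abstract labels are
    not re-inserted).  The year comes from ``PubDate/Year``, falling back to
    the leading four digits of ``MedlineDate``, else 0.  Articles without a
    PMID or title are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        line, column = exc.position
        raise CorpusParseError(
            f"{path}: malformed XML at byte offset {_byte_offset(path, line, column)} "
            f"(line {line}, column {column}): {exc.msg}"
        ) from exc
    records: list[PublicationRecord] = []
    for article in tree.getroot().iter("PubmedArticle"):
        pmid = _node_text(article.find(".//MedlineCitation/PMID"))
        if not pmid:
            logger.warning("skipping PubmedArticle without PMID in %s", path)
            continue
        title = _node_text(article.find(".//Article/ArticleTitle"))
        if not title:
            logger.warning("skipping PMID %s: no title", pmid)
            continue
        abstract = " ".join(
            t for t in (_node_text(n) for n in article.findall(".//Abstract/AbstractText")) if t
        )
        journal = _node_text(article.find(".//Article/Journal/Title"))
        pubdate = article.find(".//Article/Journal/JournalIssue/PubDate")
        year = 0
        if pubdate is not None:
            year_text = _node_text(pubdate.find("Year"))
            if year_text.isdigit():
                year = int(year_text)
            else:
                m = _MEDLINE_YEAR_RE.match(_node_text(pubdate.find("MedlineDate")))
                if m:
                    year = int(m.group(1))
        records.append(
            PublicationRecord(pmid=pmid, title=title, abstract=abstract, year=year, journal=journal)
        )
    return Corpus(records)


# ---------------------------------------------------------------------------
# Flat record tables (CSV / JSON)
# ---------------------------------------------------------------------------


def _coerce_year(value: object, pmid: str) -> int:
    if value is None:
        return 0
    text = str(value).strip()
    if not text:
        return 0
    try:
        return int(float(text))
    except ValueError:
        raise RecordValidationError(f"record {pmid}: unparseable year {value!r}") from None


def _records_from_dicts(rows: Iterable[dict], source: str) -> Corpus:
    required = set(GSPP_COLUMNS)
    records = []
    for i, row in enumerate(rows):
        missing = required - set(row)
        if missing:
            raise SchemaError(f"{source}: row {i} missing keys: {', '.join(sorted(missing))}")
        pmid = str(row["pmid"]).strip()
        records.append(
            PublicationRecord(
                pmid=pmid,
                title=str(row["title"]),
                abstract=str(row["abstract"]) if row["abstract"] is not None else "",
                year=_coerce_year(row["year"], pmid),
                journal=str(row["journal"]) if row["journal"] is not None else "",
            )
        )
    return Corpus(records)


def read_records_table(path: str | Path, dialect: str | None = None) -> Corpus:
    """Load a flat record table (CSV or JSON list) into a :class:`Corpus`.

    ``dialect`` is ``"csv"`` or ``"json"``; when omitted it is inferred from
    the file suffix.  Required columns/keys: pmid, title, abstract, year,
    journal.  Duplicate pmids raise :class:`DuplicatePmidError`.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        if not isinstance(doc, list):
            raise SchemaError(f"{path}: expected a JSON list of records")
        return _records_from_dicts(doc, str(path))
    if dialect == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty CSV file")
            missing = set(GSPP_COLUMNS) - set(reader.fieldnames)
            if missing:
                raise SchemaError(f"{path}: missing columns: {', '.join(sorted(missing))}")
            return _records_from_dicts(reader, str(path))
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_records_csv(records: Iterable[PublicationRecord], path: str | Path) -> None:
    """Write records as RFC 4180 CSV in GSPP column order.

    Embedded newlines in abstracts are preserved inside quoted fields; the
    output round-trips exactly through :func:`read_records_table`.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GSPP_COLUMNS)
        for rec in records:
            writer.writerow([rec.pmid, rec.year, rec.title, rec.abstract, rec.journal])


def write_gspp_csv(profile, path: str | Path) -> None:
    """Serialize a gene-specific publication profile to CSV."""
    write_records_csv(profile.records, path)


# ---------------------------------------------------------------------------
# Entrez query construction (+ optional network adapter)
# ---------------------------------------------------------------------------


def build_gene_query(gene) -> str:
    """Build a title/abstract-restricted disjunction query for one gene.

    The official symbol comes first, aliases follow in registry order;
    surface forms are de-duplicated case-insensitively.
    """
    forms = gene.surface_forms()
    if not forms:
        raise ValueError("gene has no surface forms")
    return " OR ".join(f"{form}[Title/Abstract]" for form in forms)


def fetch_pubmed_corpus(gene, email: str, retmax: int = 100_000) -> Corpus:
    """Optional network adapter: fetch a gene's publications via E-utilities.

    Requires ``biopython`` and network access; the core pipeline never calls
    this.  Results are parsed with the same rules as :func:`read_pubmed_xml`.
    """
    import io
    import tempfile

    from Bio import Entrez  # lazy: optional dependency

    Entrez.email = email
    with Entrez.esearch(db="pubmed", term=build_gene_query(gene), retmax=retmax) as handle:
        result = Entrez.read(handle)
    ids = result.get("IdList", [])
    if not ids:
        return Corpus()
    with Entrez.efetch(db="pubmed", id=",".join(ids), rettype="xml", retmode="xml") as handle:
        data = handle.read()
    with tempfile.NamedTemporaryFile(suffix=".xml", delete=True) as tmp:
        tmp.write(data if isinstance(data, bytes) else data.encode("utf-8"))
        tmp.flush()
        return read_pubmed_xml(tmp.name)
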