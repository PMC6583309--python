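"""Reading MEDLINE/PubMed citation XML into validated article records.

This module covers the data-extraction layer of the title-trends pipeline:
parsing ``PubmedArticleSet`` XML (the dialect returned by NCBI E-utilities
``efetch``) into :class:`ArticleRecord` objects, and the two cohort filters
used downstream — a journal/year window for the n-gram analysis and a
publication-type include/exclude screen for the clinical-trial arm.

Only the title, journal, publication year and publication types of each
citation are retained; abstracts, authors and MeSH terms are out of scope.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import yaml
from lxml import etree

__all__ = [
    "ArticleRecord",
    "CohortFilter",
    "ParseReport",
    "SelectionAccounting",
    "parse_medline_xml",
    "filter_cohort",
    "select_clinical_trials",
    "default_clinical_trial_filter",
    "load_pub_type_aliases",
    "read_records_jsonl",
    "write_records_jsonl",
    "write_records_tsv",
]

_YEAR_RUN = re.compile(r"\b(\d{4})\b")
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class ArticleRecord:
    """One parsed MEDLINE citation.

    Attributes
    ----------
    pmid : str
        PubMed identifier (unique within a parsed set).
    journal : str
        Canonical journal name.
    year : int
        Four-digit calendar year of publication.
    title : str
        Whitespace-normalised Unicode title text (trailing period kept).
    pub_types : frozenset of str
        MEDLINE publication-type names attached to the citation.
    """

    pmid: str
    journal: str
    year: int
    title: str
    pub_types: frozenset[str]

    def __post_init__(self) -> None:
        if not self.title.strip():
            raise ValueError(f"record {self.pmid}: empty title")
        if not (1000 <= self.year <= 9999):
            raise ValueError(f"record {self.pmid}: year {self.year} is not 4-digit")
        if not self.pub_types:
            raise ValueError(f"record {self.pmid}: empty publication-type set")


@dataclass(frozen=True)
class CohortFilter:
    """Journal/year window and publication-type screen.

    ``include_types``/``exclude_types`` are matched case-insensitively
    against each record's publication types after alias normalisation
    (see :func:`load_pub_type_aliases`).
    """

    journals: frozenset[str] = frozenset()
    year_min: int = 0
    year_max: int = 9999
    include_types: frozenset[str] = frozenset()
    exclude_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.year_min > self.year_max:
            raise ValueError("year_min must be <= year_max")
        inc = {t.lower() for t in self.include_types}
        exc = {t.lower() for t in self.exclude_types}
        if inc & exc:
            raise ValueError(f"include/exclude overlap: {sorted(inc & exc)}")


@dataclass
class ParseReport:
    """Accounting for one :func:`parse_medline_xml` call."""

    parsed: int = 0
    skipped: int = 0
    duplicates: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def _skip(self, reason: str) -> None:
        self.skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "parsed": self.parsed,
                "skipped": self.skipped,
                "duplicates": self.duplicates,
                "skip_reasons": self.skip_reasons,
            },
            indent=2,
        )


def _flatten_title(elem: etree._Element) -> str:
    # Inline markup (<i>, <sub>, <sup> ...) is flattened to its text content;
    # internal whitespace collapses to single spaces; trailing period kept.
    return _WS.sub(" ", "".join(elem.itertext())).strip()


def _resolve_year(article_elem: etree._Element) -> int | None:
    """``PubDate/Year`` if present, else the first 4-digit run in ``MedlineDate``."""
    year = article_elem.findtext(".//Journal/JournalIssue/PubDate/Year")
    if year and year.strip().isdigit():
        return int(year.strip())
    mdate = article_elem.findtext(".//Journal/JournalIssue/PubDate/MedlineDate")
    if mdate:
        m = _YEAR_RUN.search(mdate)
        if m:
            return int(m.group(1))
    return None


def parse_medline_xml(
    source: str | Path | IO[bytes] | IO[str],
    report: ParseReport | None = None,
) -> list[ArticleRecord]:
    """Parse a ``PubmedArticleSet`` document into article records.

    One record is emitted per citation carrying a title and a resolvable
    publication year; citations lacking either are skipped and counted in
    *report* (never silently dropped, never a crash). Records with a PMID
    already seen in this call are dropped as duplicates.

    Raises
    ------
    lxml.etree.XMLSyntaxError
        Malformed XML (message carries line/column position).
    ValueError
        Root element is not ``PubmedArticleSet``.
    """
    if report is None:
        report = ParseReport()
    tree = etree.parse(source) if not isinstance(source, (str, Path)) else etree.parse(str(source))
    root = tree.getroot()
    if root.tag != "PubmedArticleSet":
        raise ValueError(f"unknown root element {root.tag!r}; expected PubmedArticleSet")

    records: list[ArticleRecord] = []
    seen_pmids: set[str] = set()
    for citation in root.iter("MedlineCitation"):
        pmid = (citation.findtext("PMID") or "").strip()
        article = citation.find("Article")
        if article is None:
            report._skip("no Article element")
            continue
        title_elem = article.find("ArticleTitle")
        if title_elem is None or not _flatten_title(title_elem):
            report._skip("missing title")
            continue
        year = _resolve_year(article)
        if year is None:
            report._skip("unresolvable year")
            continue
        journal = (
            article.findtext("Journal/Title") or citation.findtext("MedlineJournalInfo/MedlineTA") or ""
        ).strip()
        if not journal:
            report._skip("missing journal")
            continue
        pub_types = frozenset(
            pt.strip()
            for pt in (e.text or "" for e in article.iter("PublicationType"))
            if pt.strip()
        )
        if not pub_types:
            report._skip("no publication types")
            continue
        if pmid in seen_pmids:
            report.duplicates += 1
            continue
        seen_pmids.add(pmid)
        records.append(
            ArticleRecord(
                pmid=pmid,
                journal=journal,
                year=year,
                title=_flatten_title(title_elem),
                pub_types=pub_types,
            )
        )
        report.parsed += 1
    return records


def filter_cohort(records: Iterable[ArticleRecord], f: CohortFilter) -> list[ArticleRecord]:
    """Keep exactly the records inside the journal set and year window, in order."""
    journals = {j.lower() for j in f.journals}
    return [
        r
        for r in records
        if (not journals or r.journal.lower() in journals) and f.year_min <= r.year <= f.year_max
    ]


@dataclass
class SelectionAccounting:
    """Per-rule accounting for :func:`select_clinical_trials`."""

    n_input: int = 0
    n_passing_inclusion: int = 0
    n_selected: int = 0
    removed_by_exclusion: dict[str, int] = field(default_factory=dict)


def load_pub_type_aliases() -> dict[str, str]:
    """Lowercased alias -> canonical MEDLINE publication-type name."""
    cfg = _load_cohort_config()
    return {k.lower(): v for k, v in cfg.get("aliases", {}).items()}


def _load_cohort_config() -> dict:
    text = resources.files("titletrends.data").joinpath("clinical_trial_cohort.yaml").read_text()
    return yaml.safe_load(text)


def default_clinical_trial_filter(
    journals: Iterable[str] = (), year_min: int = 0, year_max: int = 9999
) -> CohortFilter:
    """The shipped clinical-trial inclusion/exclusion publication-type screen."""
    cfg = _load_cohort_config()
    return CohortFilter(
        journals=frozenset(journals),
        year_min=year_min,
        year_max=year_max,
        include_types=frozenset(cfg["include_types"]),
        exclude_types=frozenset(cfg["exclude_types"]),
    )


def _canonical_types(record: ArticleRecord, aliases: Mapping[str, str]) -> set[str]:
    return {aliases.get(pt.lower(), pt).lower() for pt in record.pub_types}


def select_clinical_trials(
    records: Sequence[ArticleRecord],
    f: CohortFilter,
    aliases: Mapping[str, str] | None = None,
) -> tuple[list[ArticleRecord], SelectionAccounting]:
    """Apply the publication-type include/exclude screen.

    A record is kept iff its (alias-normalised, case-folded) publication types
    intersect ``f.include_types`` and avoid ``f.exclude_types`` entirely.
    Order-preserving and idempotent; the accounting reports how many records
    passed inclusion and how many each exclusion type removed.
    """
    if aliases is None:
        aliases = load_pub_type_aliases()
    include = {t.lower() for t in f.include_types}
    exclude = {t.lower() for t in f.exclude_types}
    if not include:
        raise ValueError("CohortFilter.include_types must be populated")
    acc = SelectionAccounting(n_input=len(records))
    kept: list[ArticleRecord] = []
    for r in records:
        types = _canonical_types(r, aliases)
        if not (types & include):
            continue
        acc.n_passing_inclusion += 1
        hit = types & exclude
        if hit:
            for t in sorted(hit):
                acc.removed_by_exclusion[t] = acc.removed_by_exclusion.get(t, 0) + 1
            continue
        kept.append(r)
    acc.n_selected = len(kept)
    return kept, acc


# ---------------------------------------------------------------------------
# Plain-text record I/O (line-delimited JSON and TSV)

def write_records_jsonl(records: Iterable[ArticleRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "pmid": r.pmid,
                        "journal": r.journal,
                        "year": r.year,
                        "title": r.title,
                        "pub_types": sorted(r.pub_types),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_records_jsonl(path: str | Path) -> list[ArticleRecord]:
    out: list[ArticleRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                ArticleRecord(
                    pmid=d["pmid"],
                    journal=d["journal"],
                    year=int(d["year"]),
                    title=d["title"],
                    pub_types=frozenset(d["pub_types"]),
                )
            )
    return out


def write_records_tsv(records: Iterable[ArticleRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pmid\tjournal\tyear\ttitle\tpub_types\n")
        for r in records:
            fh.write(f"{r.pmid}\t{r.journal}\t{r.year}\t{r.title}\t{'|'.join(sorted(r.pub_types))}\n")
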