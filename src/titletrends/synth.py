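"""Synthetic MEDLINE-style corpora with known term-frequency trends.

The generator emulates the statistical structure the trend screen assumes:
each year a number of articles is produced, each title is a sequence of
token slots, and every slot draws a term from a year-dependent multinomial
whose injected-term probabilities follow straight lines in calendar year,

    p_t(y) = (b_t + s_t * (y - year_min)) / 100000,

with a filler vocabulary absorbing the remaining probability mass so the
injected targets are exact rather than renormalised. Injected bigrams are
placed as adjacent token pairs at their own year-dependent rates. Articles
typed as clinical trials inside a declared era get template-generated
titles — patient-centric ("... in patients with <disease>") with the era's
probability, otherwise disease-centric ("... for <disease>") — and the true
label of every templated title is recorded.

Everything is driven by a single integer seed; the same spec and seed
reproduce the corpus byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from lxml import etree

from .records import ArticleRecord, parse_medline_xml

__all__ = [
    "TermSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "sample_term_counts",
]

_TRIAL_TYPES = {"clinical trial", "randomized controlled trial",
                "controlled clinical trial", "pragmatic clinical trial"}

_PC_NOUNS = ("patients", "adults", "children", "women", "men")
_TREATMENTS = ("prazosin", "beclomethasone", "erythromycin", "fluconazole",
               "radiotherapy", "aliskiren", "metformin", "budesonide")
_DISEASES = ("hypertension", "asthma", "diabetes", "candidiasis",
             "glioma", "ketoacidosis", "pneumonia", "migraine")


@dataclass(frozen=True)
class TermSpec:
    """One injected term: baseline frequency at year_min and linear slope.

    Units: occurrences per 100,000 words (baseline) and per 100,000 words
    per year (slope). ``term`` may hold two space-separated words, in which
    case it is injected as an adjacent bigram.
    """

    term: str
    baseline: float
    slope: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic corpus; the seed is mandatory."""

    years: tuple[int, int]
    articles_per_year: int | tuple[int, ...]
    vocabulary: tuple[TermSpec, ...]
    seed: int
    injected_bigrams: tuple[TermSpec, ...] = ()
    title_length_range: tuple[int, int] = (4, 14)
    pub_type_mix: tuple[tuple[tuple[str, ...], float], ...] = ((("Journal Article",), 1.0),)
    patient_centric_fraction_by_era: tuple[tuple[tuple[int, int], float], ...] = ()
    journal: str = "Journal of Synthetic Medicine"
    n_filler_terms: int = 100

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y0 > y1:
            raise ValueError("years must be (min, max) with min <= max")
        total_mix = sum(p for _, p in self.pub_type_mix)
        if abs(total_mix - 1.0) > 1e-9 or any(p < 0 for _, p in self.pub_type_mix):
            raise ValueError("pub_type_mix probabilities must be in [0,1] and sum to 1")
        for (e0, e1), frac in self.patient_centric_fraction_by_era:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"era fraction {frac} outside [0,1]")
            if e0 > e1:
                raise ValueError("era range must be (min, max)")
        for ts in (*self.vocabulary, *self.injected_bigrams):
            for y in (y0, y1):
                f = ts.baseline + ts.slope * (y - y0)
                if f < 0:
                    raise ValueError(
                        f"term {ts.term!r}: frequency {f:.3f} negative at year {y}"
                    )
        # total injected monogram mass must leave room for filler at every year
        for y in (y0, y1):
            mass = sum(ts.baseline + ts.slope * (y - y0) for ts in self.vocabulary)
            if mass >= 100000.0:
                raise ValueError(f"vocabulary mass {mass:.0f}/100000 infeasible at {y}")

    def n_articles(self, year: int) -> int:
        if isinstance(self.articles_per_year, int):
            return self.articles_per_year
        return self.articles_per_year[year - self.years[0]]

    def era_of(self, year: int) -> tuple[tuple[int, int], float] | None:
        for era, frac in self.patient_centric_fraction_by_era:
            if era[0] <= year <= era[1]:
                return era, frac
        return None


@dataclass
class GroundTruth:
    """What the generator actually injected, for downstream recovery checks."""

    true_slopes: dict[str, float]
    true_labels: dict[str, bool]
    record_list: list[ArticleRecord] = field(default_factory=list)


def _template_title(rng: np.random.Generator, patient_centric: bool) -> str:
    treatment = _TREATMENTS[rng.integers(len(_TREATMENTS))]
    disease = _DISEASES[rng.integers(len(_DISEASES))]
    if patient_centric:
        noun = _PC_NOUNS[rng.integers(len(_PC_NOUNS))]
        return f"{treatment} in {noun} with {disease}: a randomized clinical trial"
    return f"{treatment} for {disease}: a randomized clinical trial"


def generate_corpus(spec: SyntheticSpec) -> tuple[GroundTruth, list[ArticleRecord]]:
    """Sample a full corpus of article records plus its ground truth.

    Infeasible frequency targets fail at spec validation, not here. Titles
    in the trend arm are lowercase token sequences; template titles drive
    the classification arm for clinical-trial-typed records inside declared
    eras.
    """
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.years
    lo, hi = spec.title_length_range

    inj_terms = [ts.term for ts in spec.vocabulary]
    filler = [f"filler{i:03d}" for i in range(spec.n_filler_terms)]
    all_terms = np.array(inj_terms + filler)
    mix_types = [tuple(t) for t, _ in spec.pub_type_mix]
    mix_probs = np.array([p for _, p in spec.pub_type_mix])

    truth = GroundTruth(
        true_slopes={ts.term: ts.slope for ts in (*spec.vocabulary, *spec.injected_bigrams)},
        true_labels={},
    )
    records: list[ArticleRecord] = []
    pmid = 0
    for year in range(y0, y1 + 1):
        n_art = spec.n_articles(year)
        if n_art == 0:
            continue
        # per-slot term distribution for this year
        p_inj = np.array(
            [(ts.baseline + ts.slope * (year - y0)) / 100000.0 for ts in spec.vocabulary]
        )
        p_fill = np.full(len(filler), (1.0 - p_inj.sum()) / max(1, len(filler)))
        p = np.concatenate([p_inj, p_fill])

        type_ix = rng.choice(len(mix_types), size=n_art, p=mix_probs)
        era = spec.era_of(year)

        # trend-arm titles are sampled in one vectorised draw per year
        lengths = rng.integers(lo, hi + 1, size=n_art)
        flat = rng.choice(all_terms, size=int(lengths.sum()), p=p)
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        token_lists: list[list[str] | None] = []
        is_template = np.zeros(n_art, dtype=bool)
        for i in range(n_art):
            pub = mix_types[type_ix[i]]
            trial = era is not None and any(t.lower() in _TRIAL_TYPES for t in pub)
            if trial:
                is_template[i] = True
                token_lists.append(None)
            else:
                token_lists.append(list(flat[offsets[i]:offsets[i + 1]]))

        _inject_bigrams(spec, rng, year, token_lists)

        for i in range(n_art):
            pmid += 1
            pid = str(pmid)
            if is_template[i]:
                pc = bool(rng.random() < era[1])
                title = _template_title(rng, pc)
                truth.true_labels[pid] = pc
            else:
                title = " ".join(token_lists[i])
            records.append(
                ArticleRecord(
                    pmid=pid,
                    journal=spec.journal,
                    year=year,
                    title=title,
                    pub_types=frozenset(mix_types[type_ix[i]]),
                )
            )
    truth.record_list = records
    return truth, records


def _inject_bigrams(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    year: int,
    token_lists: list[list[str] | None],
) -> None:
    """Overwrite random adjacent slot pairs with the injected word pairs."""
    if not spec.injected_bigrams:
        return
    y0 = spec.years[0]
    n_tokens = sum(len(t) for t in token_lists if t is not None)
    positions = [
        (i, j)
        for i, toks in enumerate(token_lists)
        if toks is not None
        for j in range(len(toks) - 1)
    ]
    if not positions:
        return
    used: set[tuple[int, int]] = set()
    for ts in spec.injected_bigrams:
        words = ts.term.split()
        if len(words) != 2:
            raise ValueError(f"injected bigram {ts.term!r} must be two words")
        rate = ts.baseline + ts.slope * (year - y0)
        m = min(rng.poisson(rate * n_tokens / 100000.0), len(positions))
        if m == 0:
            continue
        for k in rng.choice(len(positions), size=m, replace=False):
            i, j = positions[k]
            # skip placements that would overlap an earlier pair
            if (i, j) in used or (i, j - 1) in used or (i, j + 1) in used:
                continue
            token_lists[i][j], token_lists[i][j + 1] = words
            used.add((i, j))


def sample_term_counts(
    baseline: float,
    slope: float,
    years: Sequence[int],
    tokens_per_year: int | Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-year occurrence counts of one injected term, sampled directly.

    Draws ``c_y ~ Binomial(N_y, p(y))`` with ``p(y)`` the generator's
    per-slot probability — the exact marginal of per-slot multinomial
    sampling — without materialising title strings. This is the fast path
    used for large simulation studies (coverage, FDR, type-I error).
    """
    years = np.asarray(years)
    n = np.broadcast_to(np.asarray(tokens_per_year), years.shape)
    p = (baseline + slope * (years - years.min())) / 100000.0
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("infeasible frequency target")
    return rng.binomial(n, p)


# ---------------------------------------------------------------------------
# MEDLINE-dialect XML output

def _record_xml(r: ArticleRecord) -> etree._Element:
    art = etree.Element("PubmedArticle")
    cit = etree.SubElement(art, "MedlineCitation")
    etree.SubElement(cit, "PMID").text = r.pmid
    a = etree.SubElement(cit, "Article")
    j = etree.SubElement(a, "Journal")
    etree.SubElement(j, "Title").text = r.journal
    issue = etree.SubElement(j, "JournalIssue")
    pd_ = etree.SubElement(issue, "PubDate")
    etree.SubElement(pd_, "Year").text = str(r.year)
    etree.SubElement(a, "ArticleTitle").text = r.title
    ptl = etree.SubElement(a, "PublicationTypeList")
    for pt in sorted(r.pub_types):
        etree.SubElement(ptl, "PublicationType").text = pt
    return art


def write_corpus(
    records: Sequence[ArticleRecord],
    path: str | Path,
    split_by_year: bool = True,
) -> list[Path]:
    """Write records as PubmedArticleSet XML, one file per journal-year.

    Round-trip guarantee: the files parse back through
    :func:`titletrends.records.parse_medline_xml` to field-equal records.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[str, int], list[ArticleRecord]] = {}
    if split_by_year:
        for r in records:
            groups.setdefault((r.journal, r.year), []).append(r)
    else:
        groups[("corpus", 0)] = list(records)
    written: list[Path] = []
    for (journal, year), recs in groups.items():
        root = etree.Element("PubmedArticleSet")
        for r in recs:
            root.append(_record_xml(r))
        safe = "".join(c if c.isalnum() else "_" for c in journal)
        fname = f"{safe}_{year}.xml" if split_by_year else "corpus.xml"
        out = path / fname
        etree.ElementTree(root).write(
            str(out), encoding="utf-8", xml_declaration=True, pretty_print=True
        )
        written.append(out)
    return sorted(written)


def read_corpus(path: str | Path) -> list[ArticleRecord]:
    """Parse every ``*.xml`` under *path*, records sorted by numeric PMID."""
    records: list[ArticleRecord] = []
    for f in sorted(Path(path).glob("*.xml")):
        records.extend(parse_medline_xml(f))
    return sorted(records, key=lambda r: (len(r.pmid), r.pmid))
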