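"""Title tokenisation and per-year monogram/bigram frequency tables.

Counts are organised per calendar year. The frequency of a term in a year is
reported per 100,000 words: ``f = 100000 * c / N`` where ``N`` is the total
number of title tokens that year, counted *before* stop-word removal so that
monogram and bigram frequencies share a denominator and their trend slopes
are directly comparable.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .records import ArticleRecord

__all__ = [
    "TokenizerConfig",
    "FrequencyTable",
    "TermSeries",
    "load_stopwords",
    "tokenize",
    "build_frequency_table",
    "low_frequency_filter",
    "get_series",
]

STOPWORDS_VERSION = "1.0"

# Maximal runs of letters/digits; internal hyphens and apostrophes retained.
_TOKEN = re.compile(r"[^\W_]+(?:['’-][^\W_]+)*", re.UNICODE)
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


def load_stopwords() -> frozenset[str]:
    """The shipped, versioned English stop-word list (174 words, lowercase)."""
    text = resources.files("titletrends.data").joinpath("stopwords_en.txt").read_text()
    words = frozenset(w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#"))
    assert len(words) == 174, "shipped stop-word list must hold exactly 174 words"
    return words


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenisation and stop-word policy.

    Stop words are removed before *monogram* counting only, by default:
    function words carry context inside bigrams ("patients with", "cause of")
    but are uninformative alone.
    """

    lowercase: bool = True
    stopword_list: frozenset[str] = field(default_factory=load_stopwords)
    apply_stopwords_to: Literal["monograms_only", "both", "neither"] = "monograms_only"

    def __post_init__(self) -> None:
        bad = [w for w in self.stopword_list if w != w.lower()]
        if bad:
            raise ValueError(f"stop-word list must be lowercase; offending: {bad[:5]}")


def tokenize(title: str, cfg: TokenizerConfig | None = None) -> list[str]:
    """Split a title into tokens.

    Punctuation other than internal hyphens/apostrophes separates tokens;
    en/em dashes are normalised to hyphens; digits are retained as tokens.
    A title with no admissible tokens yields the empty list.
    """
    if cfg is None:
        cfg = TokenizerConfig()
    text = unicodedata.normalize("NFC", title).translate(_DASHES)
    if cfg.lowercase:
        text = text.lower()
    return _TOKEN.findall(text)


@dataclass
class FrequencyTable:
    """Per-year term counts and token denominators for one n-gram order.

    ``counts`` maps each term to an integer count vector aligned with
    ``years``; ``denominators[i]`` is the total pre-stop-word token count of
    year ``years[i]`` (zero for years with no articles).
    """

    order: int
    years: list[int]
    counts: dict[str, np.ndarray]
    denominators: np.ndarray

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")

    @property
    def period_total_tokens(self) -> int:
        return int(self.denominators.sum())

    @property
    def terms(self) -> list[str]:
        return list(self.counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (order, term, year, count, denominator)."""
        rows = [
            (self.order, t, y, int(c), int(n))
            for t, cvec in self.counts.items()
            for y, c, n in zip(self.years, cvec, self.denominators)
        ]
        return pd.DataFrame(rows, columns=["order", "term", "year", "count", "denominator"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t")
        order = int(df["order"].iloc[0])
        years = sorted(df["year"].unique())
        year_ix = {y: i for i, y in enumerate(years)}
        denom = np.zeros(len(years), dtype=np.int64)
        counts: dict[str, np.ndarray] = {}
        for (term,), grp in df.groupby(["term"], sort=False):
            vec = np.zeros(len(years), dtype=np.int64)
            for _, row in grp.iterrows():
                vec[year_ix[row["year"]]] = row["count"]
                denom[year_ix[row["year"]]] = row["denominator"]
            counts[str(term)] = vec
        return cls(order=order, years=[int(y) for y in years], counts=counts, denominators=denom)


@dataclass(frozen=True)
class TermSeries:
    """Yearly frequency series of one term, per 100,000 words."""

    term: str
    years: np.ndarray
    freq: np.ndarray
    dropped_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.years) != len(self.freq):
            raise ValueError("years and freq must be equal length")


def build_frequency_table(
    records: Sequence[ArticleRecord],
    order: int,
    cfg: TokenizerConfig | None = None,
    years: Iterable[int] | None = None,
) -> FrequencyTable:
    """Count monograms (order 1) or adjacent-pair bigrams (order 2) per year.

    Bigrams never span titles. Stop-word removal (per ``cfg``) happens before
    counting, but the per-year denominators always count pre-removal tokens.
    Years given in *years* but holding no articles appear with denominator 0.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    if cfg is None:
        cfg = TokenizerConfig()
    remove_stops = (cfg.apply_stopwords_to == "both") or (
        cfg.apply_stopwords_to == "monograms_only" and order == 1
    )

    year_set = set(years) if years is not None else set()
    year_set.update(r.year for r in records)
    year_list = sorted(year_set)
    year_ix = {y: i for i, y in enumerate(year_list)}
    n_years = len(year_list)

    denom = np.zeros(n_years, dtype=np.int64)
    counts: dict[str, np.ndarray] = {}
    for r in records:
        iy = year_ix[r.year]
        tokens = tokenize(r.title, cfg)
        denom[iy] += len(tokens)
        if remove_stops:
            tokens = [t for t in tokens if t not in cfg.stopword_list]
        grams = tokens if order == 1 else [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]
        for g in grams:
            vec = counts.get(g)
            if vec is None:
                vec = counts.setdefault(g, np.zeros(n_years, dtype=np.int64))
            vec[iy] += 1
    return FrequencyTable(order=order, years=year_list, counts=counts, denominators=denom)


def low_frequency_filter(
    table: FrequencyTable, threshold: float = 1e-4
) -> tuple[set[str], int]:
    """Drop terms of very low aggregate frequency over the whole period.

    A term is retained iff its pooled count over all years, divided by the
    pooled token denominator, is >= *threshold* (strictly-below excludes;
    the default 1e-4 is the 0.01% floor). Returns the retained term set and
    the number of excluded terms.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    total = table.period_total_tokens
    if total <= 0:
        raise ValueError("table has zero total tokens")
    retained = {t for t, c in table.counts.items() if c.sum() / total >= threshold}
    return retained, len(table.counts) - len(retained)


def get_series(table: FrequencyTable, term: str) -> TermSeries:
    """Frequency series ``f = 100000 * c / N`` of one term.

    Years with a zero denominator are dropped from the series (0/0 is
    undefined) and listed in ``dropped_years``. An absent term yields an
    all-zero series over the table's populated years.
    """
    c = table.counts.get(term)
    if c is None:
        c = np.zeros(len(table.years), dtype=np.int64)
    keep = table.denominators > 0
    dropped = tuple(int(y) for y, k in zip(table.years, keep) if not k)
    years = np.asarray(table.years, dtype=np.int64)[keep]
    freq = 100000.0 * c[keep] / table.denominators[keep]
    return TermSeries(term=term, years=years, freq=freq, dropped_years=dropped)
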