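"""Patient-centric title classification and the era-contrast statistics.

A clinical-trial title is called *patient-centric* when it names the people
under study with a noun that is independent of a disease label: "patients
with diabetes" or "adults with asthma" qualify, while "diabetic ketoacidosis"
names only the disease and, under the independence rule, "diabetic patients"
characterises the patients *by* their disease and does not qualify.

The rule-based classifier is a versioned, reproducible stand-in for human
annotation; the module also implements the agreement and contrast machinery
used around annotation — Cohen's kappa between two raters, third-rater
adjudication of disagreements, the two-proportion z-test between early and
late eras, and the title-length contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .ngrams import TokenizerConfig, tokenize

__all__ = [
    "RuleSet",
    "Classification",
    "AnnotationSet",
    "KappaResult",
    "ProportionComparison",
    "LengthComparison",
    "load_default_ruleset",
    "classify_title",
    "cohens_kappa",
    "adjudicate",
    "two_proportion_z",
    "wilson_interval",
    "title_length_contrast",
]

_TOKENIZER = TokenizerConfig(apply_stopwords_to="neither")


@dataclass(frozen=True)
class RuleSet:
    """Lexicons and switches driving the classifier; carries a version tag."""

    patient_nouns: frozenset[str]
    disease_adjective_lexicon: frozenset[str]
    independence_rule: bool = True
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.patient_nouns:
            raise ValueError("patient_nouns must be non-empty")
        if not self.version:
            raise ValueError("version must be non-empty")
        for name, lex in (
            ("patient_nouns", self.patient_nouns),
            ("disease_adjective_lexicon", self.disease_adjective_lexicon),
        ):
            if any(w != w.lower() for w in lex):
                raise ValueError(f"{name} must be lowercase")


def load_default_ruleset() -> RuleSet:
    """The shipped default rule set (patient nouns, disease adjectives)."""
    text = resources.files("titletrends.data").joinpath("patient_centric_rules.yaml").read_text()
    d = yaml.safe_load(text)
    return RuleSet(
        patient_nouns=frozenset(d["patient_nouns"]),
        disease_adjective_lexicon=frozenset(d["disease_adjective_lexicon"]),
        independence_rule=bool(d["independence_rule"]),
        version=str(d["version"]),
    )


@dataclass(frozen=True)
class Classification:
    """Label plus the evidence behind it.

    ``matched_nouns`` lists every patient-noun token that qualified;
    ``disqualified`` lists (adjective, noun) pairs vetoed by the
    independence rule. ``rules_version`` makes outputs comparable across
    rule-set revisions.
    """

    patient_centric: bool
    matched_nouns: tuple[str, ...]
    disqualified: tuple[tuple[str, str], ...]
    rules_version: str


def classify_title(title: str, rules: RuleSet) -> Classification:
    """Classify one title as patient-centric or not.

    Deterministic for a fixed ``rules.version``; matching is on lowercased
    tokens, so it is invariant to case and surrounding punctuation.
    """
    tokens = tokenize(title, _TOKENIZER)
    matched: list[str] = []
    disqualified: list[tuple[str, str]] = []
    for i, tok in enumerate(tokens):
        if tok not in rules.patient_nouns:
            continue
        prev = tokens[i - 1] if i > 0 else None
        if rules.independence_rule and prev in rules.disease_adjective_lexicon:
            disqualified.append((prev, tok))
            continue
        matched.append(tok)
    return Classification(
        patient_centric=bool(matched),
        matched_nouns=tuple(matched),
        disqualified=tuple(disqualified),
        rules_version=rules.version,
    )


@dataclass
class AnnotationSet:
    """Binary labels of one rater over a title set (True = patient-centric)."""

    rater_id: str
    labels: dict[str, bool]
    blinded: bool = True


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa between two raters: observed vs chance agreement."""

    po: float
    pe: float
    kappa: float | None
    n: int

    @property
    def defined(self) -> bool:
        return self.kappa is not None


def cohens_kappa(a: AnnotationSet, b: AnnotationSet) -> KappaResult:
    """Chance-corrected agreement ``kappa = (po - pe) / (1 - pe)``.

    ``po`` is the fraction of titles labelled identically; ``pe`` the
    agreement expected from the raters' marginal label frequencies. When
    both raters are constant with identical marginals (pe == 1) kappa is
    undefined and reported as None, never NaN.
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("raters must label the same title set")
    ids = sorted(a.labels)
    n = len(ids)
    if n == 0:
        raise ValueError("empty annotation sets")
    la = np.array([a.labels[i] for i in ids], dtype=bool)
    lb = np.array([b.labels[i] for i in ids], dtype=bool)
    po = float(np.mean(la == lb))
    pa, pb = float(la.mean()), float(lb.mean())
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return KappaResult(po=po, pe=pe, kappa=None, n=n)
    return KappaResult(po=po, pe=pe, kappa=(po - pe) / (1 - pe), n=n)


def adjudicate(
    a: AnnotationSet, b: AnnotationSet, tiebreak: Mapping[str, bool]
) -> dict[str, tuple[bool, Literal["agreed", "adjudicated"]]]:
    """Resolve rater disagreements with a third rater's tie-breaking vote.

    *tiebreak* must cover exactly the disagreement set — no more, no less.
    Returns title_id -> (final label, provenance).
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("raters must label the same title set")
    disagreement = {t for t in a.labels if a.labels[t] != b.labels[t]}
    missing = disagreement - set(tiebreak)
    extra = set(tiebreak) - disagreement
    if missing:
        raise ValueError(f"tiebreak missing disagreed titles: {sorted(missing)[:5]}")
    if extra:
        raise ValueError(f"tiebreak covers agreed titles: {sorted(extra)[:5]}")
    out: dict[str, tuple[bool, Literal["agreed", "adjudicated"]]] = {}
    for t, lab in a.labels.items():
        if t in disagreement:
            out[t] = (bool(tiebreak[t]), "adjudicated")
        else:
            out[t] = (lab, "agreed")
    return out


@dataclass(frozen=True)
class ProportionComparison:
    """Two-proportion z-test between an early and a late era."""

    x_early: int
    n_early: int
    x_late: int
    n_late: int
    p_early: float
    p_late: float
    pooled_p: float
    z: float
    p_value: float
    ci_diff: tuple[float, float]


def two_proportion_z(x_early: int, n_early: int, x_late: int, n_late: int) -> ProportionComparison:
    """Two-sided two-proportion z-test (pooled SE, no continuity correction).

    ``z = (p_late - p_early) / sqrt(pooled_p (1 - pooled_p) (1/n_e + 1/n_l))``
    with ``pooled_p`` the overall success fraction; the 95% CI of the
    difference uses the unpooled standard error. A degenerate pooled
    proportion (0 or 1, i.e. no variation at all) reports z = 0, p = 1.
    """
    for x, n, era in ((x_early, n_early, "early"), (x_late, n_late, "late")):
        if n < 1:
            raise ValueError(f"n_{era} must be >= 1")
        if not (0 <= x <= n):
            raise ValueError(f"x_{era} must lie in [0, n_{era}]")
    p_e, p_l = x_early / n_early, x_late / n_late
    pooled = (x_early + x_late) / (n_early + n_late)
    diff = p_l - p_e
    se_unpooled = math.sqrt(p_e * (1 - p_e) / n_early + p_l * (1 - p_l) / n_late)
    zcrit = float(stats.norm.ppf(0.975))
    ci = (diff - zcrit * se_unpooled, diff + zcrit * se_unpooled)
    if pooled in (0.0, 1.0):
        return ProportionComparison(
            x_early, n_early, x_late, n_late, p_e, p_l, pooled, 0.0, 1.0, ci
        )
    se_pooled = math.sqrt(pooled * (1 - pooled) * (1 / n_early + 1 / n_late))
    z = diff / se_pooled
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return ProportionComparison(
        x_early, n_early, x_late, n_late, p_e, p_l, pooled, z, p_value, ci
    )


def wilson_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (used for display)."""
    if n < 1 or not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n, n >= 1")
    z = float(stats.norm.ppf(0.5 + conf / 2))
    phat = x / n
    denom = 1 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass(frozen=True)
class LengthComparison:
    """Mean title length (characters) in two eras and a Welch test."""

    mean_early: float
    mean_late: float
    diff: float
    p_value: float


def title_length_contrast(
    early_titles: Sequence[str], late_titles: Sequence[str]
) -> LengthComparison:
    """Compare mean title character counts between eras.

    Lengths are Unicode code points including spaces and any trailing
    period; the p-value is Welch's two-sided unequal-variance t-test.
    Identical samples (zero variance, zero difference) report p = 1.
    """
    if not early_titles or not late_titles:
        raise ValueError("both eras need at least one title")
    le = np.array([len(t) for t in early_titles], dtype=float)
    ll = np.array([len(t) for t in late_titles], dtype=float)
    diff = float(ll.mean() - le.mean())
    if le.var() == 0.0 and ll.var() == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
    else:
        p = float(stats.ttest_ind(ll, le, equal_var=False).pvalue)
    return LengthComparison(
        mean_early=float(le.mean()), mean_late=float(ll.mean()), diff=diff, p_value=p
    )
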