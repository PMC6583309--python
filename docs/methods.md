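# Methods

## The model

For each n-gram term *t* (monograms and bigrams analysed as separate
families) the yearly frequency is

    f_{t,y} = 100000 · c_{t,y} / N_y

where `c_{t,y}` is the term's count in titles published in year *y* and
`N_y` is the total number of title tokens that year, counted **before**
stop-word removal. Using a single pre-removal denominator for both orders
makes monogram and bigram slopes directly comparable; it is the package's
convention throughout.

The trend model is unweighted ordinary least squares of `f_{t,y}` on
calendar year with intercept — the "continuous linear model" of diachronic
corpus analysis. From the closed form `β = S_xy/S_xx`,
`se = √(SSE/(n−2)/S_xx)`, the two-tailed p-value uses Student's t with
`n−2` degrees of freedom and the 95% CI is `β ± t_{0.975,n−2}·se`.
Raw calendar year is the predictor (the slope is invariant to centring).
`total_change = β·(year_max − year_min)` is the quantity word-cloud weights
are built from (`|β|·span`), so a word's display size is proportional to the
magnitude of its absolute frequency change over the period, independent of
direction.

Multiplicity is handled with the Benjamini–Hochberg step-up adjustment at
an FDR threshold of 0.01, applied **within** each n-gram family (the two
families are reported separately; a pooled correction is a one-line change
at the call site since `bh_adjust` is family-agnostic). The screen ranks
significant terms by slope, ties broken lexicographically for determinism.

Degenerate inputs are contracted explicitly rather than left to float
behaviour: an exact linear fit (SSE = 0) yields p = 0 when the slope is
non-zero and p = 1 when it is zero; a constant or all-zero series is a null
result, not an error; years whose token denominator is zero are dropped
from every series (0/0 is undefined) and reported, never imputed as zero
frequency; a BH adjusted value is clipped to never fall below its raw
p-value (a one-ulp float artefact otherwise possible at the largest rank).

## Tokenisation and filtering

Tokens are maximal runs of letters/digits with internal hyphens and
apostrophes retained ("high-dose", "crohn's"); en/em dashes normalise to
hyphens; everything is lowercased; digits and single letters are kept
("type 1"). Hyphenated compounds are kept whole — whether to split them is
exposed only through the tokenizer, and is the main sensitivity-analysis
knob for anyone comparing against a framework that splits.

Stop words (the shipped 174-word Snowball English list, versioned as part
of the reproducibility surface) are removed before monogram counting only:
alone they are uninformative, but inside bigrams they carry the very
contrasts of interest ("patients with", "cause of"). Denominators always
count pre-removal tokens.

Terms whose pooled count over the whole period falls strictly below 0.01%
of the pooled token total are excluded before trend fitting. The floor is
interpreted as a whole-period aggregate criterion (pooled counts over
pooled tokens) applied separately per family; it is a parameter
(`low_freq_threshold`) for anyone preferring a mean-of-yearly-frequencies
reading.

## Cohort filters

The clinical-trial arm includes records indexed with any clinical-trial
publication type (clinical trial incl. phase I–IV, randomized controlled
trial, pragmatic clinical trial, controlled clinical trial) and excludes
records carrying any of 18 canonical non-report types (biography, case
reports, classical article, clinical conference, comment, congresses,
consensus development conference, duplicate publication, editorial,
guideline, historical article, legal cases, letter, news, patient education
handout, portraits, retracted publication, review). Matching is
case-insensitive exact string match after a shipped alias table maps prose
names onto canonical MEDLINE names (e.g. "randomized clinical trial" →
"Randomized Controlled Trial", "patient education"/"handout" → "Patient
Education Handout"). Parsed record sets are deduplicated by PMID with
duplicates counted in the parse report.

## The patient-centric classifier

The classifier operationalises "a patient noun that is independent of a
disease process": a title is patient-centric iff it contains at least one
token from the patient-noun lexicon (patients, adults, children, women,
men, infants, participants, survivors, ...) that is **not** immediately
premodified by a disease adjective (diabetic, asthmatic, hypertensive, ...).
So "patients with diabetes" qualifies; "diabetic patients" does not (the
independence rule, configurable); "diabetic ketoacidosis" contains no
patient noun at all. Every output carries the rule-set version so
alternative lexicons remain comparable. The shipped lexicons are a
reproducible, versioned stand-in for human annotation criteria; they are
not claimed to reproduce any particular human inter-rater agreement or
per-journal proportion.

Around the classifier: Cohen's κ = (p_o − p_e)/(1 − p_e) between two
raters (undefined, reported as such, when p_e = 1); adjudication requires a
tie-break label for exactly the disagreement set and records per-title
provenance; the era contrast uses the two-sided two-proportion z-test with
pooled SE and no continuity correction (z² equals the uncorrected χ² on
the 2×2 table), Wilson intervals for displayed per-era proportions, a
Wald interval for the difference; the title-length contrast counts Unicode
code points including spaces and punctuation and tests with Welch's
unequal-variance t-test, the conservative default when the underlying test
is unspecified.

## The synthetic generator

`generate_corpus` emulates exactly the structure the screen assumes and
nothing more: per year a fixed number of articles; title lengths uniform on
4–14 tokens; each token slot an independent draw from a year-dependent
multinomial in which injected term *t* has probability
`(b_t + s_t·(y − y_min))/100000` and a filler vocabulary (default 100
terms) absorbs the remaining mass, so injected targets are exact rather
than renormalised. Injected bigrams are placed by overwriting random
non-overlapping adjacent slot pairs at their own linear rates. Articles
typed as clinical trials inside a declared era receive template titles —
"`<treatment>` in `<patient noun>` with `<disease>`: a randomized clinical
trial" with the era's patient-centric probability, else "`<treatment>` for
`<disease>`: a randomized clinical trial" — and the true label of every
templated title is recorded. Everything is driven by one integer seed;
identical spec + seed reproduces the corpus byte for byte.

What the generator does *not* emulate: real English syntax beyond the
templates, journal house styles, vocabulary drift other than linear trends,
correlation between terms beyond the multinomial constraint, or nomenclature
shifts. Passing tests therefore demonstrate that the statistical machinery
recovers known structure under its own model assumptions — not that the
shipped lexicons match any particular human annotation of real titles.

Two details matter when interpreting ground truth. First, when injected
slopes do not sum to zero the filler terms absorb the complementary drift,
so filler terms are not exact nulls; null-calibration studies use injected
terms with slope 0. Second, template titles share a year's token
denominator with trend-arm titles, diluting injected frequencies in era
years; corpora meant for slope recovery should not mix in a classification
arm (the validation studies keep the two arms in separate corpora).

For large simulation studies (CI coverage, FDR control, type-I error) the
per-year counts of a term are sampled directly as
`c_y ~ Binomial(N_y, p_t(y))` — the exact marginal distribution of per-slot
multinomial sampling — via `sample_term_counts`, avoiding the construction
of hundreds of millions of title strings; the string-level path is
exercised end to end at desk scale by the counting-oracle, round-trip and
pipeline checks.

## Validation studies and their conditions

The studies in `scripts/acceptance.py` and `tests/test_acceptance.py` run
under one fixed set of generator conditions, chosen once as realistic for
a moderately common content word in this kind of corpus: 40 years, 50,000
title tokens per year, baseline 50 per 100,000 words.

- **CI coverage**: injected slopes {1, 5, 10} per 100,000/yr, 200
  replicates each; nominal 95% intervals are expected to cover in 90–99%
  of replicates. The frequency data are binomial proportions, so variance
  grows along a rising trend; unweighted OLS (the model as specified)
  still attains near-nominal coverage at these signal sizes.
- **FDR control**: 1,000 null + 50 trending (slope 5) terms, 50
  replicates; the realised mean false-discovery proportion among q < 0.01
  calls should stay ≤ 0.03 (observed ≈ 0.01, consistent with the
  m₀/m-deflated BH guarantee).
- **Type-I error**: 100 all-null terms × 100 replicates; raw p < 0.05 in
  5% ± 2% of fits.
- **Oracles**: the OLS fit against matrix least squares (1e-8), BH against
  the textbook step-up definition (and statsmodels in the test suite),
  κ and z against hand-computed examples, z² against the uncorrected χ²,
  table counts against a naive sliding-window recount, and XML write→parse
  field identity.

## Known limitations

- The linear model ignores autocorrelation and heteroskedasticity of yearly
  frequencies; a weighted fit is a natural extension but the unweighted
  model is the estimand this package reports.
- No stemming/lemmatisation and n ≤ 2 only; "randomized"/"randomised"
  count separately.
- The classifier is token-based: it cannot see syntactic structure, so a
  disease adjective separated from its noun ("diabetic, pregnant patients")
  escapes the independence rule.
- The live E-utilities fetch path is a thin untested wrapper by design; all
  tested inputs are local XML.
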