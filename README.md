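# titletrends

Diachronic analysis of medical-journal article titles: which words and word
pairs rose or fell over decades of publishing, and whether clinical-trial
titles became more *patient-centric* — naming the people under study
("patients with diabetes") rather than only their disease ("diabetic
ketoacidosis").

The package is aimed at bibliometrics / medical-humanities researchers who
want a tested, reproducible pipeline for this kind of corpus study rather
than one-off scripts. It provides:

- a **MEDLINE/PubMed XML parser** (`PubmedArticleSet` dialect, as returned
  by NCBI E-utilities `efetch`) extracting title, journal, year and
  publication types, with journal/year and publication-type cohort filters;
- **per-year monogram/bigram frequency tables** from tokenized titles, with
  frequencies per 100,000 words, a shipped 174-word stop-word list (removed
  for monograms, kept for bigrams), and a 0.01% aggregate-frequency floor;
- a **mass-univariate trend screen**: for each term *t* an OLS line
  `f_{t,y} = α_t + β_t·y + ε` of yearly frequency on calendar year, the
  two-tailed t-test of `β_t = 0` (df = n−2), Benjamini–Hochberg FDR control
  across terms at threshold 0.01, ranked top-increased/decreased lists with
  95% CIs, and word-cloud weights `|β_t|·span`;
- a **rule-based patient-centric classifier** (versioned lexicons; a patient
  noun immediately premodified by a disease adjective does not qualify),
  plus Cohen's κ between raters, tie-break adjudication, the two-proportion
  z-test and a Welch title-length contrast between eras;
- a **synthetic corpus generator** with exactly known injected linear trends
  and patient-centric labels, so every stage can be validated against ground
  truth.

## Worked example

```python
import titletrends as tt

spec = tt.SyntheticSpec(
    years=(1976, 2015), articles_per_year=600,
    vocabulary=(tt.TermSpec("outcomes", 100.0, 10.0),   # +10 per 100k words/yr
                tt.TermSpec("plasma",  500.0, -10.0),   # -10 per 100k words/yr
                tt.TermSpec("serum",   300.0,   0.0)),  # null term
    seed=20260920,
)
truth, records = tt.generate_corpus(spec)
model = tt.TrendScreenModel.from_records(records, order=1)
res = model.fit(k=20)
print(res.summary(top=3))
```

prints

```
Term-frequency trend screen
============================================================
order: monogram   years: 1976-2015   terms tested: 103
FDR threshold: 0.01   significant: 2

term                          slope/yr                95% CI           q
------------------------------------------------------------------------
-- top increased --
outcomes                        10.505       [8.478, 12.531]    9.07e-11
-- top decreased --
plasma                          -9.862     [-12.087, -7.636]    3.29e-09
```

The screen recovers the injected slopes (+10 and −10 per 100,000 words per
year) within their confidence intervals, calls both trends significant at
FDR < 0.01, and correctly leaves the null term `serum` (and the 100 filler
terms) uncalled. `res.cloud_weights()` returns `|β|·39` per significant term
— here `{'outcomes': 409.7, 'plasma': 384.6}` — the total absolute frequency
change over the 39-year span, suitable for any word-cloud renderer.

The same stages are available from the shell:

```bash
titletrends run --config config.yaml --out out/   # simulate ... report
titletrends parse --xml 'corpus/*.xml' --out records.jsonl
titletrends count --records records.jsonl --order 2 --out bigrams.tsv
titletrends trend --table bigrams.tsv --fdr 0.01 --top 20 --out screen/
titletrends classify --records records.jsonl --out labels.tsv
titletrends agree --a r1.tsv --b r2.tsv
```

Every pipeline run writes a manifest (config hash, stop-list and rule-set
versions, seed, tool version, input digests) next to its outputs.

## Layout

```
src/titletrends/
  records.py    MEDLINE XML parsing, cohort filters, record I/O
  ngrams.py     tokenizer, stop words, per-year frequency tables
  trends.py     OLS trend fits, BH-FDR, TrendScreenModel/Results
  classify.py   patient-centric rules, kappa, adjudication, era contrasts
  synth.py      synthetic corpus generator + ground truth, XML writer
  pipeline.py   staged pipeline with run manifests
  cli.py        `titletrends` command group
  data/         stop-word list, cohort config, rule set, journal counts
```

See `docs/methods.md` for the statistical model, generator design,
parameter defaults and known limitations.
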