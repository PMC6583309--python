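{
  "description": "Published per-journal included clinical-trial title counts (eras 1976-1980 and 2011-2015 pooled) and the published overall total, used by the cohort-accounting report.",
  "per_journal": {
    "Annals of Internal Medicine": 193,
    "BMJ": 648,
    "JAMA": 476,
    "The Lancet": 932,
    "New England Journal of Medicine": 876
  },
  "published_total": 3125
}
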