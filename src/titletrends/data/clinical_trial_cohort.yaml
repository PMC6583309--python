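# Default publication-type cohort for the clinical-trial classification arm.
# Matching is case-insensitive exact string match after alias normalisation.
version: "1.0"
include_types:
  - Clinical Trial
  - Clinical Trial, Phase I
  - Clinical Trial, Phase II
  - Clinical Trial, Phase III
  - Clinical Trial, Phase IV
  - Randomized Controlled Trial
  - Pragmatic Clinical Trial
  - Controlled Clinical Trial
exclude_types:
  - Biography
  - Case Reports
  - Classical Article
  - Clinical Conference
  - Comment
  - Congresses
  - Consensus Development Conference
  - Duplicate Publication
  - Editorial
  - Guideline
  - Historical Article
  - Legal Cases
  - Letter
  - News
  - Patient Education Handout
  - Portraits
  - Retracted Publication
  - Review
# Alias table: prose / variant names -> canonical MEDLINE publication-type names.
aliases:
  randomized clinical trial: Randomized Controlled Trial
  clinical trial of any phase: Clinical Trial
  congress: Congresses
  legal case: Legal Cases
  portrait: Portraits
  patient education: Patient Education Handout
  handout: Patient Education Handout
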