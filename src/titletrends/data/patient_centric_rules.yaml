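# Default rule set for patient-centric title classification.
# A title is patient-centric iff it contains at least one patient-noun token
# that is not immediately premodified by a disease adjective
# ("patients with diabetes" qualifies; "diabetic patients" does not when the
# independence rule is on; "diabetic ketoacidosis" has no patient noun at all).
version: "1.0"
independence_rule: true
patient_nouns:
  - patient
  - patients
  - adult
  - adults
  - adolescent
  - adolescents
  - child
  - children
  - infant
  - infants
  - neonate
  - neonates
  - newborn
  - newborns
  - woman
  - women
  - man
  - men
  - participant
  - participants
  - survivor
  - survivors
  - volunteer
  - volunteers
  - elderly
disease_adjective_lexicon:
  - diabetic
  - asthmatic
  - hypertensive
  - epileptic
  - arthritic
  - anemic
  - anaemic
  - schizophrenic
  - cirrhotic
  - uremic
  - uraemic
  - septic
  - obese
  - depressed
  - demented
  - hemophilic
  - haemophilic
  - leukemic
  - leukaemic
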