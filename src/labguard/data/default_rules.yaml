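# Default appropriateness rule set: the publicly documented minimum
# retest intervals for seven high-volume analytes, the sodium 24 h
# soft stop, and the ANA / ANA-Reflex within-order incompatibility.
analytes:
  - canonical_id: APTT
    display_name: Activated partial thromboplastin time
    local_codes: {SAP: APTT-S, GALILEO: "0301"}
  - canonical_id: VANCO
    display_name: Vancomycin
    local_codes: {SAP: VANCO-S, GALILEO: "0718"}
  - canonical_id: CBC
    display_name: Blood count
    local_codes: {SAP: CBC-B, GALILEO: "0101"}
  - canonical_id: CRP
    display_name: C-reactive protein
    local_codes: {SAP: CRP-S, GALILEO: "0412"}
  - canonical_id: PT
    display_name: Prothrombin time
    local_codes: {SAP: PT-S, GALILEO: "0302"}
  - canonical_id: FERRI
    display_name: Ferritin
    local_codes: {SAP: FERRI-S, GALILEO: "0520"}
  - canonical_id: TSH
    display_name: Thyroid-stimulating hormone
    local_codes: {SAP: TSH-S, GALILEO: "0601"}
  - canonical_id: NA
    display_name: Sodium
    local_codes: {SAP: NA-S, GALILEO: "0401"}
  - canonical_id: ANA
    display_name: Antinuclear antibodies
    local_codes: {SAP: ANA-S, GALILEO: "0901"}
  - canonical_id: ANA_REFLEX
    display_name: Antinuclear antibodies (reflex)
    local_codes: {SAP: ANAR-S, GALILEO: "0902"}

code_maps: {}

normality_ranges:
  - {analyte: NA, sex: ANY, age_min_years: 18, lower: 135.0, upper: 145.0,
     units: mmol/L}

rules:
  - rule_id: R_APTT_24H
    analyte: APTT
    min_interval: 24h
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: Test executed in the last 24h
  - rule_id: R_VANCO_72H
    analyte: VANCO
    min_interval: 72h
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: Test executed in the last 72h
  - rule_id: R_CBC_24H
    analyte: CBC
    min_interval: 24h
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: Test executed in the last 24h
  - rule_id: R_CRP_72H
    analyte: CRP
    min_interval: 72h
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: Test executed in the last 72h
  - rule_id: R_PT_24H
    analyte: PT
    min_interval: 24h
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: Test executed in the last 24h
  - rule_id: R_FERRI_3MO
    analyte: FERRI
    min_interval: 3mo
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: This test should be repeated not before 3 months or
      as suggested by a specialist
  - rule_id: R_TSH_6MO
    analyte: TSH
    min_interval: 6mo
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: ANY
    reporting_comment: This test should be repeated not before 6 months or
      as suggested by a specialist
  - rule_id: R_NA_24H
    analyte: NA
    min_interval: 24h
    prior_criteria: TIME_AND_QUANT
    priority_scope: ROUTINE
    outcome: WARN_WITH_MOTIVATION
    sample_type: serum
    reporting_comment: Sodium already executed in the latest 24 h; an
      appropriate repetition requires at least 24 h between requests
  - rule_id: R_ANA_REFLEX_INCOMPAT
    analyte: ANA
    incompatible_with: [ANA_REFLEX]
    outcome: BLOCK
    sample_type: ANY
    reporting_comment: ANA and ANA Reflex are incompatible within the same
      order; remove one from the prescription
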