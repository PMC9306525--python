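# Default event-chain configuration: risks of transfusing D-positive red cells
# or low-titre group O whole blood prehospital, England.
#
# STRUCTURE is the shipped model: 14 contingent events (X1-X14) with
# distributional inputs (N1-N14), three harms, two recipient populations.
#
# VALUES are placeholders: each input is a uniform uncertainty band around a
# plausible point estimate, clearly marked below.  To reproduce published risk
# tables, transcribe the original model-input distributions over these
# placeholders (same schema) and re-run.  Event labels are best-effort.
schema_version: 1

inputs:
  - input_id: N1
    family: uniform
    params: [0.12, 0.18]
    description: P(recipient is D-negative)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N2
    family: uniform
    params: [0.07, 0.13]
    description: P(recipient is a female of childbearing potential, <50y)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N3
    family: uniform
    params: [0.005, 0.015]
    description: P(pre-existing anti-D | D-negative recipient)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N4
    family: uniform
    params: [0.2, 0.4]
    description: P(HTR at index transfusion | pre-existing anti-D, D-positive units)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N5
    family: uniform
    params: [0.05, 0.15]
    description: P(major morbidity or death | index HTR)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N6
    family: uniform
    params: [0.6, 0.8]
    description: P(survives index admission)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N7
    family: uniform
    params: [0.1, 0.3]
    description: P(D-alloimmunization after index D-positive transfusion)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N8
    family: uniform
    params: [0.05, 0.15]
    description: P(receives a future D-positive transfusion)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N9
    family: uniform
    params: [0.1, 0.2]
    description: P(future transfusion given before anti-D is detected)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N10
    family: uniform
    params: [0.1, 0.3]
    description: P(HTR at future transfusion | anti-D, D-positive units)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N11
    family: uniform
    params: [0.05, 0.15]
    description: P(major morbidity or death | future HTR)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N12
    family: uniform
    params: [0.2, 0.4]
    description: P(future pregnancy carried)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N13
    family: uniform
    params: [0.5, 0.7]
    description: P(foetus is D-positive)
    source_note: "placeholder - transcribe the published model inputs to reproduce"
  - input_id: N14
    family: uniform
    params: [0.04, 0.12]
    description: P(foetal death or lifelong disability | maternal anti-D, D-positive foetus)
    source_note: "placeholder - transcribe the published model inputs to reproduce"

events:
  - event_id: X1
    label: Recipient is D-negative
    input_ref: N1
    population_overrides:
      dneg_females_cbp: {family: point, params: [1.0]}
  - event_id: X2
    label: Recipient is a female of childbearing potential (<50y)
    input_ref: N2
    population_overrides:
      dneg_females_cbp: {family: point, params: [1.0]}
  - event_id: X3
    label: Recipient has pre-existing anti-D
    input_ref: N3
  - event_id: X4
    label: HTR occurs at the index D-positive transfusion
    input_ref: N4
  - event_id: X5
    label: Index HTR causes major morbidity or death
    input_ref: N5
  - event_id: X6
    label: Recipient survives the index admission
    input_ref: N6
  - event_id: X7
    label: Recipient forms anti-D after the index transfusion
    input_ref: N7
  - event_id: X8
    label: Recipient receives a future D-positive transfusion
    input_ref: N8
  - event_id: X9
    label: Future transfusion is given before anti-D is detected
    input_ref: N9
  - event_id: X10
    label: HTR occurs at the future transfusion
    input_ref: N10
  - event_id: X11
    label: Future HTR causes major morbidity or death
    input_ref: N11
  - event_id: X12
    label: Recipient carries a future pregnancy
    input_ref: N12
  - event_id: X13
    label: Foetus is D-positive
    input_ref: N13
  - event_id: X14
    label: HDFN causes foetal death or lifelong disability
    input_ref: N14

harms:
  - harm_id: htr_index
    label: Major morbidity or mortality due to HTR from index D-positive transfusion
    chain: [X1, X3, X4, X5]
  - harm_id: htr_future
    label: Major morbidity or mortality due to future HTR
    chain: [X1, X6, X7, X8, X9, X10, X11]
  - harm_id: hdfn
    label: Foetal death or permanent disability due to anti-D HDFN in future pregnancy
    chain: [X1, X2, X6, X7, X12, X13, X14]

populations:
  - population_id: all_recipients
    label: All prehospital trauma recipients
    incidence_per_million_per_year: 83
    population_size: 67000000
    subgroup_fraction: 1.0
  - population_id: dneg_females_cbp
    label: D-negative females of childbearing potential (<50y)
    incidence_per_million_per_year: 83
    population_size: 67000000
    # chosen so the subgroup receives ~100 prehospital transfusions per year
    subgroup_fraction: 0.017982

life_years:
  life_years_lost_per_hdfn_event: 83
  bootstrap_samples: 10000
  survivor_life_years:
    # placeholder: life-years gained per trauma death averted
    family: triangular
    params: [20, 40, 60]
  survival_benefit_grid: {start: 0.0, stop: 2.0, step: 0.005}

mc:
  iterations: 1000
  seed: 1234
  ci_level: 0.95
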