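name: breast_panel
display_name: Breast cancer targeted panel
n_patients: 192
technology: panel
sample_design: germline_only
items:
  - label: blood sample collection
    step: sampling
    cost_type: other
    per_patient_cost: 25.05
  - label: extraction consumables
    step: dna_extraction
    cost_type: consumables
    per_patient_cost: 39.37
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 5.34
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 0.78
    note: "~0.017 h at AU$46.57/h incl. 20% overheads"
  - label: library preparation consumables
    step: library_preparation
    cost_type: consumables
    per_patient_cost: 149.67
  - label: library preparation labour
    step: library_preparation
    cost_type: labour
    per_patient_cost: 6.79
    note: "~0.15 h at AU$46.57/h incl. 20% overheads"
  - label: sequencing testing
    step: sequencing
    cost_type: testing
    per_patient_cost: 79.67
    note: includes MLPA for large-rearrangement detection
  - label: sequencing labour
    step: sequencing
    cost_type: labour
    per_patient_cost: 3.88
    note: "~0.08 h at AU$46.57/h incl. 20% overheads"
  - label: computing software
    step: analysis
    cost_type: equipment
    per_patient_cost: 3.20
    note: classified under equipment in the cost-type table
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 23.82
    note: "~0.46 h at AU$51.86/h incl. 20% overheads"
  - label: data storage (5-year cloud, nearline)
    step: data_storage
    cost_type: other
    per_patient_cost: 1.96
  - label: multidisciplinary team meeting
    step: clinician_reporting
    cost_type: labour
    per_patient_cost: 7.56
    note: held for 10% of cases; cost folded into the per-patient value
equipment:
  machine_per_patient: 22.46
  maintenance_per_patient: 11.23
metadata:
  setting: statewide health service (clinical)
  platform: Illumina MiSeq/NextSeq, in-house panel + MLPA
  coverage: 500X
  gb_per_sample: 2
  storage_tb_5yr: 28
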