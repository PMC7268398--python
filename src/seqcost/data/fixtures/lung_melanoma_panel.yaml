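name: lung_melanoma_panel
display_name: Lung cancer / melanoma targeted panel
n_patients: 745
technology: panel
sample_design: tumour_only
items:
  - label: tumour biopsy
    step: sampling
    cost_type: other
    per_patient_cost: 0.00
    note: biopsied and stored in the normal course of diagnosis; no cost attributed
  - label: extraction consumables
    step: dna_extraction
    cost_type: consumables
    per_patient_cost: 22.13
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 5.34
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 0.78
    note: "~0.017 h at AU$46.57/h incl. 20% overheads"
  - label: library prep & sequencing consumables
    step: library_preparation
    cost_type: consumables
    per_patient_cost: 322.23
    merged: true
    note: reagents, tips, beads, prep kit, plates; steps 3 and 4 costed jointly
  - label: pre-sequencing quality control
    step: library_preparation
    cost_type: testing
    per_patient_cost: 0.78
    merged: true
  - label: library prep & sequencing labour
    step: library_preparation
    cost_type: labour
    per_patient_cost: 6.31
    merged: true
    note: "~0.14 h at AU$46.57/h incl. 20% overheads"
  - label: computing software
    step: analysis
    cost_type: equipment
    per_patient_cost: 1.74
    note: classified under equipment in the cost-type table
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 59.74
    note: "~1.15 h at AU$51.86/h incl. 20% overheads"
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
  platform: Illumina MiSeq/NextSeq, TruSeq 26-gene panel
  coverage: 1000X
  gb_per_sample: 2
  storage_tb_5yr: 107
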