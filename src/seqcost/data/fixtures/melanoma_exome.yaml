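name: melanoma_exome
display_name: Melanoma exome (saliva samples)
n_patients: 383
technology: exome
sample_design: germline_only
items:
  - label: saliva self-collection kit
    step: sampling
    cost_type: other
    per_patient_cost: 27.50
  - label: extraction consumables
    step: dna_extraction
    cost_type: consumables
    per_patient_cost: 19.28
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 32.91
    note: includes Sanger sequencing validation
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 13.86
    note: "~0.30 h at AU$46.57/h incl. 20% overheads"
  - label: outsourced library prep & sequencing
    step: sequencing
    cost_type: testing
    per_patient_cost: 750.00
    merged: true
    note: commercial provider fee; library preparation not separable, bulk pricing
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 17.29
    note: "~0.33 h at AU$51.86/h incl. 20% overheads"
  - label: data storage (5-year cloud, nearline)
    step: data_storage
    cost_type: other
    per_patient_cost: 9.79
equipment:
  machine_per_patient: 61.58
  maintenance_per_patient: 30.79
metadata:
  setting: clinical research (pre-clinical; no clinician reporting)
  platform: Illumina NovaSeq (outsourced)
  coverage: ">100X"
  gb_per_sample: 10
  storage_tb_5yr: 275
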