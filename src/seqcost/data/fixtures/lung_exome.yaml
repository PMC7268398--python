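name: lung_exome
display_name: Lung cancer exome (tumour/blood pairs)
n_patients: 10
technology: exome
sample_design: tumour_germline_pair
items:
  - label: blood draw (tumour biopsy not costed)
    step: sampling
    cost_type: other
    per_patient_cost: 25.05
  - label: extraction consumables (blood and tumour kits)
    step: dna_extraction
    cost_type: consumables
    per_patient_cost: 39.99
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 81.50
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 63.86
    note: "~1.37 h at AU$46.57/h incl. 20% overheads"
  - label: library preparation consumables
    step: library_preparation
    cost_type: consumables
    per_patient_cost: 1050.21
  - label: pre-sequencing quality control
    step: library_preparation
    cost_type: testing
    per_patient_cost: 11.54
  - label: library preparation labour
    step: library_preparation
    cost_type: labour
    per_patient_cost: 139.72
    note: "~3.0 h at AU$46.57/h incl. 20% overheads"
  - label: sequencing testing
    step: sequencing
    cost_type: testing
    per_patient_cost: 1111.75
  - label: sequencing labour
    step: sequencing
    cost_type: labour
    per_patient_cost: 69.86
    note: "~1.5 h at AU$46.57/h incl. 20% overheads"
  - label: computing software
    step: analysis
    cost_type: equipment
    per_patient_cost: 0.73
    note: classified under equipment in the cost-type table
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 57.63
    note: "~1.11 h at AU$51.86/h incl. 20% overheads"
  - label: data storage (5-year cloud, nearline)
    step: data_storage
    cost_type: other
    per_patient_cost: 39.15
  - label: multidisciplinary team preparation
    step: clinician_reporting
    cost_type: labour
    per_patient_cost: 96.54
equipment:
  machine_per_patient: 131.01
  maintenance_per_patient: 65.51
metadata:
  setting: clinical research
  platform: Illumina NextSeq (in-house)
  coverage: 100-130X exome, 500-700X spiked-in panel
  gb_per_sample: 20
  storage_tb_5yr: 29
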