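name: mesothelioma_genome
display_name: Mesothelioma whole genome (tumour/blood pairs)
n_patients: 3
technology: genome
sample_design: tumour_germline_pair
items:
  - label: blood draw (tumour biopsy not costed)
    step: sampling
    cost_type: other
    per_patient_cost: 25.05
  - label: extraction consumables
    step: dna_extraction
    cost_type: consumables
    per_patient_cost: 72.69
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 139.90
    note: includes SNP arrays
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 31.05
    note: "~0.67 h at AU$46.57/h incl. 20% overheads"
  - label: outsourced library prep & sequencing
    step: sequencing
    cost_type: testing
    per_patient_cost: 1631.26
    merged: true
    note: commercial fee of USD 600/sample converted at 1.29038 AUD per USD
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 777.96
    note: "~15 h at AU$51.86/h incl. 20% overheads; small batch (3 patients)"
  - label: data storage (5-year cloud, nearline)
    step: data_storage
    cost_type: other
    per_patient_cost: 217.28
    note: ~222 GB per tumour/blood pair
equipment:
  machine_per_patient: 74.24
  maintenance_per_patient: 37.12
metadata:
  setting: research (pre-clinical; no clinician reporting)
  platform: BGISEQ-500 (outsourced)
  coverage: 28X blood, 50X tumour
  gb_per_sample: "150 tumour / 72 blood"
  storage_tb_5yr: 26
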