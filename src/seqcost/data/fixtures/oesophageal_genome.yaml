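name: oesophageal_genome
display_name: Oesophageal cancer whole genome (tumour/blood pairs)
n_patients: 100
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
    per_patient_cost: 84.19
    note: includes re-extraction for ~30% of tumour samples below 40% tumour content
  - label: validation / quality control
    step: dna_extraction
    cost_type: testing
    per_patient_cost: 180.70
    note: includes repeated quality control after tumour-sample rework
  - label: extraction labour
    step: dna_extraction
    cost_type: labour
    per_patient_cost: 35.39
    note: "~0.76 h at AU$46.57/h incl. 20% overheads"
  - label: outsourced library prep & sequencing
    step: sequencing
    cost_type: testing
    per_patient_cost: 4188.60
    merged: true
    note: commercial provider fee; library preparation not separable
  - label: analysis labour
    step: analysis
    cost_type: labour
    per_patient_cost: 98.54
    note: "~1.90 h at AU$51.86/h incl. 20% overheads"
  - label: data storage (5-year cloud, nearline)
    step: data_storage
    cost_type: other
    per_patient_cost: 217.28
    note: ~222 GB per tumour/blood pair
equipment:
  machine_per_patient: 62.45
  maintenance_per_patient: 31.22
metadata:
  setting: research (pre-clinical; no clinician reporting)
  platform: Illumina HiSeq XTen (outsourced)
  coverage: 30X blood, 60X tumour
  gb_per_sample: "150 tumour / 72 blood"
  storage_tb_5yr: 529
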