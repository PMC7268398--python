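# Standard one-way sensitivity scenario set.
scenarios:
  - name: library_prep_and_sequencing_price
    selector: {steps: [library_preparation, sequencing]}
    low: 0.9
    high: 1.1
  - name: labour_rates
    selector: {cost_type: labour}
    low: 0.8
    high: 1.2
  - name: storage_tier
    selector: {steps: [data_storage]}
    low: 0.7    # nearline (0.01 USD/GB-month) -> coldline (0.007)
    high: 2.5   # nearline -> regional (0.025)
  - name: capital_equipment
    selector: {capital: true}
    low: 0.8
    high: 1.2
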