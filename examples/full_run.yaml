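# Full-pipeline configuration on simulated study-sized data.
# Sampling budgets here favour a quick demonstration run; raise warmup/
# steps/target_ess for production-grade effective sample sizes.
stages: [hier, niche, overlap, classify]

isotope:
  simulate: default        # or: path: data/isotope_reference.csv
diet:
  simulate: default        # or: path: data/stomach_reference.csv

hier:
  chains: 3
  warmup: 1000
  steps: 1500
  draws: 3000
  target_ess: 200
  max_retries: 1

niche:
  ndraw: 4000

overlap:
  conf: 0.95
  nmc: 10000
  ndraw: 1000

classify:
  tasks:
    - {target: species}
    - {target: stage, species: N_entemedor}
    - {target: sex, species: N_entemedor}
  shap: true
  shap_rows: 40
  shap_samples: 24
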