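# Demo run: two synthetic reporting systems drawn from one generative
# specification, full analysis bundle (descriptives, overlap, pooled and
# sex-stratified screening).  Run with:
#   pvsignal run --config examples/demo_config.yaml
drug: DRUG-X
dictionary: bundled
simulate:
  n_reports: 4000
  doi_weight: 0.1
  two_source: true
criteria:
  min_a: 3
  prr_min: 2.0
  chi2_min: 4.0
  ci_z: 1.96
top_n: 30
stratify: [sex]
output_dir: out/demo
seed: 7
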