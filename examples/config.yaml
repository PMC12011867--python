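# Bundled synthetic demonstration scenario: simulate four quarters of
# FAERS-dialect data with planted pembrolizumab signals, then run the
# full signal-detection pipeline on them.
input_dir: example_run/input
output_dir: example_run/output
quarters: ["23Q1", "23Q2", "23Q3", "23Q4"]
seed: 4
top_frequency: 30
top_strength: 20
simulate:
  n_reports: 2000
  seed: 4
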