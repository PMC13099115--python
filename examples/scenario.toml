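# Example pipeline scenario: self-contained simulation + full analysis.
# Run:  ervkit run-all -c examples/scenario.toml -o example_out/toml_run --seed 7
seed = 7
rate = 2.3e-9
rate_interval = [2.0e-9, 2.5e-9]
min_methods = 2
bootstrap_replicates = 20

[simulation]
background_length = 300000
min_spacing = 30000
position_margin = 20000
endogenization_rate = 1.7

[mining]
flank_len = 16000

[annotation]
gene_cutoff = 0.25
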