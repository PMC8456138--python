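# Sex-bias turnover without true masculinization: female-only comparisons
# show apparent masculinization, males show the mirror-image feminization.
simulate:
  masculinization_m: 0.0
  turnover_tau: 0.3
  seed: 11
seed: 11
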