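# True masculinization of asexual females: female expression shifted 30%
# of the way toward the male state; no sex-bias turnover.
simulate:
  masculinization_m: 0.3
  turnover_tau: 0.0
  seed: 11
seed: 11
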