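# Null: no masculinization, no turnover; asexuals mirror their closest
# sexual relative except at the core/private asexuality genes.
simulate:
  masculinization_m: 0.0
  turnover_tau: 0.0
  seed: 11
seed: 11
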