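{
  "correct_only": 159,
  "distractor_horizontal": 59,
  "distractor_repetition": 133,
  "n_input": 200,
  "rt_window": 192,
  "sd_trim": 191
}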