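{
  "Src": {
    "cell_type": "RS",
    "C": 100.0,
    "v_r": -60.0,
    "v_t": -40.0,
    "v_p": 35.0,
    "k": 0.7,
    "a": 0.03,
    "b": -2.0,
    "c": -50.0,
    "d": 100.0
  },
  "Int": {
    "cell_type": "FS",
    "C": 20.0,
    "v_r": -55.0,
    "v_t": -40.0,
    "v_p": 25.0,
    "k": 1.0,
    "a": 0.2,
    "b": 0.025,
    "c": -45.0,
    "d": 0.0,
    "v_b": -55.0
  },
  "Tgt_subthreshold": {
    "cell_type": "RS",
    "C": 100.0,
    "v_r": -60.0,
    "v_t": -40.0,
    "v_p": 35.0,
    "k": 0.7,
    "a": 0.03,
    "b": -2.0,
    "c": -50.0,
    "d": 100.0
  },
  "Tgt_network": {
    "cell_type": "RS",
    "C": 50.0,
    "v_r": -60.0,
    "v_t": -45.0,
    "v_p": 35.0,
    "k": 0.7,
    "a": 0.03,
    "b": -2.0,
    "c": -50.0,
    "d": 100.0
  }
}
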