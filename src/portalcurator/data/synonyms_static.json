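{
  "palliative": {
    "direct": ["alleviative", "preventative", "lenitive"],
    "inherited": ["curative", "remedial", "therapeutic"]
  },
  "care": {
    "direct": ["aid", "attention", "tending"],
    "inherited": ["work", "action", "procedure"]
  }
}
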