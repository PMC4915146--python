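name: ecoli_ccm
growth:
  mode: atp
  expression: null
knocked_out: []
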