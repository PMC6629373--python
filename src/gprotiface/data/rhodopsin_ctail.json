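{
  "receptor_id": "bovine_rhodopsin",
  "receptor_chain": "R",
  "h8_end": 321,
  "tail_range": [
    324,
    335
  ],
  "full_length_tail": [
    324,
    348
  ],
  "hinges": [
    324,
    327,
    329
  ],
  "phosphosites": [
    334,
    336,
    338,
    340,
    342,
    343
  ]
}
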