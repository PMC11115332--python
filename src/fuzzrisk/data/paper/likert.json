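{
  "note": "Default five-point odd-valued Likert mapping used for expert validation triples; user-overridable.",
  "levels": {
    "Strongly Disagree": 1,
    "Disagree": 3,
    "Neutral": 5,
    "Agree": 7,
    "Strongly Agree": 9
  }
}
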