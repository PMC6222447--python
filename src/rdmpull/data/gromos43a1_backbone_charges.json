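{
  "comment": "Backbone partial charges (elementary charge units) transcribed by hand from the published GROMOS 43A1 united-atom force field. Two neutral backbone charge groups per residue: the amide group (N, H) and the carbonyl group (C, O); CA is its own neutral group. Proline has a tertiary amide nitrogen with no amide hydrogen and a neutral N group.",
  "default": {
    "charges": {"N": -0.28, "H": 0.28, "CA": 0.0, "C": 0.38, "O": -0.38},
    "groups": [["N", "H"], ["CA"], ["C", "O"]]
  },
  "PRO": {
    "charges": {"N": 0.0, "CA": 0.0, "C": 0.38, "O": -0.38},
    "groups": [["N"], ["CA"], ["C", "O"]]
  }
}
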