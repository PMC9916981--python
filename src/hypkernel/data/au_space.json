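{
  "version": 1,
  "description": "Canonical 33-dimensional action-unit space for facial-expression stimuli: compound AUs are expanded into their constituents and bilateral AUs into independent left/right variables.",
  "canonical_order": [
    "1", "2L", "2R", "4", "5", "6L", "6R", "7L", "7R", "9",
    "10L", "10R", "11L", "11R", "12L", "12R", "13", "14L", "14R", "15",
    "16", "17", "20L", "20R", "22", "23", "24", "25", "26", "27",
    "38", "39", "43"
  ],
  "compounds": {
    "1+2": [1, 2],
    "6+12": [6, 12],
    "12+25": [12, 25]
  },
  "lateralized": [2, 6, 7, 10, 11, 12, 14, 20]
}
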