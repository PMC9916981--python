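{
  "version": 1,
  "tasks": {
    "basic6": {
      "categories": ["anger", "disgust", "fear", "happy", "sadness", "surprise"],
      "other_label": "other"
    },
    "conversational4": {
      "categories": ["bored", "confused", "interested", "thinking"],
      "other_label": "other"
    }
  }
}
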