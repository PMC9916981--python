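{
  "version": 1,
  "task": "conversational4",
  "description": "Registry slots for action-unit models of four conversational signals (bored, confused, interested, thinking). The published AU configurations for these five studies are not bundled; supply them as spec strings or explicit AU lists. Models may cover only a subset of the task's categories.",
  "models": [
    {"name": "cunningham_2005", "task": "conversational4", "categories": {}},
    {"name": "ekman_1979", "task": "conversational4", "categories": {}},
    {"name": "unnamed_study_3", "task": "conversational4", "categories": {}},
    {"name": "el_kaliouby_robinson_2005", "task": "conversational4", "categories": {}},
    {"name": "unnamed_study_5", "task": "conversational4", "categories": {}}
  ]
}
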