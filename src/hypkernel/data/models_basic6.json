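{
  "version": 1,
  "task": "basic6",
  "description": "Seven published action-unit models of the six basic emotions. Notation: '+' joins co-occurring AUs, AUs after a comma are optional, '(a ∨ b)' is a mutually exclusive alternation, and list entries are separate explicitly proposed configurations.",
  "models": [
    {
      "name": "darwin_1872",
      "task": "basic6",
      "categories": {
        "anger": ["4 + 5 + 24 + 38"],
        "disgust": ["10 + 16 + 22 + 25 + 26"],
        "fear": ["1 + 2 + 5 + 20"],
        "happy": ["6 + 12"],
        "sadness": ["1 + 15"],
        "surprise": ["1 + 2 + 5 + 25 + 26"]
      }
    },
    {
      "name": "friesen_ekman_1978",
      "task": "basic6",
      "categories": {
        "anger": [
          "4 + 5 + 7 + 10 + 22 + 23 + (25 ∨ 26)",
          "4 + 5 + 7 + 10 + 23 + (25 ∨ 26)",
          "4 + 5 + 7 + 17 + (23 ∨ 24)",
          "4 + 5 + 7 + (23 ∨ 24)",
          "4 + (5 ∨ 7)",
          "17 + 24"
        ],
        "disgust": [
          "(9 ∨ 10) + 17",
          "(9 ∨ 10)",
          "(9 ∨ 10) + 16 + (25 ∨ 26)"
        ],
        "fear": [
          "1 + 2 + 4",
          "1 + 2 + 4 + 5 + 20 + (25 ∨ 26 ∨ 27)",
          "1 + 2 + 4 + 5 + (25 ∨ 26 ∨ 27)",
          "1 + 2 + 4 + 5",
          "1 + 2 + 5 + (25 ∨ 26 ∨ 27)",
          "5 + 20 + (25 ∨ 26 ∨ 27)",
          "5 + 20",
          "20"
        ],
        "happy": ["12", "6 + 12"],
        "sadness": [
          "1 + 4",
          "1 + 4 + (11 ∨ 15)",
          "1 + 4 + 15 + 17",
          "6 + 15",
          "11 + 17",
          "1"
        ],
        "surprise": [
          "1 + 2 + 5 + (26 ∨ 27)",
          "1 + 2 + 5",
          "1 + 2 + (26 ∨ 27)",
          "5 + (26 ∨ 27)"
        ]
      }
    },
    {
      "name": "matsumoto_2008",
      "task": "basic6",
      "categories": {
        "anger": ["4 + (5 ∨ 7) + 22 + 23 + 24"],
        "disgust": ["(9 ∨ 10), (25 ∨ 26)"],
        "fear": ["1 + 2 + 4 + 5 + 20, (25 ∨ 26)"],
        "happy": ["6 + 12"],
        "sadness": ["1 + 15, 4, 17"],
        "surprise": ["1 + 2 + 5 + (25 ∨ 26)"]
      }
    },
    {
      "name": "cordaro_2018_ref",
      "task": "basic6",
      "categories": {
        "anger": ["4 + 5 + 7 + 23"],
        "disgust": ["9 + 15 + 16"],
        "fear": ["1 + 2 + 4 + 5 + 20 + 25 + 26"],
        "happy": ["6 + 12"],
        "sadness": ["1 + 4 + 5"],
        "surprise": ["1 + 2 + 5 + 26"]
      }
    },
    {
      "name": "cordaro_2018_icp",
      "task": "basic6",
      "categories": {
        "anger": ["4 + 7"],
        "disgust": ["4 + 6 + 7 + 9 + 10 + 25 + (26 ∨ 27)"],
        "fear": ["1 + 2 + 5 + 7 + 25 + (26 ∨ 27)"],
        "happy": ["6 + 7 + 12 + 16 + 25 + (26 ∨ 27)"],
        "sadness": ["4 + 43"],
        "surprise": ["1 + 2 + 5 + 25 + (26 ∨ 27)"]
      }
    },
    {
      "name": "keltner_2019",
      "task": "basic6",
      "categories": {
        "anger": ["4 + 5 + 17 + 23 + 24"],
        "disgust": ["7 + 9 + 19 + 25 + 26"],
        "fear": ["1 + 2 + 4 + 5 + 7 + 20 + 25"],
        "happy": ["6 + 7 + 12 + 25 + 26"],
        "sadness": ["1 + 4 + 6 + 15 + 17"],
        "surprise": ["1 + 2 + 5 + 25 + 26"]
      }
    },
    {
      "name": "jack_2014",
      "task": "basic6",
      "categories": {
        "anger": ["9 + 10 + 16 + 22"],
        "disgust": ["9 + 10 + 11 + 43"],
        "fear": ["4 + 5 + 20"],
        "happy": ["6 + 12 + 13 + 14 + 25"],
        "sadness": ["4 + 15 + 17 + 24 + 43"],
        "surprise": ["1 + 2 + 5 + 26 + 27"]
      }
    }
  ]
}
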