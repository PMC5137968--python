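{
  "categories": ["registration", "attention", "recall"],
  "centroids": {
    "cognisant":   {"registration": 100.0, "attention": 98.0, "recall": 83.3},
    "inattentive": {"registration": 93.3,  "attention": 44.0, "recall": 83.3},
    "forgetful":   {"registration": 93.3,  "attention": 94.0, "recall": 13.3},
    "distant":     {"registration": 100.0, "attention": 21.0, "recall": 6.7},
    "absent":      {"registration": 43.3,  "attention": 18.0, "recall": 0.0}
  },
  "provenance": "Published training-set signature: mean success rates of the five cognitive groups over the three selected categories."
}
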