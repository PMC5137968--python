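{
  "mmse30": {
    "name": "mmse30",
    "max_points": {
      "orientation": 10,
      "registration": 3,
      "attention": 5,
      "recall": 3,
      "language": 9
    }
  },
  "mmse56": {
    "name": "mmse56",
    "max_points": {
      "orientation": 20,
      "registration": 6,
      "attention": 10,
      "recall": 6,
      "language": 14
    }
  },
  "mmse51": {
    "name": "mmse51",
    "max_points": {
      "orientation": 20,
      "registration": 6,
      "attention": 5,
      "recall": 6,
      "language": 14
    }
  }
}
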