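{
  "cpts": {
    "D1": {
      "parents": [
        "S1",
        "S4"
      ],
      "rows": {
        "00": 0.0,
        "01": 1.0,
        "10": 1.0,
        "11": 1.0
      }
    },
    "D2": {
      "parents": [
        "S5",
        "S6"
      ],
      "rows": {
        "00": 0.0,
        "01": 1.0,
        "10": 1.0,
        "11": 1.0
      }
    },
    "D3": {
      "parents": [
        "S3"
      ],
      "rows": {
        "0": 0.05,
        "1": 0.95
      }
    },
    "S1": {
      "parents": [],
      "rows": {
        "": 0.2681855344189046
      }
    },
    "S2": {
      "parents": [],
      "rows": {
        "": 0.5085335717720239
      }
    },
    "S3": {
      "parents": [
        "S2"
      ],
      "rows": {
        "0": 0.1,
        "1": 0.85
      }
    },
    "S4": {
      "parents": [
        "S1",
        "S2"
      ],
      "rows": {
        "00": 0.028,
        "01": 1.0,
        "10": 0.0,
        "11": 1.0
      }
    },
    "S5": {
      "parents": [],
      "rows": {
        "": 0.40335894808641476
      }
    },
    "S6": {
      "parents": [
        "S2",
        "S3"
      ],
      "rows": {
        "00": 1.0,
        "01": 0.0,
        "10": 0.0,
        "11": 1.0
      }
    }
  },
  "nodes": [
    "S1",
    "S2",
    "S3",
    "S4",
    "S5",
    "S6",
    "D1",
    "D2",
    "D3"
  ]
}
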