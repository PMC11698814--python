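{
  "version": "EAR-norms-1.0",
  "citation": "Normative study of the Emotion Authenticity Recognition (EAR) test, 522 healthy Italian adults; regression-based age/sex adjustment with Equivalent Scores standardisation.",
  "norms": {
    "n": 522,
    "coverage_p": 0.05,
    "confidence": 0.95,
    "ER": {
      "adjustment": {
        "beta_age2": 0.002,
        "centering_c": 1811.257,
        "sex_offset": 0.818
      },
      "validity_age_range": [
        17,
        88
      ],
      "oTL": 42.35,
      "iTL": 44.71,
      "es_thresholds": [
        42.35,
        46.09,
        48.87,
        51.45
      ]
    },
    "EA": {
      "adjustment": {
        "beta_age2": 0.002,
        "centering_c": 1811.257,
        "sex_offset": 0.42
      },
      "validity_age_range": [
        17,
        88
      ],
      "oTL": 41.25,
      "iTL": 43.23,
      "es_thresholds": [
        41.25,
        45.09,
        47.77,
        50.62
      ]
    }
  },
  "checksum": "bc179397c4f53e7fb493fef51efcf1286d3fe0388d04f05f8a87b446ed269b68"
}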