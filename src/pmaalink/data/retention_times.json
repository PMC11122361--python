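{
  "description": "Invented retention-time library for a 60 m medium-polarity column, minutes. Monotone spacing follows the usual elution order (lighter, less-acetylated PMAAs first); values make no claim of matching any real column. Co-elution groups are the chain-reversal symmetric pairs, which share a single peak.",
  "entries": {
    "t-Xylp":        {"rt": 28.0, "tolerance": 0.15},
    "t-Araf":        {"rt": 29.5, "tolerance": 0.15},
    "2-Xylp":        {"rt": 31.5, "tolerance": 0.15},
    "4-Xylp":        {"rt": 31.5, "tolerance": 0.15},
    "3-Xylp":        {"rt": 33.0, "tolerance": 0.15},
    "2,4-Xylp":      {"rt": 36.0, "tolerance": 0.15},
    "3,4-Xylp":      {"rt": 37.5, "tolerance": 0.15},
    "t-Glcp":        {"rt": 40.0, "tolerance": 0.15},
    "t-Galp":        {"rt": 41.5, "tolerance": 0.15},
    "4-AnGalp":      {"rt": 44.0, "tolerance": 0.15},
    "2,4-AnGalp":    {"rt": 47.0, "tolerance": 0.15},
    "3-Galp":        {"rt": 52.0, "tolerance": 0.15},
    "4-Glcp":        {"rt": 54.0, "tolerance": 0.15},
    "4-Galp":        {"rt": 56.0, "tolerance": 0.15},
    "4-Manp":        {"rt": 57.5, "tolerance": 0.15},
    "2,3-Galp":      {"rt": 60.0, "tolerance": 0.15},
    "2,4-Galp":      {"rt": 62.0, "tolerance": 0.15},
    "3,4-Galp":      {"rt": 64.0, "tolerance": 0.15},
    "3,6-Galp":      {"rt": 66.0, "tolerance": 0.15},
    "4,6-Glcp":      {"rt": 68.0, "tolerance": 0.15},
    "4,6-Galp":      {"rt": 70.0, "tolerance": 0.15},
    "2,6-Galp":      {"rt": 71.5, "tolerance": 0.15},
    "2,3,6-Galp":    {"rt": 74.0, "tolerance": 0.15},
    "2,4,6-Galp":    {"rt": 74.0, "tolerance": 0.15},
    "3,4,6-Galp":    {"rt": 77.0, "tolerance": 0.15},
    "2,3,4,6-Galp":  {"rt": 82.0, "tolerance": 0.15}
  },
  "coelution_groups": {
    "xylp_2_4": ["2-Xylp", "4-Xylp"],
    "galp_236_246": ["2,3,6-Galp", "2,4,6-Galp"]
  }
}
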