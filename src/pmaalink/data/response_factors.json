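{
  "description": "Relative FID molar response factors per PMAA label. The 3-Galp, 4-AnGalp and 2,4-AnGalp values are the experimentally anchored ones; remaining entries extend per-sugar-class terminal baselines (hexose 0.69, pentose 0.59, deoxyhexose 0.66) by +0.05 per acetyl-for-methyl substitution, consistent with the shipped increment rule. Curated defaults: edit freely.",
  "entries": {
    "t-Glcp": 0.69,
    "t-Galp": 0.69,
    "3-Galp": 0.74,
    "4-Galp": 0.74,
    "4-Glcp": 0.74,
    "4-Manp": 0.74,
    "2,3-Galp": 0.79,
    "2,4-Galp": 0.79,
    "2,6-Galp": 0.79,
    "3,4-Galp": 0.79,
    "3,6-Galp": 0.79,
    "4,6-Galp": 0.79,
    "4,6-Glcp": 0.79,
    "2,3,6-Galp": 0.84,
    "2,4,6-Galp": 0.84,
    "3,4,6-Galp": 0.84,
    "2,3,4,6-Galp": 0.89,
    "t-Xylp": 0.59,
    "t-Araf": 0.59,
    "2-Xylp": 0.64,
    "3-Xylp": 0.64,
    "4-Xylp": 0.64,
    "5-Araf": 0.64,
    "2,4-Xylp": 0.69,
    "3,4-Xylp": 0.69,
    "t-Rhap": 0.66,
    "t-Fucp": 0.66,
    "2-Rhap": 0.71,
    "4-AnGalp": 0.49
  },
  "increment_rules": [
    {"position": 2, "delta": 0.05, "note": "acetyl replacing methyl at O-2"}
  ]
}
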