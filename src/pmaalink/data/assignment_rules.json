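{
  "description": "Ordered rules assigning relative linkage percentages to polysaccharide structures. Rules consume from a shared pool of remaining linkage percentages; leftovers fall into the residual bucket. Floridean starch expands its 4,6-Glcp branch-point share by the average degree of branching (one branch per 4.8 residues), drawing the backbone residues from the 4-Glcp pool.",
  "residual": "residual",
  "rules": [
    {"name": "Floridean starch", "type": "branch_expand", "branch": "4,6-Glcp", "backbone": "4-Glcp", "degree": 4.8},
    {"name": "cellulose", "type": "sum", "labels": ["4-Glcp"]},
    {"name": "agarose", "type": "min_pair", "labels": ["4-AnGalp", "3-Galp"]},
    {"name": "mixed-linkage xylan", "type": "sum", "labels": ["3-Xylp", "4-Xylp", "2,4-Xylp", "3,4-Xylp"]},
    {"name": "other galactans", "type": "sugar_remainder", "sugars": ["Gal"]}
  ]
}
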