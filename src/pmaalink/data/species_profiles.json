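{
  "description": "Synthetic default linkage profiles (relative mol percent) for six red seaweeds, used by the dataset simulator. The prominent per-species values follow published ranges for these taxa; minor unreported linkages are plausible fill chosen once so each profile sums to 100. These are simulator ground truths, not measured data.",
  "profiles": {
    "Palmaria palmata": {
      "3-Xylp": 18, "4-Xylp": 54, "2,4-Xylp": 1, "3,4-Xylp": 1, "t-Xylp": 2,
      "2-Xylp": 1, "4-Glcp": 5, "4,6-Glcp": 1, "3-Galp": 5, "4-AnGalp": 1,
      "3,4-Galp": 2, "4-Galp": 2, "3,6-Galp": 1, "t-Galp": 1, "t-Araf": 2,
      "4-Manp": 3
    },
    "Gracilariopsis sp.": {
      "3-Galp": 40, "4-AnGalp": 27, "4-Galp": 2, "2,4-Galp": 1, "3,4-Galp": 1,
      "4,6-Galp": 3, "2,4,6-Galp": 2, "2,3,4,6-Galp": 1, "2,3,6-Galp": 1,
      "3,6-Galp": 3, "2,3-Galp": 2, "t-Galp": 1, "4-Glcp": 8, "4,6-Glcp": 1,
      "t-Glcp": 2, "t-Xylp": 1, "2-Xylp": 1, "3-Xylp": 1, "4-Xylp": 2
    },
    "Prionitis sp.": {
      "3-Galp": 30, "4-AnGalp": 12, "3,4-Galp": 11, "2,4-Galp": 6, "4-Galp": 5,
      "3,6-Galp": 5, "3,4,6-Galp": 4, "2,3-Galp": 4, "4,6-Galp": 2,
      "2,3,4,6-Galp": 2, "2,4-AnGalp": 1, "2,4,6-Galp": 1, "2,3,6-Galp": 1,
      "t-Xylp": 2, "t-Galp": 1, "4-Glcp": 6, "4,6-Glcp": 1, "4-Xylp": 3,
      "3-Xylp": 1, "2-Xylp": 1, "t-Glcp": 1
    },
    "Callophyllis sp.": {
      "4-AnGalp": 16, "3,6-Galp": 15, "2,3-Galp": 7, "3-Galp": 6, "3,4-Galp": 4,
      "2,4,6-Galp": 2, "2,4-AnGalp": 2, "4,6-Galp": 2, "4-Glcp": 15,
      "2,3,6-Galp": 3, "2,4-Galp": 4, "2,3,4,6-Galp": 3, "3,4,6-Galp": 3,
      "4-Galp": 3, "4,6-Glcp": 2, "4-Xylp": 4, "3-Xylp": 2, "2-Xylp": 2,
      "t-Glcp": 2, "2,6-Galp": 3
    },
    "Mastocarpus papillatus": {
      "4-AnGalp": 22, "2,4-AnGalp": 12, "3,4-Galp": 46, "4,6-Galp": 1,
      "2,4,6-Galp": 1, "3-Galp": 5, "4-Glcp": 3, "2,3-Galp": 2, "4-Galp": 2,
      "3-Xylp": 1, "4-Xylp": 2, "t-Xylp": 1, "4,6-Glcp": 1, "2,3,6-Galp": 1
    },
    "Mazzaella splendens": {
      "3,4-Galp": 20, "2,3-Galp": 18, "3-Galp": 12, "4-AnGalp": 10,
      "2,4,6-Galp": 10, "2,4-AnGalp": 8, "4,6-Galp": 2, "2,4-Galp": 2,
      "4-Galp": 3, "4-Glcp": 6, "4,6-Glcp": 1, "4-Xylp": 2, "3-Xylp": 1,
      "t-Xylp": 1, "2,3,6-Galp": 2, "3,6-Galp": 2
    }
  }
}
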