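{
  "_comment": "Printed 3x3 cross-tabulation counts (rows = traditional risk score tertile, columns = polygenic risk score tertile) from the two population-based melanoma case-control studies (Australia, early-onset; Leeds, UK, unrestricted age).",
  "australia": {
    "counts": [[223, 91, 30], [94, 160, 91], [27, 94, 225]],
    "n": 1035
  },
  "leeds": {
    "counts": [[244, 138, 104], [153, 209, 125], [89, 140, 258]],
    "n": 1460
  }
}
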