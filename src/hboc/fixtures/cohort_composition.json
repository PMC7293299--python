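{
  "group1_tested_negative": 230,
  "group2_untested": 436,
  "group2_brca1_positive": 37,
  "group2_brca2_positive": 44,
  "group2_brca1_brca2_positive": 1,
  "group2_vus": 16,
  "group2_wildtype": 338,
  "n_wildtype_cases": 568,
  "n_wildtype_breast": 534,
  "n_wildtype_ovary": 29,
  "n_wildtype_synchronous": 5
}
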