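{
  "database": {
    "n_ici_event_records": 353949,
    "n_total_event_records": 49568379
  },
  "scan_counts": {
    "Autoimmune hepatitis": {"n_ici": 634, "n_other": 4566},
    "Immune-mediated hepatitis": {"n_ici": 546, "n_other": 350},
    "Hepatitis fulminant": {"n_ici": 80, "n_other": 2439}
  },
  "strategy_totals": {
    "pd1_pdl1_mono": 268517,
    "ctla4_mono": 22903,
    "dual": 62530
  },
  "strategy_counts": {
    "Autoimmune hepatitis": {"pd1_pdl1_mono": 352, "ctla4_mono": 63, "dual": 219},
    "Immune-mediated hepatitis": {"pd1_pdl1_mono": 336, "ctla4_mono": 8, "dual": 202},
    "Hepatitis fulminant": {"pd1_pdl1_mono": 54, "ctla4_mono": 4, "dual": 22}
  },
  "per_drug_counts": {
    "Cemiplimab": {"hrae": 22, "total": 9906},
    "Nivolumab": {"hrae": 576, "total": 471495},
    "Pembrolizumab": {"hrae": 320, "total": 298395},
    "Atezolizumab": {"hrae": 111, "total": 104568},
    "Avelumab": {"hrae": 13, "total": 6798},
    "Durvalumab": {"hrae": 38, "total": 43278},
    "Ipilimumab": {"hrae": 179, "total": 123792}
  },
  "trial_incidence_pct": {"dual": 6.5, "mono": 3.8},
  "published": {
    "t1": 19.34,
    "t2": 17.80,
    "t3": 21.02,
    "t4": 217.24,
    "t5": 4.56,
    "t6": 3.65,
    "t7": 3.59,
    "t8": 2.74,
    "t9": 2.46,
    "t10": 0.84,
    "t11": 1.71,
    "imh_ror05": 189.95,
    "imh_ror95": 248.45,
    "fulminant_ror95": 5.70
  }
}
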