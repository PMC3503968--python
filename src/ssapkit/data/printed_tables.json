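{
  "te_families": ["Au", "TS", "Ns1", "Nt2", "Tnt1", "Tnt2", "TRIM"],
  "polyploids": ["NUD", "REP", "ISL"],
  "maternal_diploid": "SYL",
  "paternal_diploid": "TRI",
  "category_order": ["NUD+REP+ISL", "NUD+REP", "NUD+ISL", "REP+ISL", "NUD", "REP", "ISL"],
  "table3": {
    "Au":   {"total": 87, "shared": [15, 17.2], "paternal_specific": [37, 42.5], "maternal_specific": [35, 40.2], "chi_square": null, "direction": "NS"},
    "TS":   {"total": 30, "shared": [2, 6.7],  "paternal_specific": [15, 50.0], "maternal_specific": [13, 43.3], "chi_square": null, "direction": "NS"},
    "Ns1":  {"total": 66, "shared": [10, 15.1], "paternal_specific": [18, 27.3], "maternal_specific": [38, 57.6], "chi_square": 12.89, "direction": "T<S"},
    "Nt2":  {"total": 58, "shared": [8, 13.8],  "paternal_specific": [35, 60.3], "maternal_specific": [15, 25.9], "chi_square": 14.44, "direction": "T>S"},
    "Tnt1": {"total": 56, "shared": [3, 5.3],   "paternal_specific": [31, 55.4], "maternal_specific": [22, 39.3], "chi_square": null, "direction": "NS"},
    "Tnt2": {"total": 63, "shared": [5, 7.9],   "paternal_specific": [19, 30.2], "maternal_specific": [39, 61.9], "chi_square": 12.45, "direction": "T<S"},
    "TRIM": {"total": 66, "shared": [11, 16.6], "paternal_specific": [30, 45.5], "maternal_specific": [25, 37.9], "chi_square": null, "direction": "NS"},
    "_totals": {"total": 426, "shared": 54, "paternal_specific": 185, "maternal_specific": 187}
  },
  "table4": {
    "NUD": {
      "Au": [0.733, 0.628, 0.819], "TS": [0.953, 0.830, 0.992], "Ns1": [0.855, 0.737, 0.927],
      "Nt2": [0.767, 0.651, 0.855], "Tnt1": [0.851, 0.738, 0.922], "Tnt2": [0.900, 0.788, 0.959],
      "TRIM": [0.797, 0.668, 0.886]
    },
    "REP": {
      "Au": [0.840, 0.738, 0.909], "TS": [0.927, 0.790, 0.981], "Ns1": [0.912, 0.822, 0.977],
      "Nt2": [0.867, 0.749, 0.937], "Tnt1": [0.875, 0.753, 0.944], "Tnt2": [0.864, 0.745, 0.936],
      "TRIM": [0.774, 0.635, 0.873]
    },
    "ISL": {
      "Au": [0.817, 0.713, 0.891], "TS": [0.891, 0.756, 0.959], "Ns1": [0.903, 0.795, 0.960],
      "Nt2": [0.809, 0.692, 0.890], "Tnt1": [0.844, 0.727, 0.919], "Tnt2": [0.912, 0.800, 0.967],
      "TRIM": [0.769, 0.628, 0.870]
    }
  },
  "table5_new": {
    "Au":   {"in_all": [21, 24.1], "per_taxon": {"NUD": [17, 81], "REP": [11, 52.4], "ISL": [12, 57.1]},
             "categories": {"NUD+REP+ISL": [3, 14.3], "NUD+REP": [6, 28.6], "NUD+ISL": [7, 33.3], "REP+ISL": [0, 0], "NUD": [1, 4.8], "REP": [2, 9.5], "ISL": [2, 9.5]}},
    "TS":   {"in_all": [32, 106], "per_taxon": {"NUD": [22, 68.8], "REP": [19, 59.4], "ISL": [21, 65.6]},
             "categories": {"NUD+REP+ISL": [8, 25], "NUD+REP": [4, 12.5], "NUD+ISL": [6, 18.8], "REP+ISL": [4, 12.5], "NUD": [4, 12.5], "REP": [3, 9.4], "ISL": [3, 9.4]}},
    "Ns1":  {"in_all": [23, 34.8], "per_taxon": {"NUD": [17, 73.9], "REP": [9, 39.1], "ISL": [14, 60.9]},
             "categories": {"NUD+REP+ISL": [3, 13], "NUD+REP": [0, 0], "NUD+ISL": [10, 43.5], "REP+ISL": [1, 4.3], "NUD": [4, 17.4], "REP": [5, 21.7], "ISL": [0, 0]}},
    "Nt2":  {"in_all": [28, 48.3], "per_taxon": {"NUD": [24, 85.7], "REP": [5, 17.9], "ISL": [17, 60.7]},
             "categories": {"NUD+REP+ISL": [2, 7.1], "NUD+REP": [2, 7.1], "NUD+ISL": [12, 42.9], "REP+ISL": [0, 0], "NUD": [8, 28.6], "REP": [1, 3.6], "ISL": [3, 10.7]}},
    "Tnt1": {"in_all": [21, 37.5], "per_taxon": {"NUD": [14, 66.7], "REP": [7, 33.3], "ISL": [8, 38.1]},
             "categories": {"NUD+REP+ISL": [1, 4.8], "NUD+REP": [0, 0], "NUD+ISL": [6, 28.6], "REP+ISL": [0, 0], "NUD": [7, 33.3], "REP": [6, 28.6], "ISL": [1, 4.8]}},
    "Tnt2": {"in_all": [34, 54.0], "per_taxon": {"NUD": [20, 58.8], "REP": [24, 70.6], "ISL": [20, 58.8]},
             "categories": {"NUD+REP+ISL": [9, 26.5], "NUD+REP": [4, 11.8], "NUD+ISL": [6, 17.6], "REP+ISL": [2, 5.9], "NUD": [1, 2.9], "REP": [9, 26.5], "ISL": [3, 8.8]}},
    "TRIM": {"in_all": [11, 16.7], "per_taxon": {"NUD": [8, 72.7], "REP": [9, 81.8], "ISL": [7, 63.6]},
             "categories": {"NUD+REP+ISL": [4, 36.4], "NUD+REP": [2, 18.2], "NUD+ISL": [2, 18.2], "REP+ISL": [1, 9.1], "NUD": [0, 0], "REP": [2, 18.2], "ISL": [0, 0]}},
    "_all_tes": {"in_all": [170, 39.9], "per_taxon": {"NUD": [122, 71.8], "REP": [82, 48.2], "ISL": [99, 58.2]},
                 "categories": {"NUD+REP+ISL": [30, 17.6], "NUD+REP": [18, 10.6], "NUD+ISL": [49, 28.8], "REP+ISL": [8, 4.7], "NUD": [25, 14.7], "REP": [28, 16.5], "ISL": [12, 7.1]}}
  },
  "table5_lost": {
    "Au":   {"in_all": [71, 81.6], "per_taxon": {"NUD": [49, 56.3], "REP": [57, 65.5], "ISL": [55, 63.2]},
             "categories": {"NUD+REP+ISL": [35, 49.3], "NUD+REP": [3, 4.2], "NUD+ISL": [8, 11.3], "REP+ISL": [9, 12.7], "NUD": [3, 4.2], "REP": [10, 14.1], "ISL": [3, 4.2]}},
    "TS":   {"in_all": [26, 86.7], "per_taxon": {"NUD": [19, 63.3], "REP": [19, 63.3], "ISL": [23, 76.7]},
             "categories": {"NUD+REP+ISL": [14, 53.8], "NUD+REP": [2, 7.7], "NUD+ISL": [2, 7.7], "REP+ISL": [3, 11.5], "NUD": [1, 3.8], "REP": [0, 0], "ISL": [4, 15.4]}},
    "Ns1":  {"in_all": [58, 87.9], "per_taxon": {"NUD": [36, 54.5], "REP": [43, 65.2], "ISL": [42, 63.6]},
             "categories": {"NUD+REP+ISL": [24, 41.4], "NUD+REP": [1, 1.7], "NUD+ISL": [9, 15.5], "REP+ISL": [5, 8.6], "NUD": [2, 3.4], "REP": [13, 22.4], "ISL": [4, 6.9]}},
    "Nt2":  {"in_all": [51, 87.9], "per_taxon": {"NUD": [32, 55.2], "REP": [46, 79.3], "ISL": [38, 65.5]},
             "categories": {"NUD+REP+ISL": [28, 54.9], "NUD+REP": [0, 0], "NUD+ISL": [3, 5.9], "REP+ISL": [6, 11.8], "NUD": [1, 2], "REP": [12, 23.5], "ISL": [1, 2]}},
    "Tnt1": {"in_all": [54, 96.4], "per_taxon": {"NUD": [43, 76.8], "REP": [42, 75], "ISL": [46, 82.1]},
             "categories": {"NUD+REP+ISL": [31, 57.4], "NUD+REP": [0, 0], "NUD+ISL": [10, 18.6], "REP+ISL": [5, 9.3], "NUD": [2, 3.7], "REP": [6, 11.1], "ISL": [0, 0]}},
    "Tnt2": {"in_all": [45, 71.4], "per_taxon": {"NUD": [34, 54], "REP": [27, 42.9], "ISL": [32, 50.8]},
             "categories": {"NUD+REP+ISL": [14, 31.1], "NUD+REP": [2, 4.4], "NUD+ISL": [13, 28.9], "REP+ISL": [5, 11.1], "NUD": [5, 11.1], "REP": [6, 13.3], "ISL": [0, 0]}},
    "TRIM": {"in_all": [46, 69.7], "per_taxon": {"NUD": [39, 59.1], "REP": [32, 48.5], "ISL": [33, 50]},
             "categories": {"NUD+REP+ISL": [24, 52.2], "NUD+REP": [2, 4.3], "NUD+ISL": [7, 15.2], "REP+ISL": [1, 2.2], "NUD": [6, 13.0], "REP": [5, 10.9], "ISL": [1, 2.2]}},
    "_all_tes": {"in_all": [351, 82.4], "per_taxon": {"NUD": [252, 59.2], "REP": [266, 62.4], "ISL": [269, 63.1]},
                 "categories": {"NUD+REP+ISL": [170, 48.4], "NUD+REP": [10, 2.8], "NUD+ISL": [52, 14.8], "REP+ISL": [34, 9.7], "NUD": [20, 5.7], "REP": [52, 14.8], "ISL": [13, 3.4]}}
  },
  "table6": {
    "new":  {"ss_between": 0.2855, "df_between": 6, "ms_between": 0.0476, "f": 4.981, "p": 0.0006,
             "ss_within": 0.4005, "df_within": 42, "ms_within": 0.0096},
    "lost": {"ss_between": 1.0436, "df_between": 6, "ms_between": 0.1739, "f": 44.100, "p": null,
             "ss_within": 0.1656, "df_within": 42, "ms_within": 0.0038}
  },
  "prose": {
    "total_bands": 594,
    "per_te_bands": {"Au": 108, "TS": 62, "Ns1": 89, "Nt2": 86, "Tnt1": 80, "Tnt2": 97, "TRIM": 72},
    "parental_total": 426,
    "new_total": 170,
    "lost_total": 351,
    "new_pct_of_parental": 39.9,
    "lost_pct_of_parental": 82.4
  },
  "accessions_per_taxon": {"SYL": 4, "TRI": 6, "NUD": 5, "REP": 6, "ISL": 4}
}
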