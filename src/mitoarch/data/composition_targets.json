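{
  "_comment": "Per-genome target base composition (percent) for each region class, used by the synthetic replicator; ncr_runs gives planted homopolymer spans (bp) in the A+T-rich region, poly-A carrying one T interruption.",
  "MW288057_A_virgata": {
    "regions": {
      "genome": {"T": 41.0, "C": 11.8, "A": 39.7, "G": 7.5},
      "pcg_pos1": {"T": 37.3, "C": 10.2, "A": 37.3, "G": 15.2},
      "pcg_pos2": {"T": 48.2, "C": 16.4, "A": 22.3, "G": 13.2},
      "pcg_pos3": {"T": 51.0, "C": 5.1, "A": 41.3, "G": 2.6},
      "ncr": {"T": 48.3, "C": 6.6, "A": 41.4, "G": 3.7},
      "trna": {"T": 39.6, "C": 7.7, "A": 42.0, "G": 10.7},
      "rrna": {"T": 41.5, "C": 4.9, "A": 43.7, "G": 9.9}
    },
    "ncr_runs": {"poly_t": 22, "poly_a": 24}
  },
  "MW288058_H_nephele": {
    "regions": {
      "genome": {"T": 39.7, "C": 12.3, "A": 40.3, "G": 7.6},
      "pcg_pos1": {"T": 37.5, "C": 10.3, "A": 36.5, "G": 15.7},
      "pcg_pos2": {"T": 48.2, "C": 16.6, "A": 22.3, "G": 13.0},
      "pcg_pos3": {"T": 50.1, "C": 5.7, "A": 40.4, "G": 3.7},
      "ncr": {"T": 45.7, "C": 7.2, "A": 43.6, "G": 3.5},
      "trna": {"T": 40.3, "C": 7.5, "A": 41.4, "G": 10.7},
      "rrna": {"T": 42.1, "C": 5.1, "A": 42.8, "G": 9.9}
    },
    "ncr_runs": {"poly_t": 16, "poly_a": 12}
  },
  "MW288059_O_maga": {
    "regions": {
      "genome": {"T": 40.2, "C": 12.2, "A": 39.8, "G": 7.7},
      "pcg_pos1": {"T": 37.0, "C": 10.6, "A": 36.7, "G": 15.7},
      "pcg_pos2": {"T": 48.1, "C": 16.7, "A": 22.0, "G": 13.2},
      "pcg_pos3": {"T": 50.2, "C": 5.7, "A": 40.7, "G": 3.4},
      "ncr": {"T": 46.1, "C": 5.7, "A": 45.8, "G": 2.4},
      "trna": {"T": 40.1, "C": 7.8, "A": 41.2, "G": 10.9},
      "rrna": {"T": 41.4, "C": 5.1, "A": 44.1, "G": 9.5}
    },
    "ncr_runs": {"poly_t": 18, "poly_a": 18}
  }
}
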