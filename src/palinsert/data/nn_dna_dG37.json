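{
  "comment": "Unified DNA nearest-neighbor free energies at 37 C, kcal/mol. Stack keys are the two top-strand bases of a dinucleotide step read 5'->3'; the bottom strand is the Watson-Crick complement. Hairpin loop initiation is keyed by loop length (nt); beyond 30 nt the model extrapolates monotonically. The mismatch penalty applies per broken (1x1 internal-loop) pair inside a stem; the bulge penalty applies per bulge run.",
  "temperature_celsius": 37.0,
  "stack": {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84
  },
  "hairpin_loop": {
    "3": 3.5, "4": 3.5, "5": 3.3, "6": 4.0, "7": 4.2, "8": 4.3,
    "9": 4.5, "10": 4.6, "11": 4.8, "12": 5.0, "13": 5.05, "14": 5.1,
    "15": 5.2, "16": 5.3, "17": 5.4, "18": 5.5, "19": 5.6, "20": 5.7,
    "21": 5.78, "22": 5.86, "23": 5.94, "24": 6.02, "25": 6.1,
    "26": 6.14, "27": 6.18, "28": 6.22, "29": 6.26, "30": 6.3
  },
  "mismatch_penalty": 1.0,
  "bulge_penalty": 3.5,
  "extrapolation_per_nt": 0.1
}
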