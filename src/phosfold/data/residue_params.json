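{
  "version": "1.0",
  "comment": "Reduced heavy-atom/united-atom parameter set for the package's coarse residue representation (CA backbone pseudo-atom, SC side-chain pseudo-atom, explicit hydroxyl/phosphate atoms for TYR/PTR). Charges are the dominant protonation state near neutral pH; model pKa values are standard model-compound constants.",
  "termini": {"n_term_pka": 8.0, "c_term_pka": 3.2},
  "residues": {
    "ALA": {"formal_charge": 0.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.0, "charge": 0.0}}},
    "GLY": {"formal_charge": 0.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 1.7, "charge": 0.0}}},
    "ASP": {"formal_charge": -1.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.0, "charge": -1.0}},
            "titratable": {"model_pka": 3.8, "is_acid": true, "ionized_charge": -1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "GLU": {"formal_charge": -1.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.1, "charge": -1.0}},
            "titratable": {"model_pka": 4.5, "is_acid": true, "ionized_charge": -1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "HIS": {"formal_charge": 0.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.1, "charge": 0.0}},
            "titratable": {"model_pka": 6.5, "is_acid": false, "ionized_charge": 1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "CYS": {"formal_charge": 0.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.0, "charge": 0.0}},
            "titratable": {"model_pka": 9.0, "is_acid": true, "ionized_charge": -1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "TYR": {"formal_charge": 0.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.2, "charge": 0.0}, "OH": {"radius": 1.6, "charge": 0.0}},
            "titratable": {"model_pka": 10.0, "is_acid": true, "ionized_charge": -1.0, "fixed_charge": 0.0, "atom": "OH"}},
    "LYS": {"formal_charge": 1.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.1, "charge": 1.0}},
            "titratable": {"model_pka": 10.5, "is_acid": false, "ionized_charge": 1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "ARG": {"formal_charge": 1.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.2, "charge": 1.0}},
            "titratable": {"model_pka": 12.5, "is_acid": false, "ionized_charge": 1.0, "fixed_charge": 0.0, "atom": "SC"}},
    "PTR": {"formal_charge": -2.0, "atoms": {"CA": {"radius": 1.9, "charge": 0.0}, "SC": {"radius": 2.2, "charge": 0.0}, "OH": {"radius": 1.6, "charge": -0.2}, "P": {"radius": 1.9, "charge": 1.2}, "O1P": {"radius": 1.6, "charge": -1.0}, "O2P": {"radius": 1.6, "charge": -1.0}, "O3P": {"radius": 1.6, "charge": -1.0}},
            "titratable": {"model_pka": 5.8, "is_acid": true, "ionized_charge": -1.0, "fixed_charge": -1.0, "atom": "OH"}},
    "ION": {"formal_charge": 0.0, "atoms": {"ION": {"radius": 2.0, "charge": 0.0}}},
    "CAT": {"formal_charge": 2.0, "atoms": {"CAT": {"radius": 0.8, "charge": 2.0}}},
    "SLB": {"formal_charge": 0.0, "atoms": {"Q": {"radius": 1.9, "charge": 0.0}}}
  }
}
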