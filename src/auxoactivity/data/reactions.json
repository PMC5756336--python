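[
 {
  "name": "hexadecane_fermentation",
  "reference": "incomplete oxidation of n-hexadecane to acetate with H2 release",
  "stoichiometry": {"hexadecane": "-1", "H2O": "-16", "acetate": "8", "H+": "8", "H2": "17"},
  "species_phase": {"hexadecane": "pure_liquid", "H2O": "water", "acetate": "aqueous", "H+": "aqueous", "H2": "gas"}
 },
 {
  "name": "wl_acetogenesis",
  "reference": "reductive acetogenesis from bicarbonate and H2 (Wood-Ljungdahl)",
  "stoichiometry": {"H2": "-4", "HCO3-": "-2", "H+": "-1", "acetate": "1", "H2O": "4"},
  "species_phase": {"H2": "gas", "HCO3-": "aqueous", "H+": "aqueous", "acetate": "aqueous", "H2O": "water"}
 },
 {
  "name": "hexadecane_to_acetate_net",
  "reference": "hexadecane fermented with acetate as sole product: fermentation coupled to 17/4 acetogenesis, H2-free net reaction",
  "stoichiometry": {"hexadecane": "-1", "HCO3-": "-17/2", "acetate": "49/4", "H+": "15/4", "H2O": "1"},
  "species_phase": {"hexadecane": "pure_liquid", "HCO3-": "aqueous", "acetate": "aqueous", "H+": "aqueous", "H2O": "water"}
 },
 {
  "name": "acetoclastic_methanogenesis",
  "reference": "acetate dismutated to methane and bicarbonate",
  "stoichiometry": {"acetate": "-1", "H2O": "-1", "CH4": "1", "HCO3-": "1"},
  "species_phase": {"acetate": "aqueous", "H2O": "water", "CH4": "gas", "HCO3-": "aqueous"}
 }
]
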