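{
 "H2O": {
  "name": "water (liquid)",
  "delta_Gf_standard": -237.18,
  "delta_Hf_standard": -285.83,
  "elemental_composition": {"H": 2, "O": 1},
  "charge": 0,
  "default_phase": "water"
 },
 "H+": {
  "name": "proton (aqueous); activity is always 10^-pH",
  "delta_Gf_standard": 0.0,
  "delta_Hf_standard": 0.0,
  "elemental_composition": {"H": 1},
  "charge": 1,
  "default_phase": "aqueous"
 },
 "acetate": {
  "name": "acetate anion (aqueous)",
  "delta_Gf_standard": -369.41,
  "delta_Hf_standard": -486.01,
  "elemental_composition": {"C": 2, "H": 3, "O": 2},
  "charge": -1,
  "default_phase": "aqueous"
 },
 "HCO3-": {
  "name": "bicarbonate (aqueous)",
  "delta_Gf_standard": -586.85,
  "delta_Hf_standard": -691.99,
  "elemental_composition": {"C": 1, "H": 1, "O": 3},
  "charge": -1,
  "default_phase": "aqueous"
 },
 "CH4": {
  "name": "methane (gas)",
  "delta_Gf_standard": -50.75,
  "delta_Hf_standard": -74.81,
  "elemental_composition": {"C": 1, "H": 4},
  "charge": 0,
  "default_phase": "gas"
 },
 "H2": {
  "name": "dihydrogen (gas)",
  "delta_Gf_standard": 0.0,
  "delta_Hf_standard": 0.0,
  "elemental_composition": {"H": 2},
  "charge": 0,
  "default_phase": "gas"
 },
 "hexadecane": {
  "name": "n-hexadecane (pure liquid, activity 1)",
  "delta_Gf_standard": 58.7,
  "delta_Hf_standard": -456.3,
  "elemental_composition": {"C": 16, "H": 34},
  "charge": 0,
  "default_phase": "pure_liquid"
 }
}
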