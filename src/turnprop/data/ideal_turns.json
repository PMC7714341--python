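{
  "comment": "Ideal central-residue torsion angles (phi_i+1, psi_i+1, phi_i+2, psi_i+2), degrees, for the classical Thornton beta-turn types. Types I, I', II, II' per Thornton's classification; type VIII values are the standard Thornton/PROMOTIF angles (not restated in every source that uses them). Type IV is the miscellaneous catch-all and has no ideal angles. Pro-dependent types VIa1/VIa2/VIb are deliberately excluded.",
  "version": 1,
  "tolerance_deg": 30.0,
  "relaxed_tolerance_deg": 45.0,
  "types": {
    "I":    [-60.0, -30.0, -90.0, 0.0],
    "I'":   [60.0, 30.0, 90.0, 0.0],
    "II":   [-60.0, 120.0, 80.0, 0.0],
    "II'":  [60.0, -120.0, -80.0, 0.0],
    "VIII": [-60.0, -30.0, -120.0, 120.0],
    "IV":   null
  }
}
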