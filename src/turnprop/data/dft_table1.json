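{
  "comment": "DFT-optimized (SMD M06-2X/6-31G(d), water) backbone torsion angles of the beta-turn residues i..i+3 for three Asn-Gly capped heptapeptides. Angle order: phi_i, psi_i, phi_i+1, psi_i+1, phi_i+2, psi_i+2, phi_i+3, psi_i+3 (degrees).",
  "version": 1,
  "peptides": {
    "hpNG-1": {"sequence": ["ALA", "ALA", "ASN", "GLY", "ALA", "ALA"], "turn_start": 2},
    "hpNG-2": {"sequence": ["LEU", "VAL", "ASN", "GLY", "GLN", "TYR"], "turn_start": 2},
    "hpNG-3": {"sequence": ["PHE", "VAL", "ASN", "GLY", "LEU", "PHE"], "turn_start": 2}
  },
  "geometries": [
    {"peptide": "hpNG-1", "turn_type": "I",   "angles": [-64.5, 165.4, -54.5, -37.0, -86.6, -12.3, -170.0, 148.9]},
    {"peptide": "hpNG-1", "turn_type": "I'",  "angles": [-86.0, 92.2, 53.3, 41.5, 98.7, -16.5, -77.8, 92.5]},
    {"peptide": "hpNG-1", "turn_type": "II",  "angles": [-62.1, 163.9, -50.5, 134.9, 77.3, -6.9, -164.7, 129.5]},
    {"peptide": "hpNG-1", "turn_type": "II'", "angles": [-84.3, 96.0, 51.9, -133.5, -71.3, -9.8, -80.5, 90.2]},
    {"peptide": "hpNG-2", "turn_type": "I",   "angles": [-106.0, 153.7, -54.5, -35.1, -74.9, -26.2, -175.5, 150.4]},
    {"peptide": "hpNG-2", "turn_type": "I'",  "angles": [-132.4, 119.6, 57.8, 36.1, 91.2, -23.5, -80.0, 109.3]},
    {"peptide": "hpNG-2", "turn_type": "II",  "angles": [-108.6, 151.0, -47.8, 130.4, 89.9, -18.1, -166.6, 128.0]},
    {"peptide": "hpNG-2", "turn_type": "II'", "angles": [-130.1, 132.5, 57.1, -134.9, -87.8, -7.4, -84.1, 108.9]},
    {"peptide": "hpNG-3", "turn_type": "I",   "angles": [-130.0, 168.9, -55.1, -28.3, -112.2, 25.8, -158.4, 145.3]},
    {"peptide": "hpNG-3", "turn_type": "I'",  "angles": [-145.3, 121.2, 58.3, 38.7, 78.1, -4.8, -106.4, -169.9]},
    {"peptide": "hpNG-3", "turn_type": "II",  "angles": [-129.7, 167.6, -47.3, 136.6, 63.9, 23.0, -160.0, 130.6]},
    {"peptide": "hpNG-3", "turn_type": "II'", "angles": [-78.9, 85.1, 54.2, -146.9, -65.9, -24.8, -56.1, 150.2]}
  ]
}
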