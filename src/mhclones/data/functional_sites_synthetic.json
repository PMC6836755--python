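{
  "description": "SYNTHETIC default functional-residue set for simulation: 36 peptide-binding (PBS) and 26 TCR-binding (TBS) residue positions within residues 2-182 of the MHC class I alpha1/alpha2 domains, 8 shared, 54 distinct in total. These are placeholder positions with the correct class structure, concentrated along the groove-forming regions; supply a study-specific file to use real PBS/TBS assignments.",
  "pbs": [5, 7, 9, 24, 33, 45, 59, 62, 63, 66, 67, 69, 70, 73, 74, 76, 77, 80, 81, 84, 95, 97, 99, 114, 116, 118, 123, 124, 133, 143, 146, 147, 152, 156, 159, 163],
  "tbs": [58, 60, 61, 62, 64, 65, 66, 68, 69, 71, 72, 73, 75, 76, 78, 79, 145, 146, 148, 149, 150, 151, 152, 154, 155, 159]
}
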