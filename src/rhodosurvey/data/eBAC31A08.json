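{
  "name": "eBAC31A08",
  "description": "Canonical green-absorbing proteorhodopsin used as the residue-numbering frame. Positions are 1-based in this sequence.",
  "motif_positions_pr": [97, 101, 105, 108],
  "motif_positions_br": [85, 89, 93, 96],
  "retinal_lysine_pr": 231,
  "native_motif": ["D", "T", "L", "E"]
}
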