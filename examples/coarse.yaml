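# Quick synthetic biatrial model at 2.4 mm (walls thickened so the two
# transmural layers stay resolved at this edge length).
geometry:
  target_edge_length: 2.4
  la_wall_thickness: 2.5
  ra_wall_thickness: 2.8
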