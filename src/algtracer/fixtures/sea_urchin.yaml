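# Sea urchin ALG history: from the 24-group deuterostome root through the
# ambulacrarian/echinoderm fusions (stem_events) to the 21-group sea urchin
# ancestor, then the Lytechinus-genus fusion and the two species-specific
# end-end fusions.
name: sea_urchin
root_labels: [A1, A2, B1, B2, B3, C1, C2, D, E, F, G, H, I, J1, J2, K, L, M, N, O1, O2, P, Q, R]
tree: "(SPU,(LVA,LPI)Lytechinus)SeaUrchin;"
stem_events:
  - {kind: fusion_mixing, operands: [B2, C2]}          # ambulacrarian stem
  - {kind: fusion_mixing, operands: [E, "B2⊗C2"]}      # earlier of the two shared urchin fusions
  - {kind: fusion_centric, operands: [J1, B3]}         # later, still centric pattern
events:
  Lytechinus:
    - {kind: fusion_end_end, operands: [G, D]}
  LVA:
    - {kind: fusion_end_end, operands: [F, "J1↘B3"]}
  LPI:
    - {kind: fusion_end_end, operands: [F, C1]}
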