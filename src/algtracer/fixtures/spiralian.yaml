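# Spiralian ALG history: 24-group protostome ancestor, the four shared
# spiralian fusions-with-mixing (stem_events -> 20 groups), the extra annelid
# fusion (-> 19), and lineage-specific fusions in three bivalves (RPH, SCO,
# PYE) and two annelids (PEC, SBE).
name: spiralian
root_labels: [A1, A2, B1, B2, B3, C1, C2, D, E, F, G, H, I, J1, J2, K, L, M, N, O1, O2, P, Q, R]
tree: "((RPH,SCO,PYE)Bivalvia,(PEC,SBE)Annelida)Spiralia;"
stem_events:
  - {kind: fusion_mixing, operands: [L, J2]}
  - {kind: fusion_mixing, operands: [O2, K]}
  - {kind: fusion_mixing, operands: [Q, H]}
  - {kind: fusion_mixing, operands: [O1, R]}
events:
  Annelida:
    - {kind: fusion_mixing, operands: [C2, "L⊗J2"]}
  RPH:
    - {kind: fusion_mixing, operands: [A2, B2]}
  SCO:
    - {kind: fusion_mixing, operands: [A2, B2]}
    - {kind: fusion_end_end, operands: [J1, "Q⊗H"]}
    - {kind: fission, operands: ["J1●(Q⊗H)"], products: ["J1●(Q⊗H)-a", "J1●(Q⊗H)-b"]}
  PYE:
    - {kind: fusion_mixing, operands: [M, B2]}
  PEC:
    - {kind: fusion_mixing, operands: [B1, E]}
    - {kind: fusion_mixing, operands: [J1, B2]}
    - {kind: fusion_mixing, operands: [P, D]}
    - {kind: fusion_mixing, operands: [B3, "O1⊗R"]}
    - {kind: fusion_mixing, operands: [M, A2]}
  SBE:
    - {kind: fusion_mixing, operands: [F, "C2⊗(L⊗J2)"]}
    - {kind: fusion_mixing, operands: [J1, "O2⊗K"]}
    - {kind: fusion_mixing, operands: [G, M]}
    - {kind: fusion_mixing, operands: [P, N]}
    - {kind: fusion_mixing, operands: [E, "O1⊗R"]}
    - {kind: fusion_mixing, operands: [A1, B3]}
    - {kind: fusion_mixing, operands: [D, A2]}
    - {kind: fusion_mixing, operands: [C1, B2]}
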