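# Deuterostome ALG history: 24-linkage-group deuterostome ancestor and the
# recorded lineage-specific rearrangements down to five extant leaves
# (amphioxus BFL, hemichordates PFL/SCA, sea urchin SPU, sea star POC) plus
# the vertebrate ancestral karyotype (VRT).  Events on a branch key apply on
# the edge leading into that node.
name: deuterostome
root_labels: [A1, A2, B1, B2, B3, C1, C2, D, E, F, G, H, I, J1, J2, K, L, M, N, O1, O2, P, Q, R]
tree: "(((PFL,SCA)Hemichordata,(SPU,POC)Echinodermata)Ambulacraria,(BFL,VRT)Chordata)Deuterostomia;"
events:
  # ambulacrarian stem: B2 and C2 fuse and mix extensively -> 23 groups
  Ambulacraria:
    - {kind: fusion_mixing, operands: [B2, C2]}
  # hemichordate stem: the fused B2/C2 group splits (Robertsonian-style
  # fission) and R fuses-with-mixing with B1 -> 23 chromosomes in PFL and SCA
  Hemichordata:
    - {kind: fission, operands: ["B2⊗C2"], products: ["B2⊗C2-a", "B2⊗C2-b"]}
    - {kind: fusion_mixing, operands: [R, B1]}
  # sea star branch: O2 + B3 fuse -> 22 chromosomes
  POC:
    - {kind: fusion_mixing, operands: [O2, B3]}
  # sea urchin branch: centric insertion of B3 into J1, then E fuses-with-
  # mixing with the already-fused B2/C2 group -> 21 chromosomes
  SPU:
    - {kind: fusion_centric, operands: [J1, B3]}
    - {kind: fusion_mixing, operands: [E, "B2⊗C2"]}
  # chordate stem: linkage group R dissolves across the genome -> 23 groups
  Chordata:
    - {kind: dispersal, operands: [R]}
  # amphioxus branch: four fusions -> 19 chromosomes
  BFL:
    - {kind: fusion_centric, operands: [J2, C1]}
    - {kind: fusion_mixing, operands: [A1, A2]}
    - {kind: fusion_end_end, operands: [O1, I]}
    - {kind: fusion_end_end, operands: [C2, Q]}
  # vertebrate stem: three pairwise fusions and one three-way -> 18 groups
  VRT:
    - {kind: fusion_mixing, operands: [J1, J2]}
    - {kind: fusion_mixing, operands: [C1, C2]}
    - {kind: fusion_mixing, operands: [O1, O2]}
    - {kind: fusion_mixing, operands: [B1, B2, B3]}
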