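# Per-continent haplogroup label pools used by the synthetic-data generator
# when dressing simulated uniparental continental origins as haplogroup
# labels. Synthetic stand-in lists; every label resolves through
# continent_map.yaml to the continent of its pool. Editable data.
NRY:
  Africa: [E1b1a, E1b1a7, E1b1b1a, E2, A]
  Europe: [R1b1b2, R1a1, I, J2, G, H1]
  EastAsia: [O, N1c, D, K-M106]
  America: [Q1a]
mtDNA:
  Africa: [L0, L1b, L2a, L3e]
  Europe: [H, U5, K1, J1, T2, V]
  EastAsia: [D4, G2, M7, F1, B4, A5]
  America: [A2, B2, C1, D1]
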