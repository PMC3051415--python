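# Haplogroup -> continental-origin lookup (longest-prefix match), one block
# per uniparental system. Synthetic stand-in assembled from published
# continental-origin assignments; "Europe" stands for the broad Eurasian
# (Europe / Middle East / South & Central Asia) parental cluster, matching
# the four parental populations of the analysis. Editable data.
NRY:
  'Y': other
  A: Africa
  B: Africa
  E: Africa
  CT: other
  DE: other
  D: EastAsia
  C: EastAsia
  F: other
  G: Europe
  H: Europe
  I: Europe
  J: Europe
  K: other
  K-M106: EastAsia
  L: Europe
  'NO': EastAsia
  'N': EastAsia
  O: EastAsia
  P: other
  Q: America
  R: Europe
mtDNA:
  L: Africa
  H: Europe
  HV: Europe
  V: Europe
  U: Europe
  K: Europe
  J: Europe
  T: Europe
  W: Europe
  X: Europe
  I: Europe
  'N': other
  R: other
  M: EastAsia
  C: EastAsia
  D: EastAsia
  E: EastAsia
  G: EastAsia
  F: EastAsia
  B: EastAsia
  A: EastAsia
  Z: EastAsia
  'Y': EastAsia
  A2: America
  B2: America
  C1: America
  D1: America
  X2a: America
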