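# Rooted NRY-SNP marker phylogeny covering the 24 core haplogroup markers
# and the 18 haplogroup-E subtyping markers, arranged per standard YCC-style
# nomenclature. This is a synthetic stand-in tree assembled from published
# nomenclature, shipped as editable data so users can correct topology
# without code changes. Each node: haplogroup label; each child edge: the
# marker whose derived state leads to it. M106's published placement is
# uncertain; it is kept as a K-lineage here.
label: 'Y'
children:
  - marker: M91
    label: A
  - marker: M168
    label: CT
    children:
      - marker: M145
        label: DE
        children:
          - marker: M174
            label: D
          - marker: M96
            label: E
            children:
              - marker: M33
                label: E1a
              - marker: P2
                label: E1b1
                children:
                  - marker: M2
                    label: E1b1a
                    children:
                      - marker: M154
                        label: E1b1a6
                      - marker: M191
                        label: E1b1a7
                  - marker: M215
                    label: E1b1b
                    children:
                      - marker: M35
                        label: E1b1b1
                        children:
                          - marker: M78
                            label: E1b1b1a
                            children:
                              - marker: V12
                                label: E1b1b1a1
                              - marker: V13
                                label: E1b1b1a2
                              - marker: V22
                                label: E1b1b1a3
                              - marker: V32
                                label: E1b1b1a4
                              - marker: M224
                                label: E1b1b1a5
                          - marker: M81
                            label: E1b1b1b
                          - marker: M123
                            label: E1b1b1c
                          - marker: V6
                            label: E1b1b1d
                          - marker: M281
                            label: E1b1b1e
              - marker: M75
                label: E2
      - marker: M213
        label: F
        children:
          - marker: M201
            label: G
          - marker: M69
            label: H
            children:
              - marker: M52
                label: H1
          - marker: M170
            label: I
          - marker: 12f2
            label: J
            children:
              - marker: M172
                label: J2
          - marker: M9
            label: K
            children:
              - marker: M20
                label: L
              - marker: M106
                label: K-M106
              - marker: M214
                label: 'NO'
                children:
                  - marker: Tat
                    label: N1c
                  - marker: M175
                    label: O
              - marker: M45
                label: P
                children:
                  - marker: MEH2
                    label: Q1a
                  - marker: M207
                    label: R
                    children:
                      - marker: SRY1532
                        label: R1a1
                      - marker: M269
                        label: R1b1b2
                      - marker: M124
                        label: R2
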