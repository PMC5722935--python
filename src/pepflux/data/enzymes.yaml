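# Declarative cleavage rule sets (Keil-style P4..P4' context grammar).
#
# Each rule constrains residues at positions around the scissile bond
# (P1 = residue N-terminal of the bond, P1' = residue C-terminal of it).
# Constraint forms:
#   in:      the position must hold one of the listed residues
#            (fails when the position lies beyond the chain),
#   not_in:  the position must not hold any of the listed residues
#            (vacuously satisfied beyond the chain).
# A bond is cleavable when at least one `license` rule matches and no
# `veto` rule matches; vetoes always take precedence.
pepsin-ph1.3:
  enzyme: pepsin
  variant: "pH1.3"
  rules:
    - action: license
      where:
        P1: {in: [F, L]}
    - action: license
      where:
        P1': {in: [F, L]}
        P1: {not_in: [R]}
    - action: veto
      where:
        P3: {in: [H, K, R]}
    - action: veto
      where:
        P2: {in: [P]}
    - action: veto
      where:
        P2': {in: [P]}
pepsin-ph2:
  enzyme: pepsin
  variant: "pH>2"
  rules:
    - action: license
      where:
        P1: {in: [F, L, W, Y]}
    - action: license
      where:
        P1': {in: [F, L, W, Y]}
        P1: {not_in: [R]}
    - action: veto
      where:
        P3: {in: [H, K, R]}
    - action: veto
      where:
        P2: {in: [P]}
    - action: veto
      where:
        P2': {in: [P]}
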