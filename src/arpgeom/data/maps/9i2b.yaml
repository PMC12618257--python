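# Chain layout for the deposited SPIN90-Arp2/3 bidirectional-filament
# model (PDB 9I2B), one entry per asymmetric copy of the C2 assembly.
# BEST-EFFORT PLACEHOLDER: the deposition does not print its chain ids in
# the accompanying text, so this layout must be confirmed on the file
# itself. Run `arpgeom metrics --verify-map` (or structure_io.verify_map /
# fingerprint_map), which checks every mapped chain against anchor-residue
# fingerprints and re-derives the mapping when a check fails.
structure: 9I2B
copies:
  copy1:
    Arp3:   A
    Arp2:   B
    ArpC1:  C
    ArpC2:  D
    ArpC3:  E
    ArpC4:  F
    ArpC5:  G
    SPIN90: H
    "SPIN90*": I
    Ac1:    J
    Ac2:    K
  copy2:
    Arp3:   a
    Arp2:   b
    ArpC1:  c
    ArpC2:  d
    ArpC3:  e
    ArpC4:  f
    ArpC5:  g
    SPIN90: I
    "SPIN90*": H
    Ac1:    j
    Ac2:    k
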