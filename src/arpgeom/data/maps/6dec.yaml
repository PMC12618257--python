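# SPIN90(ARD)-bound inactive bovine Arp2/3 cocrystal (PDB 6DEC).
# BEST-EFFORT PLACEHOLDER - verify with fingerprint_map/verify_map.
structure: 6DEC
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
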