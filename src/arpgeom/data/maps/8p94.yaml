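# Chain layout for the cortactin-bound branch-junction model (PDB 8P94):
# Arp2/3, daughter-filament subunits and mother-filament actins MA1-MA6.
# BEST-EFFORT PLACEHOLDER - verify with fingerprint_map/verify_map on the
# downloaded file before quoting numbers.
structure: 8P94
copies:
  copy1:
    Arp3:  A
    Arp2:  B
    ArpC1: C
    ArpC2: D
    ArpC3: E
    ArpC4: F
    ArpC5: G
    Ac1:   H
    Ac2:   I
    MA1:   L
    MA2:   M
    MA3:   N
    MA4:   O
    MA5:   P
    MA6:   Q
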