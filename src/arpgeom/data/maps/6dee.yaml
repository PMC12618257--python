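# SPIN90 armadillo-repeat-domain structure (PDB 6DEE).
# BEST-EFFORT PLACEHOLDER - verify with fingerprint_map/verify_map.
structure: 6DEE
copies:
  copy1:
    SPIN90: A
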