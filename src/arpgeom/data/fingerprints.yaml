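# Anchor-residue fingerprints used to verify or infer subunit maps on real
# files (human Arp2/3 numbering). A chain qualifies for a logical subunit
# only if every listed (residue number, residue name) pair matches.
fingerprints:
  ArpC2:
    - [18, LYS]
    - [244, ILE]
  ArpC4:
    - [130, LYS]
    - [141, GLU]
    - [163, GLU]
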