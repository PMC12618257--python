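# Activation-metric anchors for the human Arp2/3 complex, author numbering.
# clamp_twist: four-CA dihedral spanning the ArpC2/ArpC4 clamp;
# arpc4_bend: three-CA interior angle at the hinge-helix kink.
name: human
clamp_twist:
  - {subunit: ArpC2, residue: 18,  name: LYS, atom: CA}
  - {subunit: ArpC2, residue: 244, name: ILE, atom: CA}
  - {subunit: ArpC4, residue: 147, name: SER, atom: CA}
  - {subunit: ArpC4, residue: 32,  name: ARG, atom: CA}
arpc4_bend:
  - {subunit: ArpC4, residue: 130, name: LYS, atom: CA}
  - {subunit: ArpC4, residue: 141, name: GLU, atom: CA}
  - {subunit: ArpC4, residue: 163, name: GLU, atom: CA}
alignment_range: {subunit: ArpC4, start: 2, end: 141}
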