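# Element-level van der Waals radii in Å used for solvent-accessible
# surface areas. Values follow the ProtOr (Tsai et al. 1999) united
# radii collapsed to elements, the common default of SASA tools; the set
# name is stamped into every report so a different set is a config change,
# not a code change.
name: protor-element
radii:
  H: 1.00
  D: 1.00
  C: 1.88
  N: 1.64
  O: 1.46
  S: 1.77
  P: 1.80
  SE: 1.90
  MG: 1.73
  MN: 1.73
  NA: 1.36
  K: 1.76
  CL: 1.75
  CA: 1.74
  FE: 1.30
  ZN: 1.39
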