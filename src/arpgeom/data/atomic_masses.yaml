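# Average atomic masses in Da (IUPAC 2021 standard atomic weights,
# conventional values). Covers the elements occurring in protein models
# plus the ligands of the structures analysed here (ADP, Mg, phalloidin).
masses:
  H: 1.008
  D: 2.014
  C: 12.011
  N: 14.007
  O: 15.999
  S: 32.06
  P: 30.974
  SE: 78.971
  MG: 24.305
  MN: 54.938
  NA: 22.990
  K: 39.098
  CL: 35.45
  CA: 40.078
  FE: 55.845
  ZN: 65.38
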