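# Four-subdomain division of the actin fold, used for the flattening
# dihedral over subdomain centers of mass taken in the order 2, 1, 3, 4.
#
# Boundaries for actin follow the conventional division introduced by the
# Kabsch/Holmes actin structure (SD1: 1-32, 70-144, 338-C; SD2: 33-69;
# SD3: 145-180, 270-337; SD4: 181-269). Arp2 keeps actin-like numbering;
# Arp3 carries insertions, so its ranges are shifted accordingly. These
# boundaries are data, not code: edit this file (or pass --scheme) to test
# sensitivity of the dihedral to the division.
schemes:
  actin:
    subunit: Ac1
    subdomains:
      1: [[1, 32], [70, 144], [338, 375]]
      2: [[33, 69]]
      3: [[145, 180], [270, 337]]
      4: [[181, 269]]
  Arp2:
    subunit: Arp2
    subdomains:
      1: [[1, 32], [70, 146], [339, 394]]
      2: [[33, 69]]
      3: [[147, 182], [272, 338]]
      4: [[183, 271]]
  Arp3:
    subunit: Arp3
    subdomains:
      1: [[1, 36], [80, 158], [375, 418]]
      2: [[37, 79]]
      3: [[159, 196], [287, 374]]
      4: [[197, 286]]
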