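# arpgeom

Geometric analysis of SPIN90-dimer-activated Arp2/3 complexes and the
bidirectional actin filaments they nucleate.

The Arp2/3 complex (subunits Arp2, Arp3, ArpC1–ArpC5) nucleates actin
filaments once its actin-related subunits flatten into a filament-like
arrangement. Proteins of the WISH/DIP/SPIN90 family trigger this without a
pre-existing mother filament; human SPIN90 does so as a C2-symmetric dimer
that activates two Arp2/3 complexes at once, growing two filaments in
nearly antiparallel directions. `arpgeom` computes the structural
statistics that quantify this mechanism from PDB/mmCIF coordinate models:

- **Flattening dihedral** of an actin-fold subunit: the signed dihedral
  over the centers of mass of its four subdomains taken in the order
  2, 1, 3, 4 — near 0° the subunit is flat (active), strongly negative is
  the inactive twist.
- **Clamp-twist dihedral**: the Cα dihedral K18–I244 (ArpC2) ×
  S147–R32 (ArpC4) reporting the hinge rotation of activation.
- **ArpC4 hinge bend**: the interior angle at E141 Cα between K130 Cα and
  E163 Cα; the hinge helix bends in the active state.
- **Buried surface areas** per subunit-pair interface: half the
  solvent-accessible surface area (SASA) lost on complex formation,
  BSA = (SASA(A) + SASA(B) − SASA(A∪B)) / 2, from a deterministic
  Shrake–Rupley computation (probe 1.4 Å, Fibonacci-spiral quadrature),
  with 5-Å interface residue lists and salt-bridge / hydrogen-bond /
  hydrophobic contact classification.
- **Filament axis geometry**: per-filament axes as the principal
  direction of subunit centers of mass, per-subunit screw parameters
  (rise Å, twist °), and the interfilament angle of a bidirectional
  assembly (180° = perfectly antiparallel).

Every computation is testable offline: the `arpgeom.synthetic` module
generates structures whose metric values are known in closed form (anchor
clouds at prescribed dihedrals, ideal helices, two-sphere SASA fixtures,
a miniature C2 toy assembly).

## Worked example

```sh
python examples/filament_axes.py
```

prints

```
screw parameters  : rise 27.500 Å, twist -166.700° (generator: 27.500, -166.700)
axis residual     : 9.856 Å (= RMS helical radius of the subunit COMs)
interfilament angle: 165.000° (built at 165.000°)
```

An ideal actin-like helix is generated with the canonical F-actin rise of
27.5 Å and left-handed twist of −166.7° per subunit; `screw_decompose`
recovers both exactly from the rigid transform relating consecutive
subunits. A pair of such filaments built 165° apart — the slightly
off-antiparallel geometry a SPIN90 dimer produces — is recovered by the
axis fits. The other examples cover the activation metrics
(`activation_metrics.py`), buried areas and contact classes
(`interface_areas.py`), an end-to-end C2 toy report
(`toy_complex_report.py`), and reproduction on the deposited models
(`reproduce_deposited.py`, network required).

The same operations are available as a CLI:

```sh
arpgeom fixtures --kind toy_complex --seed 0 --out-dir fx/
arpgeom metrics fx/toy_complex.pdb --map fx/toy_complex_map.yaml --out metrics.tsv
arpgeom axes fx/toy_complex.pdb --map fx/toy_complex_map.yaml \
    --subunits Ac1,Ac2,Ac3,Ac4 --out axes.tsv
```

Chain-to-subunit maps, anchor sets and subdomain schemes are YAML data
(`src/arpgeom/data/`); maps for deposited files can be verified or
inferred from anchor-residue fingerprints (`arpgeom.structure_io.verify_map`
/ `fingerprint_map`).

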