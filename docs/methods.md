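# Methods

## Coordinate model and numbering

Structures are parsed with gemmi from PDB or mmCIF into a chain → residue
→ atom hierarchy keyed by **author** chain ids and residue numbers, because
every anchor the activation metrics use (K130/E141/E163 of ArpC4,
K18/I244 of ArpC2, S147/R32 of ArpC4) is author-numbered. Insertion codes
are part of the residue key (absent in the deposited models but supported).
Alternative locations are resolved at parse time — highest occupancy wins,
ties broken by alphabetical altloc id — so each residue holds at most one
copy of each atom name and all downstream computations are deterministic.
Hydrogens are kept but flagged and excluded from metrics by default;
hetero records (ADP, Mg²⁺, phalloidin, waters) are kept with `is_hetero`
set and excluded from metrics and SASA unless explicitly included, since
published per-interface figures describe protein–protein surfaces and the
treatment of ligands in such figures is rarely stated.

Logical subunit names (Arp2, Arp3, ArpC1–ArpC5, SPIN90, SPIN90*, nucleated
actins Ac1…, mother-filament actins MA1–MA6) are bound to chain ids by a
YAML `SubunitMap`. Deposited files do not advertise which chain is which
subunit, so shipped maps are treated as claims to be checked, not facts:
`verify_map` tests every mapped chain against anchor-residue fingerprints
(e.g. the ArpC4 chain must carry LYS at 130, GLU at 141 and 163), and
`fingerprint_map` re-derives a mapping from those fingerprints when a
check fails. The shipped maps for the deposited accessions are explicit
best-effort placeholders pending that verification.

## Angular metrics

Dihedrals use the IUPAC/biomolecular sign convention via the two-plane
normal construction with `atan2`, stable near 0° and 180°, range
(−180°, 180°]; interior angles use `atan2(|u×v|, u·v)`, range [0°, 180°].
Degenerate inputs (coincident or collinear points) raise rather than
return garbage.

The **flattening dihedral** is computed over the centers of mass of the
four actin-fold subdomains taken in the fixed order 2, 1, 3, 4; the order
is not configurable because it is what makes the sign comparable across
structures. Centers of mass are mass-weighted over heavy atoms by default
(average atomic masses, IUPAC 2021); a geometric (unweighted) mode exists
for sensitivity checks and every result records which mode produced it.
Subdomain boundaries are data, not code: the shipped scheme transfers the
conventional actin subdomain division (SD1 1–32/70–144/338–C, SD2 33–69,
SD3 145–180/270–337, SD4 181–269) onto Arp2 and Arp3 numbering, with
Arp3's ranges shifted for its insertions. Published flattening values for
these complexes were produced with unstated boundaries, so agreement on
real structures should be judged to a few degrees and the scheme edited in
YAML when testing sensitivity — nothing in the code pins it.

The **clamp-twist dihedral** and **ArpC4 hinge bend** are anchor-based:
each anchor is an identity-checked named Cα (wrong residue name raises,
or warns in permissive mode — useful on close orthologs). Human and
alternate metazoan anchor sets (ArpC2 R18/I262) ship as named YAML
configs; species selection is always explicit.

State comparisons superpose structures over the Cα atoms of a residue
range (by default ArpC4 2–141, the rigid side of the hinge) using a
Kabsch SVD restricted to proper rotations; atoms are paired strictly by
residue number and atom name, unmatched residues dropped with a logged
count, because deposited and crystal models differ in completeness.
Activation labels (active/inactive cutoffs) are deliberately not
defaulted; users set thresholds in config if they want classification.

## Solvent-accessible and buried areas

SASA is Shrake–Rupley: each atom's sphere (van der Waals radius + 1.4 Å
probe) is sampled at `points_per_atom` (default 960) points of a
golden-spiral lattice — deterministic, so every figure is bit-reproducible
— and a point is accessible when no neighbouring expanded sphere contains
it strictly. Neighbour search uses a k-d tree. Exactly coincident equal
spheres are collapsed to one surface (the analytic limit of the union),
which keeps merged-selection SASA well defined even on degenerate
fixtures. Element-level radii (ProtOr-derived; C 1.88, N 1.64, O 1.46,
S 1.77 Å …) ship as a named YAML set stamped into every report; switching
sets is a config change. Accuracy against the closed-form two-sphere
spherical-cap formula is ≤2% at 960 points across the full separation
range, and totals move <0.5% on point doubling (both are exercised by the
acceptance script).

Buried area per interface is reported as **half** the SASA loss,
(SASA(A)+SASA(B)−SASA(A∪B))/2, the convention of common interactive
structure tools and the scale on which per-interface figures in the
hundreds of Å² are quoted for complexes of this size; the full loss is
carried in the same report row for transparency. Interface residues are
those with any heavy atom within 5 Å of the other side (annotated with
the minimum cross-side distance); contacts are classified by the first
matching rule in the priority order salt bridge (charged sidechain N/O
pairs of opposite formal charge ≤4.0 Å) > hydrogen bond (N/O pair
≤3.5 Å) > hydrophobic (C–C of apolar residues ≤4.5 Å) > other. Hydrogen
bonds are distance-only — on ~3-Å cryo-EM maps hydrogens are unresolved,
so an angle term would be spurious precision; reports record this.

## Filament axes and screw parameters

Filaments nucleated off an activated complex are short (the two
actin-related subunits plus a few actins), too short for a robust helix
regression, so the axis is the first principal direction (total least
squares) of the subunit centers of mass, anchored at their centroid and
oriented pointed→barbed by the given subunit order (the Arp end is the
pointed end). The fit records its method, the subunits used, and the RMS
perpendicular residual (for an ideal helix, the RMS helical radius).
Which subunits enter the fit is a config list. The interfilament angle is
taken between *oriented* directions, so perfectly antiparallel growth
reads 180°. Screw parameters between consecutive subunits come from the
Kabsch transform of residue-matched Cα sets: twist is the rotation angle
about, and rise the translation along, the screw axis, with the axis
oriented so rise ≥ 0 and the twist signed accordingly (left-handed
F-actin steps are negative); the 180° rotation case is handled through
the symmetric part of the rotation with an explicit handedness probe.

## Synthetic fixtures and what they do (not) show

The generators emulate exactly the geometric content of the real
assemblies: anchor clouds realise requested clamp/bend/flattening values
through the closed-form four-point dihedral construction; ideal filaments
repeat a rigid 6-atom subunit by the exact screw transform (defaults:
rise 27.5 Å, twist −166.7°, the canonical F-actin geometry; radius 10 Å);
filament pairs are built at a prescribed inter-axis angle (default 165°,
the midpoint of the reported 160–167° bidirectional range) by rotating
about an axis perpendicular to the filament's *analytic* principal
direction, making the target exact rather than approximate; sphere pairs
carry spherical-cap ground truth; and the C2 toy assembly composes all of
these with a 180° rotation, so copy-equality of every metric is a
construction invariant. Ground truths are computed by independent
closed-form math inside the generator (including a separate eigen-solve
for the helix principal axis), never by the analysis modules. Every
stochastic element — only the global pose — is seeded.

What the fixtures do **not** emulate: real sidechain packing, missing
residues and alternate conformations beyond the parser tests, map-derived
coordinate error, and the conformational variability of armadillo
repeats. Passing the synthetic tier therefore validates the mathematics
and the file-format path, not the biological values; those are recomputed
on the deposited coordinates by the reproduction tier
(`examples/reproduce_deposited.py` and the network-dependent acceptance
tests), which requires downloading the models.

## Numerical choices and limitations

- PDB files carry 3-decimal coordinates; fixtures with ~10 Å anchor arms
  therefore reproduce angles to ~0.01° through file I/O, and tests assert
  at that precision (in-memory paths assert at 1e-9°).
- Problem sizes in tests and the acceptance script (≤100-atom SASA
  clusters, 4–8-subunit filaments, 5-point superposition instances with a
  simplex-polished rotation-search oracle) were chosen as the smallest
  sizes that still exercise every code path and keep oracles exact.
- The sequence-mass routine uses average (not monoisotopic) residue
  masses plus one water, matching how "theoretical molecular weight" is
  quoted for recombinant constructs; it is cross-checked against an
  independent implementation in the tests.
- Known limitations: no symmetry expansion (maps must name both C2 copies
  explicitly), no Poisson–Boltzmann electrostatics or interface energies,
  no density-map handling, and buried-area values on real depositions
  depend a few percent on the radii set and hetero-atom policy — both are
  reported in every output header so a comparison is always to a stated
  convention.
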