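"""Compute activation-state metrics on a structure with known geometry.

Builds a synthetic anchor cloud whose clamp-twist dihedral, ArpC4 hinge
bend and Arp3 flattening dihedral are fixed by construction, then runs the
real metric pipeline on it (through PDB file I/O, as for any structure).
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from arpgeom.conformation import (
    arp_flattening_dihedral,
    arpc4_bend_angle,
    clamp_twist_dihedral,
    load_subdomain_schemes,
)
from arpgeom.structure_io import read_structure, write_pdb
from arpgeom.synthetic import make_anchor_cloud

fx = make_anchor_cloud(clamp_twist_deg=-35.0, bend_angle_deg=141.0,
                       flattening_deg=-2.5, seed=42)
with TemporaryDirectory() as tmp:
    path = Path(tmp) / "anchor_cloud.pdb"
    write_pdb(fx.model, path)
    model = read_structure(path)

smap = fx.maps["copy1"]
scheme = load_subdomain_schemes()["Arp3"]

clamp = clamp_twist_dihedral(model, smap)
bend = arpc4_bend_angle(model, smap)
flat = arp_flattening_dihedral(model, smap, scheme)

print(f"clamp-twist dihedral : {clamp.value:8.3f}°  (built at -35.0°)")
print(f"ArpC4 hinge bend     : {bend.value:8.3f}°  (built at 141.0°)")
print(f"Arp3 flattening      : {flat.value:8.3f}°  (built at  -2.5°)")
print()
print("The flattening dihedral is taken over subdomain centers of mass in")
print("the order 2,1,3,4: values near 0° mean a flat, filament-like Arp3;")
print("the clamp-twist dihedral tracks the ArpC2/ArpC4 hinge rotation of")
print("activation. Values match construction to PDB coordinate precision.")
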