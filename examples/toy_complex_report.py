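"""End-to-end report on the miniature C2 toy assembly.

The toy complex bundles every metric the pipeline reports — activation
dihedrals, hinge bend, dimer buried area, filament axes — into one
two-copy C2 structure with recorded ground truth, mimicking how the full
analysis runs on a deposited bidirectional-filament model.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from arpgeom.conformation import metrics_table
from arpgeom.filaments import fit_axis, interfilament_angle
from arpgeom.interfaces import buried_area
from arpgeom.structure_io import read_structure, write_pdb
from arpgeom.synthetic import make_toy_complex

fx = make_toy_complex(seed=11)
with TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pdb"
    write_pdb(fx.model, path)
    model = read_structure(path)

df = metrics_table([(model, fx.maps["copy1"]), (model, fx.maps["copy2"])],
                   scheme_keys=("Arp3",))
print(df[df.error == ""][["copy", "metric", "value_deg"]]
      .to_string(index=False))

order = fx.meta["filament_order"]
angle = interfilament_angle(fit_axis(model, fx.maps["copy1"], order),
                            fit_axis(model, fx.maps["copy2"], order))
bsa = buried_area(model, fx.maps["copy1"], ["SPIN90"], ["SPIN90*"])
print(f"\ninterfilament angle     : {angle:8.3f}°  "
      f"(truth {fx.truth['inter_axis_angle']}°)")
print(f"SPIN90–SPIN90* buried   : {bsa:8.2f} Å² "
      f"(truth {fx.truth['spin90_buried_area']:.2f} Å²)")
print("\nCopies agree because the assembly is C2-symmetric; every value")
print("matches its construction target to PDB coordinate precision.")
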