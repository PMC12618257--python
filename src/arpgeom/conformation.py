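"""Activation-state metrics for Arp2/3 complexes.

Three numbers summarise how far an Arp2/3 complex has moved toward its
filament-nucleating state:

* the **flattening dihedral** of an actin-fold subunit (Arp2, Arp3 or an
  actin), the signed dihedral over the centers of mass of its four
  subdomains taken in the order 2, 1, 3, 4 — near 0° the two lobes are
  flat, filament-like; strongly negative values are the inactive twist;
* the **clamp-twist dihedral**, a four-Cα dihedral spanning ArpC2 and
  ArpC4 (human anchors K18/I244 of ArpC2, S147/R32 of ArpC4) reporting the
  hinge rotation that accompanies activation;
* the **ArpC4 hinge bend**, the interior angle at E141 Cα between K130 and
  E163 Cα — the hinge helix bends on activation, so the active state has
  the *smaller* interior angle.

Structures are compared after a range-restricted superposition (typically
on ArpC4 residues 2–141, the rigid part of the hinge).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import geometry
from .errors import ArpGeomError, EmptySelectionError, PairingError
from .geometry import AtomicMassTable, RigidTransform
from .structure_io import (
    ResidueRange,
    StructureModel,
    SubunitMap,
    resolve_anchor,
    select_atoms,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorSpec:
    """One identity-checked Cα anchor."""

    subunit: str
    residue: int
    name: str
    atom: str = "CA"


@dataclass
class MetricDefinition:
    """A named dihedral4/angle3 metric over explicit anchors."""

    name: str
    kind: str  # "dihedral4" | "angle3"
    anchors: list[AnchorSpec]

    def __post_init__(self) -> None:
        need = 4 if self.kind == "dihedral4" else 3
        if self.kind not in ("dihedral4", "angle3"):
            raise ArpGeomError(f"unknown metric kind {self.kind!r}")
        if len(self.anchors) != need:
            raise ArpGeomError(
                f"metric {self.name!r} ({self.kind}) needs {need} anchors, "
                f"got {len(self.anchors)}")


@dataclass
class SubdomainScheme:
    """Residue ranges of the four actin-fold subdomains of one subunit."""

    subunit: str
    subdomain_ranges: dict[int, list[ResidueRange]]

    def __post_init__(self) -> None:
        if set(self.subdomain_ranges) != {1, 2, 3, 4}:
            raise ArpGeomError(
                "SubdomainScheme needs exactly subdomains 1-4, got "
                f"{sorted(self.subdomain_ranges)}")
        covered: set[int] = set()
        for sd, ranges in self.subdomain_ranges.items():
            for rr in ranges:
                span = set(range(rr.start, rr.end + 1))
                if covered & span:
                    raise ArpGeomError(
                        f"subdomain {sd} overlaps another subdomain at "
                        f"residues {sorted(covered & span)[:5]}...")
                covered |= span


@dataclass
class MetricResult:
    """One computed metric value plus its provenance."""

    metric: str
    value: float
    structure: str
    copy_label: str = "copy1"
    weighting: str = "anchor"
    anchor_positions: list[np.ndarray] = field(default_factory=list)
    atom_counts: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def _data_path(rel: str):
    return resources.files("arpgeom.data").joinpath(rel)


def load_anchor_set(name_or_path: str = "human") -> dict:
    """Load an anchor set: a shipped name ('human', 'metazoan_alt') or a
    YAML file path of the same layout."""
    candidate = _data_path(f"anchors/{name_or_path}.yaml")
    try:
        exists = candidate.is_file()
    except OSError:
        exists = False
    fh = candidate.open() if exists else open(name_or_path)
    with fh:
        doc = yaml.safe_load(fh)
    out = {"name": doc.get("name", name_or_path)}
    for key in ("clamp_twist", "arpc4_bend"):
        out[key] = [AnchorSpec(a["subunit"], int(a["residue"]), a["name"],
                               a.get("atom", "CA")) for a in doc[key]]
    rng = doc.get("alignment_range")
    if rng:
        out["alignment_range"] = ResidueRange(rng["subunit"],
                                              int(rng["start"]),
                                              int(rng["end"]))
    return out


def load_subdomain_schemes(path: str | None = None) -> dict[str, SubdomainScheme]:
    """Load subdomain schemes (default: the shipped actin-fold division)."""
    fh = (open(path) if path
          else _data_path("schemes/actin_fold_subdomains.yaml").open())
    with fh:
        doc = yaml.safe_load(fh)
    out = {}
    for key, entry in doc["schemes"].items():
        subunit = entry["subunit"]
        ranges = {int(sd): [ResidueRange(subunit, int(a), int(b))
                            for a, b in lst]
                  for sd, lst in entry["subdomains"].items()}
        out[key] = SubdomainScheme(subunit, ranges)
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def arp_flattening_dihedral(model: StructureModel, smap: SubunitMap,
                            scheme: SubdomainScheme,
                            weighting: str = "mass",
                            mass_table: AtomicMassTable | None = None,
                            include_hetero: bool = False) -> MetricResult:
    """Flattening dihedral over subdomain COMs in the order 2, 1, 3, 4.

    The order is fixed — it is what makes the sign of the reported values
    comparable across structures.  ``weighting`` selects mass-weighted
    (default) or geometric subdomain centers; the result records the mode
    and the per-subdomain atom counts actually found on the structure.
    """
    coms = []
    counts = []
    missing = []
    for sd in (2, 1, 3, 4):
        ranges = scheme.subdomain_ranges[sd]
        atoms = select_atoms(model, ranges, smap, atom_filter="heavy",
                             include_hetero=include_hetero)
        if not atoms:
            missing.append(f"subdomain {sd}: {[(r.start, r.end) for r in ranges]}")
            continue
        counts.append(len(atoms))
        coms.append(geometry.center_of_mass(atoms, mass_table, weighting))
    if missing:
        raise EmptySelectionError(
            f"{model.identifier}/{scheme.subunit}: empty subdomain "
            f"selection(s): {'; '.join(missing)}")
    value = geometry.dihedral(*coms)
    return MetricResult(
        metric=f"{scheme.subunit}_flattening_dihedral",
        value=value, structure=model.identifier,
        copy_label=smap.copy_label, weighting=weighting,
        anchor_positions=coms, atom_counts=counts)


def _anchor_positions(model: StructureModel, smap: SubunitMap,
                      anchors: Sequence[AnchorSpec],
                      permissive: bool) -> list[np.ndarray]:
    return [resolve_anchor(model, smap, a.subunit, a.residue, a.name,
                           a.atom, permissive=permissive)
            for a in anchors]


def clamp_twist_dihedral(model: StructureModel, smap: SubunitMap,
                         anchor_set: str | Mapping = "human",
                         permissive: bool = False) -> MetricResult:
    """Signed clamp-twist dihedral over the four ArpC2/ArpC4 Cα anchors."""
    anchors = (load_anchor_set(anchor_set) if isinstance(anchor_set, str)
               else dict(anchor_set))
    pos = _anchor_positions(model, smap, anchors["clamp_twist"], permissive)
    return MetricResult(
        metric="clamp_twist_dihedral",
        value=geometry.dihedral(*pos),
        structure=model.identifier, copy_label=smap.copy_label,
        weighting="anchor", anchor_positions=pos)


def arpc4_bend_angle(model: StructureModel, smap: SubunitMap,
                     anchor_set: str | Mapping = "human",
                     permissive: bool = False) -> MetricResult:
    """Hinge-helix bend: interior angle at E141 Cα (K130–E141–E163)."""
    anchors = (load_anchor_set(anchor_set) if isinstance(anchor_set, str)
               else dict(anchor_set))
    pos = _anchor_positions(model, smap, anchors["arpc4_bend"], permissive)
    return MetricResult(
        metric="arpc4_bend_angle",
        value=geometry.angle(*pos),
        structure=model.identifier, copy_label=smap.copy_label,
        weighting="anchor", anchor_positions=pos)


def align_states(reference: StructureModel, mobile: StructureModel,
                 ref_map: SubunitMap, mob_map: SubunitMap,
                 align_range: ResidueRange
                 ) -> tuple[RigidTransform, float, StructureModel]:
    """Superpose ``mobile`` on ``reference`` over shared Cα of a range.

    Pairing is strict by residue number within ``align_range``; unmatched
    residues are dropped with a logged count.  The whole mobile model is
    returned transformed.
    """
    ref_ca = select_atoms(reference, [align_range], ref_map, "calpha")
    mob_range = ResidueRange(align_range.subunit, align_range.start,
                             align_range.end)
    mob_ca = select_atoms(mobile, [mob_range], mob_map, "calpha")
    ref_p, mob_p, dropped = geometry.pair_atoms_by_identity(ref_ca, mob_ca)
    if dropped:
        logger.info("align_states: dropped %d unmatched reference Cα",
                    dropped)
    if len(ref_p) < 3:
        raise PairingError(
            f"alignment range {align_range} shares only {len(ref_p)} Cα")
    transform, rmsd = geometry.superpose(ref_p, mob_p)
    moved = StructureModel(mobile.identifier + "_aligned",
                           mobile.source_format)
    for atom in mobile.iter_atoms():
        moved.add_atom(replace(atom, position=transform.apply(atom.position)))
    return transform, rmsd, moved


# ---------------------------------------------------------------------------
# tabular report
# ---------------------------------------------------------------------------

def metrics_table(models: Sequence[tuple[StructureModel, SubunitMap]],
                  anchor_set: str | Mapping = "human",
                  schemes: Mapping[str, SubdomainScheme] | None = None,
                  scheme_keys: Iterable[str] = ("Arp3", "Arp2"),
                  weighting: str = "mass",
                  permissive: bool = False) -> pd.DataFrame:
    """One row per (structure copy, metric); failures become flagged rows.

    Computes the clamp-twist dihedral, the ArpC4 bend angle and the
    flattening dihedral for each requested subdomain scheme, continuing
    past per-structure failures.  The output is suitable for the standard
    clamp-vs-flattening activation scatter.
    """
    if schemes is None:
        schemes = load_subdomain_schemes()
    rows = []

    def _row(result: MetricResult | None, name: str, model, smap, err=None):
        rows.append({
            "structure": model.identifier,
            "copy": smap.copy_label,
            "metric": name,
            "value_deg": None if result is None else round(result.value, 3),
            "weighting": weighting if result is None else result.weighting,
            "error": "" if err is None else f"{type(err).__name__}: {err}",
        })

    for model, smap in models:
        for name, fn in (("clamp_twist_dihedral", clamp_twist_dihedral),
                         ("arpc4_bend_angle", arpc4_bend_angle)):
            try:
                _row(fn(model, smap, anchor_set, permissive), name, model, smap)
            except ArpGeomError as exc:
                _row(None, name, model, smap, exc)
        for key in scheme_keys:
            scheme = schemes[key]
            name = f"{scheme.subunit}_flattening_dihedral"
            try:
                _row(arp_flattening_dihedral(model, smap, scheme, weighting),
                     name, model, smap)
            except ArpGeomError as exc:
                _row(None, name, model, smap, exc)
    return pd.DataFrame(rows)
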