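"""Buried-surface and contact analysis of subunit interfaces.

Solvent-accessible surface area (SASA) is computed by the Shrake–Rupley
method with a *deterministic* Fibonacci-spiral point set, so every report
is bit-reproducible: a probe sphere (1.4 Å) is rolled over van der Waals
spheres, each atom's expanded sphere is sampled at ``points_per_atom``
quasi-uniform points, and a point counts as accessible when no neighbouring
expanded sphere covers it.

The buried area of an interface is reported as **half** the SASA lost on
complex formation, (SASA(A) + SASA(B) − SASA(A∪B)) / 2 — the convention of
common interactive structure tools, which is what per-interface figures in
the hundreds-of-Å² range refer to; the full (unhalved) loss is carried
alongside for transparency.  Interface residues are those with any heavy
atom within a cutoff (default 5 Å) of the other side; qualifying atom
pairs are classified salt bridge > hydrogen bond > hydrophobic > other by
distance rules only (on ~3-Å cryo-EM maps hydrogens are unresolved, so no
angle term is used).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .errors import DisjointnessError, EmptySelectionError, RadiiError
from .structure_io import AtomRecord, StructureModel, SubunitMap, select_atoms


def _load_radii() -> tuple[str, dict[str, float]]:
    with resources.files("arpgeom.data").joinpath("vdw_radii.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return doc["name"], {k.upper(): float(v) for k, v in doc["radii"].items()}


@dataclass
class SasaParameters:
    """Parameters of the Shrake–Rupley computation."""

    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii_set: dict[str, float] | None = None  # element -> vdW radius, Å
    radii_set_name: str = ""
    include_hetero: bool = False
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.points_per_atom < 92:
            raise ValueError("points_per_atom must be >= 92")
        if self.radii_set is None:
            self.radii_set_name, self.radii_set = _load_radii()
        self.radii_set = {k.upper(): float(v)
                          for k, v in self.radii_set.items()}
        if any(v <= 0 for v in self.radii_set.values()):
            raise ValueError("van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii_set[element.upper()]
        except KeyError:
            raise RadiiError(
                f"element {element!r} has no van der Waals radius in set "
                f"{self.radii_set_name!r}") from None


@dataclass
class ContactRules:
    """Distance rules for interface membership and contact classes."""

    interface_cutoff: float = 5.0
    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    hydrophobic_cutoff: float = 4.5
    hydrophobic_residues: frozenset[str] = frozenset(
        {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "GLY",
         "CYS", "TYR"})

    def __post_init__(self) -> None:
        for name in ("interface_cutoff", "salt_bridge_cutoff",
                     "hbond_cutoff", "hydrophobic_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# side-chain atoms carrying formal charge (no hydrogens on a cryo-EM map)
_BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"),
                 ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass
class InterfaceReport:
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    buried_area: float          # half SASA loss, Å²
    sasa_loss: float            # full SASA loss, Å²
    interface_residues_a: list[tuple[tuple[str, int, str], str, float]]
    interface_residues_b: list[tuple[tuple[str, int, str], str, float]]
    contacts: list[dict] = field(default_factory=list)
    radii_set_name: str = ""

    def contact_counts(self) -> dict[str, int]:
        counts = {"salt_bridge": 0, "hbond": 0, "hydrophobic": 0, "other": 0}
        for c in self.contacts:
            counts[c["class"]] += 1
        return counts


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (golden-spiral lattice).

    Fully deterministic — the same n always yields the same points, which
    makes every SASA figure reproducible to the bit.
    """
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(atoms: Sequence[AtomRecord],
         params: SasaParameters | None = None
         ) -> tuple[float, np.ndarray]:
    """Shrake–Rupley SASA: (total Å², per-atom Å² summing to the total)."""
    params = params or SasaParameters()
    work = [a for a in atoms
            if (params.include_hydrogens or not a.is_hydrogen)]
    if not work:
        raise EmptySelectionError("sasa: no atoms after hydrogen filter")
    pos = np.array([a.position for a in work])
    rad = np.array([params.radius(a.element) for a in work])
    ext = rad + params.probe_radius
    sphere = fibonacci_sphere(params.points_per_atom)

    # exactly coincident equal spheres are one surface, not two: keep the
    # first of each duplicate set (its area) and zero the copies, so the
    # union SASA of merged selections behaves like the analytic limit
    seen: dict[tuple, int] = {}
    duplicate = np.zeros(len(work), dtype=bool)
    for i in range(len(work)):
        key = (round(pos[i, 0], 6), round(pos[i, 1], 6),
               round(pos[i, 2], 6), round(ext[i], 6))
        if key in seen:
            duplicate[i] = True
        else:
            seen[key] = i

    tree = cKDTree(pos)
    ext_max = ext.max()
    areas = np.zeros(len(work))
    for i in range(len(work)):
        if duplicate[i]:
            continue
        neighbours = [j for j in tree.query_ball_point(pos[i], ext[i] + ext_max)
                      if j != i and not duplicate[j]
                      and np.linalg.norm(pos[j] - pos[i]) < ext[i] + ext[j]]
        pts = pos[i] + ext[i] * sphere
        if neighbours:
            npos = pos[neighbours]
            next_ = ext[neighbours]
            d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 > (next_ ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return float(areas.sum()), areas


def two_sphere_sasa(r1: float, r2: float, d: float,
                    probe: float = 1.4) -> tuple[float, float, float]:
    """Closed-form two-sphere reference: (SASA1, SASA2, union SASA), Å².

    Spherical-cap formula on the probe-expanded spheres R_i = r_i + probe;
    the analytic oracle the numerical SASA is validated against.
    """
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2
    if d >= R1 + R2:
        return full1, full2, full1 + full2
    if d <= abs(R1 - R2):
        # smaller sphere engulfed
        if R1 >= R2:
            return full1, 0.0, full1
        return 0.0, full2, full2
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    acc1 = full1 - 2 * np.pi * R1 * h1
    acc2 = full2 - 2 * np.pi * R2 * h2
    return acc1, acc2, acc1 + acc2


# ---------------------------------------------------------------------------
# buried areas and interfaces
# ---------------------------------------------------------------------------

def _side_atoms(model: StructureModel, smap: SubunitMap,
                side: Iterable, params: SasaParameters) -> list[AtomRecord]:
    atoms = select_atoms(model, list(side), smap, atom_filter="heavy",
                         include_hetero=params.include_hetero)
    return atoms


def _check_disjoint(side_a, side_b) -> None:
    named_a = {s for s in side_a if isinstance(s, str)}
    named_b = {s for s in side_b if isinstance(s, str)}
    shared = named_a & named_b
    if shared:
        raise DisjointnessError(f"sides share subunit(s) {sorted(shared)}")
    if not side_a or not side_b:
        raise EmptySelectionError("both interface sides must be non-empty")


def buried_area(model: StructureModel, smap: SubunitMap,
                side_a: Iterable, side_b: Iterable,
                params: SasaParameters | None = None) -> float:
    """Buried surface area of an interface: half the SASA loss, Å²."""
    half, _full = buried_area_detail(model, smap, side_a, side_b, params)
    return half


def buried_area_detail(model: StructureModel, smap: SubunitMap,
                       side_a: Iterable, side_b: Iterable,
                       params: SasaParameters | None = None
                       ) -> tuple[float, float]:
    """(half SASA loss, full SASA loss) for one interface."""
    params = params or SasaParameters()
    side_a, side_b = list(side_a), list(side_b)
    _check_disjoint(side_a, side_b)
    atoms_a = _side_atoms(model, smap, side_a, params)
    atoms_b = _side_atoms(model, smap, side_b, params)
    total_a, _ = sasa(atoms_a, params)
    total_b, _ = sasa(atoms_b, params)
    total_ab, _ = sasa(list(atoms_a) + list(atoms_b), params)
    loss = total_a + total_b - total_ab
    return loss / 2.0, loss


def interface_residues(model: StructureModel, smap: SubunitMap,
                       side_a: Iterable, side_b: Iterable,
                       rules: ContactRules | None = None,
                       params: SasaParameters | None = None
                       ) -> tuple[list, list]:
    """Residues of each side with any heavy atom within the cutoff.

    Returns two lists of ((chain, resnum, icode), resname, min_distance)
    sorted by chain/residue; symmetric by construction.
    """
    rules = rules or ContactRules()
    params = params or SasaParameters()
    side_a, side_b = list(side_a), list(side_b)
    _check_disjoint(side_a, side_b)
    atoms_a = _side_atoms(model, smap, side_a, params)
    atoms_b = _side_atoms(model, smap, side_b, params)
    if not atoms_a or not atoms_b:
        return [], []
    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([a.position for a in atoms_b])
    tree_b = cKDTree(pos_b)
    dist_a, _ = tree_b.query(pos_a, k=1)
    tree_a = cKDTree(pos_a)
    dist_b, _ = tree_a.query(pos_b, k=1)

    def collect(atoms, dists):
        best: dict[tuple, tuple[str, float]] = {}
        for atom, d in zip(atoms, dists):
            if d > rules.interface_cutoff:
                continue
            key = (atom.chain_id, atom.residue_number, atom.insertion_code)
            if key not in best or d < best[key][1]:
                best[key] = (atom.residue_name, float(d))
        return [(k, v[0], round(v[1], 3)) for k, v in sorted(best.items())]

    return collect(atoms_a, dist_a), collect(atoms_b, dist_b)


def classify_contacts(model: StructureModel, smap: SubunitMap,
                      side_a: Iterable, side_b: Iterable,
                      rules: ContactRules | None = None,
                      params: SasaParameters | None = None) -> list[dict]:
    """Cross-side atom pairs labelled salt_bridge > hbond > hydrophobic > other.

    A pair qualifies when within ``interface_cutoff``; the first matching
    rule in priority order assigns the class.
    """
    rules = rules or ContactRules()
    params = params or SasaParameters()
    side_a, side_b = list(side_a), list(side_b)
    _check_disjoint(side_a, side_b)
    atoms_a = _side_atoms(model, smap, side_a, params)
    atoms_b = _side_atoms(model, smap, side_b, params)
    if not atoms_a or not atoms_b:
        return []
    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([a.position for a in atoms_b])
    pairs = cKDTree(pos_a).query_ball_tree(cKDTree(pos_b),
                                           rules.interface_cutoff)
    contacts = []
    for i, hits in enumerate(pairs):
        a = atoms_a[i]
        for j in hits:
            b = atoms_b[j]
            d = float(np.linalg.norm(a.position - b.position))
            contacts.append({
                "atom_a": f"{a.chain_id}/{a.residue_name}{a.residue_number}/{a.atom_name}",
                "atom_b": f"{b.chain_id}/{b.residue_name}{b.residue_number}/{b.atom_name}",
                "distance": round(d, 3),
                "class": _contact_class(a, b, d, rules),
            })
    contacts.sort(key=lambda c: (c["atom_a"], c["atom_b"]))
    return contacts


def _contact_class(a: AtomRecord, b: AtomRecord, d: float,
                   rules: ContactRules) -> str:
    ka = (a.residue_name, a.atom_name)
    kb = (b.residue_name, b.atom_name)
    opposite = ((ka in _BASIC_ATOMS and kb in _ACIDIC_ATOMS)
                or (ka in _ACIDIC_ATOMS and kb in _BASIC_ATOMS))
    if opposite and d <= rules.salt_bridge_cutoff:
        return "salt_bridge"
    polar = {"N", "O"}
    if (a.element.upper() in polar and b.element.upper() in polar
            and d <= rules.hbond_cutoff):
        return "hbond"
    if (a.element.upper() == "C" and b.element.upper() == "C"
            and a.residue_name in rules.hydrophobic_residues
            and b.residue_name in rules.hydrophobic_residues
            and d <= rules.hydrophobic_cutoff):
        return "hydrophobic"
    return "other"


def interface_table(model: StructureModel, smap: SubunitMap,
                    pair_list: Sequence[tuple[str, Iterable, Iterable]],
                    rules: ContactRules | None = None,
                    params: SasaParameters | None = None) -> pd.DataFrame:
    """Per-pair buried areas, residue counts and contact-class counts.

    Row-level failures are recorded in an ``error`` column and the run
    continues — one bad pair definition must not void a report.
    """
    rules = rules or ContactRules()
    params = params or SasaParameters()
    rows = []
    for name, side_a, side_b in pair_list:
        row: dict = {"interface": name,
                     "side_a": "+".join(map(_side_label, side_a)),
                     "side_b": "+".join(map(_side_label, side_b))}
        try:
            half, full = buried_area_detail(model, smap, side_a, side_b,
                                            params)
            res_a, res_b = interface_residues(model, smap, side_a, side_b,
                                              rules, params)
            counts = {"salt_bridge": 0, "hbond": 0, "hydrophobic": 0,
                      "other": 0}
            for c in classify_contacts(model, smap, side_a, side_b, rules,
                                       params):
                counts[c["class"]] += 1
            row.update(buried_area_A2=round(half, 1),
                       sasa_loss_A2=round(full, 1),
                       n_res_a=len(res_a), n_res_b=len(res_b),
                       **{f"n_{k}": v for k, v in counts.items()},
                       error="")
        except Exception as exc:  # row-level: keep going
            row.update(buried_area_A2=None, sasa_loss_A2=None,
                       n_res_a=None, n_res_b=None,
                       n_salt_bridge=None, n_hbond=None, n_hydrophobic=None,
                       n_other=None,
                       error=f"{type(exc).__name__}: {exc}")
        rows.append(row)
    columns = ["interface", "side_a", "side_b", "buried_area_A2",
               "sasa_loss_A2", "n_res_a", "n_res_b", "n_salt_bridge",
               "n_hbond", "n_hydrophobic", "n_other", "error"]
    return pd.DataFrame(rows, columns=columns)


def _side_label(s) -> str:
    if isinstance(s, str):
        return s
    return f"{s.subunit}:{s.start}-{s.end}"
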