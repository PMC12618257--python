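"""Synthetic structures with closed-form ground truth.

Every generator here emits a :class:`StructureModel` (plus a
:class:`SubunitMap` and a ground-truth record) whose metric values are
known *by construction* — anchor clouds realising a requested dihedral or
bend angle, ideal helical filaments with stated rise/twist, filament pairs
at a prescribed inter-axis angle, two-sphere fixtures with analytic
accessible areas, and a miniature C2 "SPIN90 dimer + two complexes + two
filaments" toy assembly for end-to-end runs.

Ground truths are produced by independent closed-form math in this module
(spherical-cap areas, analytic principal axes of helix points), never by
calling the analysis modules, so they remain valid oracles.  All
randomness (the global pose of each fixture) is driven by an explicit
seed, and fixtures are plain PDB once written, so the real parser sits on
every tested path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .structure_io import AtomRecord, StructureModel, SubunitMap

_GOLD = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass
class Fixture:
    """A generated structure, its subunit maps and its ground truth."""

    model: StructureModel
    maps: dict[str, SubunitMap]
    truth: dict[str, float | tuple]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# small helpers (independent of the analysis modules)
# ---------------------------------------------------------------------------

def _random_pose(seed: int | None) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random proper rotation + translation for fixture poses."""
    if seed is None:
        return np.eye(3), np.zeros(3)
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return Q, t


def _ca(chain: str, resnum: int, resname: str, pos,
        element: str = "C", atom: str = "CA") -> AtomRecord:
    return AtomRecord(chain_id=chain, residue_number=resnum,
                      insertion_code="", residue_name=resname,
                      atom_name=atom, element=element,
                      position=np.asarray(pos, dtype=float))


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation sending unit vector u to unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-14:
        return np.eye(3)
    if c < -1 + 1e-14:
        # 180°: rotate about any perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _rotation_about(perp, 180.0)
    axis = np.cross(u, v)
    angle = np.degrees(np.arctan2(np.linalg.norm(axis), c))
    return _rotation_about(axis, angle)


def dihedral_points(target_deg: float, arm: float = 10.0) -> np.ndarray:
    """Four points realising a signed dihedral exactly (closed form).

    p1=(0,arm,0), p2=origin, p3=(arm,0,0), p4=(arm, arm·cosφ, −arm·sinφ)
    gives dihedral φ under the IUPAC two-plane convention.
    """
    if not (-180.0 < target_deg <= 180.0):
        raise ParameterError(
            f"dihedral target {target_deg}° outside (-180, 180]")
    phi = np.radians(target_deg)
    return np.array([[0.0, arm, 0.0],
                     [0.0, 0.0, 0.0],
                     [arm, 0.0, 0.0],
                     [arm, arm * np.cos(phi), -arm * np.sin(phi)]])


def angle_points(target_deg: float, arm: float = 10.0) -> np.ndarray:
    """Three points with the requested interior angle at the middle one."""
    if not (0.0 < target_deg < 180.0):
        raise ParameterError(
            f"bend-angle target {target_deg}° outside (0, 180)")
    th = np.radians(target_deg)
    return np.array([[arm * np.cos(th), arm * np.sin(th), 0.0],
                     [0.0, 0.0, 0.0],
                     [arm, 0.0, 0.0]])


def cap_sasa(r1: float, r2: float, d: float, probe: float = 1.4
             ) -> dict[str, float]:
    """Closed-form two-sphere accessible areas (independent oracle copy).

    Returns the per-sphere accessible areas, the union area, and the
    buried area under the half-loss convention.
    """
    if d < 0:
        raise ParameterError("negative separation")
    R1, R2 = r1 + probe, r2 + probe
    f1, f2 = 4 * np.pi * R1 ** 2, 4 * np.pi * R2 ** 2
    if d >= R1 + R2:
        a1, a2 = f1, f2
    elif d <= abs(R1 - R2):
        a1, a2 = (f1, 0.0) if R1 >= R2 else (0.0, f2)
    else:
        x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        a1 = f1 - 2 * np.pi * R1 * (R1 - x1)
        a2 = f2 - 2 * np.pi * R2 * (R2 - (d - x1))
    union = a1 + a2
    return {"sasa_1": a1, "sasa_2": a2, "sasa_union": union,
            "buried_half": (f1 + f2 - union) / 2.0,
            "sasa_loss": f1 + f2 - union}


def helix_com_axis(rise: float, twist_deg: float, n: int, radius: float
                   ) -> tuple[np.ndarray, float]:
    """Oriented principal axis + RMS radius of n ideal helix points.

    Closed-form eigen analysis of the covariance of the analytic center
    points (r·cos kτ, r·sin kτ, k·rise) — the independent oracle for
    principal-axis fits on ideal filaments.  Oriented first→last subunit.
    """
    k = np.arange(n, dtype=float)
    tau = np.radians(twist_deg)
    pts = np.column_stack([radius * np.cos(k * tau),
                           radius * np.sin(k * tau),
                           k * rise])
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if np.dot(pts[-1] - pts[0], axis) < 0:
        axis = -axis
    perp = centered - np.outer(centered @ axis, axis)
    rms = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    return axis, rms


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

#: default chain assignment of the anchor cloud
_ANCHOR_CHAINS = {"Arp3": "A", "ArpC2": "B", "ArpC4": "C"}

#: residues used for the four one-atom Arp3 "subdomains" — one residue
#: inside each range of the shipped actin-fold scheme, listed in COM order
#: 2, 1, 3, 4
_ARP3_SD_RESIDUES = {2: 50, 1: 100, 3: 170, 4: 230}


def make_anchor_cloud(clamp_twist_deg: float = -35.0,
                      bend_angle_deg: float = 141.0,
                      flattening_deg: float = -2.5,
                      seed: int | None = 0,
                      chains: dict[str, str] | None = None) -> Fixture:
    """Anchor cloud realising the three activation metrics exactly.

    Emits chains named for ArpC2/ArpC4 (carrying the clamp and hinge-bend
    Cα anchors, human numbering) and an Arp3 chain whose four one-atom
    subdomains realise the requested flattening dihedral.  The whole cloud
    is placed in a seeded random pose; all three metrics are invariant.
    """
    chains = chains or dict(_ANCHOR_CHAINS)
    model = StructureModel("anchor_cloud", "pdb")

    # clamp twist: K18(C2), I244(C2), S147(C4), R32(C4)
    p = dihedral_points(clamp_twist_deg)
    model.add_atom(_ca(chains["ArpC2"], 18, "LYS", p[0]))
    model.add_atom(_ca(chains["ArpC2"], 244, "ILE", p[1]))
    model.add_atom(_ca(chains["ArpC4"], 147, "SER", p[2]))
    model.add_atom(_ca(chains["ArpC4"], 32, "ARG", p[3]))

    # hinge bend K130-E141-E163, offset away from the clamp anchors
    q = angle_points(bend_angle_deg) + np.array([0.0, 0.0, 60.0])
    model.add_atom(_ca(chains["ArpC4"], 130, "LYS", q[0]))
    model.add_atom(_ca(chains["ArpC4"], 141, "GLU", q[1]))
    model.add_atom(_ca(chains["ArpC4"], 163, "GLU", q[2]))

    # Arp3 flattening: one-atom subdomains at COM order 2,1,3,4
    f = dihedral_points(flattening_deg) + np.array([0.0, 0.0, -60.0])
    for (sd, res), pos in zip(sorted(_ARP3_SD_RESIDUES.items(),
                                     key=lambda kv: (2, 1, 3, 4).index(kv[0])),
                              f):
        model.add_atom(_ca(chains["Arp3"], res, "GLY", pos))

    Q, t = _random_pose(seed)
    posed = StructureModel("anchor_cloud", "pdb")
    for atom in model.iter_atoms():
        posed.add_atom(AtomRecord(
            atom.chain_id, atom.residue_number, atom.insertion_code,
            atom.residue_name, atom.atom_name, atom.element,
            Q @ atom.position + t))
    smap = SubunitMap({k: v for k, v in chains.items()})
    truth = {"clamp_twist_dihedral": clamp_twist_deg,
             "arpc4_bend_angle": bend_angle_deg,
             "Arp3_flattening_dihedral": flattening_deg}
    return Fixture(posed, {"copy1": smap}, truth, {"seed": seed})


#: offsets of the 6-atom rigid subunit cloud (sum to zero, non-coplanar)
_SUBUNIT_OFFSETS = np.array([
    [2.0, 0.0, 0.0], [-2.0, 0.0, 0.0],
    [0.0, 2.0, 0.0], [0.0, -2.0, 0.0],
    [0.0, 0.0, 3.0], [0.0, 0.0, -3.0],
])


def _filament_atoms(rise: float, twist_deg: float, n: int, radius: float
                    ) -> list[np.ndarray]:
    """Subunit atom clouds related by the exact screw transform."""
    S = _rotation_about([0, 0, 1], twist_deg)
    base = np.array([radius, 0.0, 0.0]) + _SUBUNIT_OFFSETS
    out = []
    current = base.copy()
    for k in range(n):
        out.append(current + np.array([0.0, 0.0, 0.0]))
        current = current @ S.T + np.array([0.0, 0.0, rise])
    return out


def make_filament(rise: float = 27.5, twist_deg: float = -166.7,
                  n_subunits: int = 8, radius: float = 10.0,
                  seed: int | None = 0,
                  chain_offset: int = 0,
                  subunit_prefix: str = "Ac") -> Fixture:
    """Ideal helical filament with known screw parameters.

    Each subunit is a rigid 6-atom cloud (residues 1–6, one Cα each)
    repeated by the exact screw transform, chains labelled Ac1..AcN.  The
    ground truth carries (rise, twist), the analytic principal axis of the
    subunit centers, and the RMS helical radius.
    """
    if n_subunits < 2:
        raise ParameterError("filament needs >= 2 subunits")
    if abs(rise) <= 1e-9 and abs(twist_deg) <= 1e-9:
        raise ParameterError(
            "zero rise with zero twist leaves subunits coincident")
    if not (-180.0 < twist_deg <= 180.0):
        raise ParameterError(f"twist {twist_deg}° outside (-180, 180]")
    clouds = _filament_atoms(rise, twist_deg, n_subunits, radius)
    model = StructureModel("ideal_filament", "pdb")
    chain_ids = []
    mapping = {}
    for k, cloud in enumerate(clouds):
        chain_id = chr(ord("A") + chain_offset + k)
        chain_ids.append(chain_id)
        mapping[f"{subunit_prefix}{k + 1}"] = chain_id
        for r, pos in enumerate(cloud, start=1):
            model.add_atom(_ca(chain_id, r, "GLY", pos))
    Q, t = _random_pose(seed)
    posed = StructureModel("ideal_filament", "pdb")
    for atom in model.iter_atoms():
        posed.add_atom(AtomRecord(
            atom.chain_id, atom.residue_number, atom.insertion_code,
            atom.residue_name, atom.atom_name, atom.element,
            Q @ atom.position + t))
    axis_local, rms_radius = helix_com_axis(rise, twist_deg, n_subunits,
                                            radius)
    truth = {"rise": rise, "twist": twist_deg,
             "axis": tuple(Q @ axis_local),
             "rms_radius": rms_radius}
    smap = SubunitMap(mapping)
    return Fixture(posed, {"copy1": smap}, truth,
                   {"seed": seed, "n_subunits": n_subunits,
                    "subunit_order": [f"{subunit_prefix}{k+1}"
                                      for k in range(n_subunits)]})


def make_filament_pair(inter_axis_deg: float = 165.0,
                       rise: float = 27.5, twist_deg: float = -166.7,
                       n_subunits: int = 4, radius: float = 10.0,
                       separation: float = 120.0,
                       seed: int | None = 0) -> Fixture:
    """Two filaments whose oriented principal axes meet at a set angle.

    Filament B is filament A rotated by ``inter_axis_deg`` about an axis
    chosen perpendicular to A's *analytic* principal direction, so the
    inter-axis angle is exact by construction (not merely approximately
    the generator-axis angle).  Chains: A side Ac1..AcN, B side MA1..MAN.
    """
    if not (0.0 <= inter_axis_deg <= 180.0):
        raise ParameterError(
            f"inter-axis angle {inter_axis_deg}° outside [0, 180]")
    if n_subunits > 6:
        raise ParameterError("pair fixture supports at most 6 subunits "
                             "per filament (MA1..MA6 vocabulary)")
    axis_local, rms_radius = helix_com_axis(rise, twist_deg, n_subunits,
                                            radius)
    clouds = _filament_atoms(rise, twist_deg, n_subunits, radius)
    # rotation axis perpendicular to the analytic principal direction
    perp = np.cross(axis_local, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis_local, [0.0, 1.0, 0.0])
    R = _rotation_about(perp, inter_axis_deg)
    shift = np.array([separation, 0.0, 0.0])

    model = StructureModel("filament_pair", "pdb")
    mapping = {}
    for k, cloud in enumerate(clouds):
        cid = chr(ord("A") + k)
        mapping[f"Ac{k + 1}"] = cid
        for r, pos in enumerate(cloud, start=1):
            model.add_atom(_ca(cid, r, "GLY", pos))
    for k, cloud in enumerate(clouds):
        cid = chr(ord("a") + k)
        mapping[f"MA{k + 1}"] = cid
        for r, pos in enumerate(cloud, start=1):
            model.add_atom(_ca(cid, r, "GLY", pos @ R.T + shift))
    Q, t = _random_pose(seed)
    posed = StructureModel("filament_pair", "pdb")
    for atom in model.iter_atoms():
        posed.add_atom(AtomRecord(
            atom.chain_id, atom.residue_number, atom.insertion_code,
            atom.residue_name, atom.atom_name, atom.element,
            Q @ atom.position + t))
    truth = {"inter_axis_angle": inter_axis_deg,
             "rise": rise, "twist": twist_deg, "rms_radius": rms_radius}
    smap = SubunitMap(mapping)
    return Fixture(posed, {"copy1": smap}, truth,
                   {"seed": seed,
                    "order_a": [f"Ac{k+1}" for k in range(n_subunits)],
                    "order_b": [f"MA{k+1}" for k in range(n_subunits)]})


def make_sphere_fixture(r1: float = 1.88, r2: float = 1.88,
                        separation: float = 3.0, probe: float = 1.4,
                        elements: tuple[str, str] = ("C", "C"),
                        seed: int | None = 0) -> Fixture:
    """Two single-atom chains with analytic SASA/buried-area ground truth."""
    truth = cap_sasa(r1, r2, separation, probe)
    Q, t = _random_pose(seed)
    model = StructureModel("sphere_pair", "pdb")
    model.add_atom(_ca("A", 1, "GLY", Q @ np.zeros(3) + t,
                       element=elements[0]))
    model.add_atom(_ca("B", 1, "GLY",
                       Q @ np.array([separation, 0.0, 0.0]) + t,
                       element=elements[1]))
    smap = SubunitMap({"Ac1": "A", "Ac2": "B"})
    return Fixture(model, {"copy1": smap}, dict(truth),
                   {"seed": seed, "r1": r1, "r2": r2,
                    "separation": separation, "probe": probe})


def make_cage(seed: int | None = 0) -> Fixture:
    """A carbon atom fully enclosed by a tight shell: its SASA is zero."""
    Q, t = _random_pose(seed)
    model = StructureModel("cage", "pdb")
    model.add_atom(_ca("A", 1, "GLY", Q @ np.zeros(3) + t))
    directions = []
    for x in (-1, 0, 1):
        for y in (-1, 0, 1):
            for z in (-1, 0, 1):
                if (x, y, z) != (0, 0, 0):
                    d = np.array([x, y, z], dtype=float)
                    directions.append(d / np.linalg.norm(d))
    for i, d in enumerate(directions, start=1):
        model.add_atom(_ca("B", i, "GLY", Q @ (2.0 * d) + t))
    smap = SubunitMap({"Ac1": "A", "Ac2": "B"})
    return Fixture(model, {"copy1": smap},
                   {"caged_atom_sasa": 0.0}, {"seed": seed})


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

def make_toy_complex(clamp_twist_deg: float = -35.0,
                     bend_angle_deg: float = 141.0,
                     flattening_deg: float = -2.5,
                     inter_axis_deg: float = 165.0,
                     rise: float = 27.5, twist_deg: float = -166.7,
                     n_subunits: int = 4, radius: float = 10.0,
                     spin90_separation: float = 3.0,
                     seed: int | None = 0) -> Fixture:
    """Miniature C2 assembly covering every reported metric.

    One half = an anchor cloud (clamp, bend, flattening anchors), a
    single-atom SPIN90 "chain" and a 4-subunit ideal filament oriented so
    the two filament axes meet at ``inter_axis_deg``; the second half is
    the first rotated 180° about the C2 axis.  The two SPIN90 atoms sit
    ``spin90_separation`` Å apart across the dyad with analytic two-sphere
    buried-area truth.  Chains: copy1 uppercase, copy2 lowercase; SPIN90
    of copy1 is SPIN90* of copy2 and vice versa.
    """
    axis_local, _rms = helix_com_axis(rise, twist_deg, n_subunits, radius)
    # orient filament A so its analytic axis sits at half the target angle
    # from the C2 axis (z): C2 then maps it to exactly inter_axis_deg away
    half = inter_axis_deg / 2.0
    target_dir = np.array([np.sin(np.radians(half)), 0.0,
                           np.cos(np.radians(half))])
    R_fil = _rotation_between(axis_local, target_dir)
    fil_shift = np.array([35.0, 0.0, 20.0])

    clouds = _filament_atoms(rise, twist_deg, n_subunits, radius)
    half_model: list[AtomRecord] = []

    def add(atom):
        half_model.append(atom)

    # anchor cloud, displaced off the dyad
    anchor_shift = np.array([60.0, 0.0, 0.0])
    p = dihedral_points(clamp_twist_deg) + anchor_shift
    add(_ca("B", 18, "LYS", p[0]))
    add(_ca("B", 244, "ILE", p[1]))
    add(_ca("C", 147, "SER", p[2]))
    add(_ca("C", 32, "ARG", p[3]))
    q = angle_points(bend_angle_deg) + anchor_shift + np.array([0, 0, 60.0])
    add(_ca("C", 130, "LYS", q[0]))
    add(_ca("C", 141, "GLU", q[1]))
    add(_ca("C", 163, "GLU", q[2]))
    f = dihedral_points(flattening_deg) + anchor_shift + np.array([0, 0, -60.0])
    order = sorted(_ARP3_SD_RESIDUES.items(),
                   key=lambda kv: (2, 1, 3, 4).index(kv[0]))
    for (sd, res), pos in zip(order, f):
        add(_ca("A", res, "GLY", pos))
    # SPIN90 single atom near the dyad
    add(_ca("S", 330, "LEU",
            [spin90_separation / 2.0, 0.0, 0.0]))
    # filament
    for k, cloud in enumerate(clouds):
        cid = "JKLMNP"[k]
        for r, pos in enumerate(cloud, start=1):
            add(_ca(cid, r, "GLY", pos @ R_fil.T + fil_shift))

    C2 = _rotation_about([0, 0, 1], 180.0)
    model = StructureModel("toy_complex", "pdb")
    for atom in half_model:
        model.add_atom(atom)
        model.add_atom(AtomRecord(
            atom.chain_id.lower() if atom.chain_id != "S" else "T",
            atom.residue_number, atom.insertion_code, atom.residue_name,
            atom.atom_name, atom.element, C2 @ atom.position))

    Q, t = _random_pose(seed)
    posed = StructureModel("toy_complex", "pdb")
    for atom in model.iter_atoms():
        posed.add_atom(AtomRecord(
            atom.chain_id, atom.residue_number, atom.insertion_code,
            atom.residue_name, atom.atom_name, atom.element,
            Q @ atom.position + t))

    fil_order = [f"Ac{k+1}" for k in range(n_subunits)]
    maps = {
        "copy1": SubunitMap({"Arp3": "A", "ArpC2": "B", "ArpC4": "C",
                             "SPIN90": "S", "SPIN90*": "T",
                             **{f"Ac{k+1}": "JKLMNP"[k]
                                for k in range(n_subunits)}},
                            copy_label="copy1"),
        "copy2": SubunitMap({"Arp3": "a", "ArpC2": "b", "ArpC4": "c",
                             "SPIN90": "T", "SPIN90*": "S",
                             **{f"Ac{k+1}": "JKLMNP"[k].lower()
                                for k in range(n_subunits)}},
                            copy_label="copy2"),
    }
    spin_truth = cap_sasa(1.88, 1.88, spin90_separation)
    truth = {"clamp_twist_dihedral": clamp_twist_deg,
             "arpc4_bend_angle": bend_angle_deg,
             "Arp3_flattening_dihedral": flattening_deg,
             "inter_axis_angle": inter_axis_deg,
             "rise": rise, "twist": twist_deg,
             "spin90_buried_area": spin_truth["buried_half"]}
    return Fixture(posed, maps, truth,
                   {"seed": seed, "filament_order": fil_order})
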