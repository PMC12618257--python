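"""Primitive geometry shared by all metrics.

Signed dihedrals (IUPAC convention, atan2-stable), interior angles, mass- or
geometry-weighted centers of mass, Kabsch least-squares superposition, and
average-mass protein sequence weights.  All angles are degrees, all lengths
Å, all masses Da (kDa where stated).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateGeometryError,
    EmptySelectionError,
    MassTableError,
    PairingError,
    SequenceError,
)
from .structure_io import AtomRecord

_EPS = 1e-10


def _load_yaml_data(name: str) -> dict:
    with resources.files("arpgeom.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


class AtomicMassTable:
    """Element -> average atomic mass (Da); ships IUPAC 2021 values."""

    def __init__(self, masses: dict[str, float] | None = None) -> None:
        if masses is None:
            masses = _load_yaml_data("atomic_masses.yaml")["masses"]
        self.masses = {k.upper(): float(v) for k, v in masses.items()}
        bad = [k for k, v in self.masses.items() if v <= 0]
        if bad:
            raise MassTableError(f"non-positive masses for {bad}")

    def mass(self, element: str) -> float:
        try:
            return self.masses[element.upper()]
        except KeyError:
            raise MassTableError(
                f"element {element!r} not in atomic mass table") from None


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise DegenerateGeometryError("RigidTransform needs 3x3 R, 3 t")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateGeometryError("rotation has determinant -1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, range (-180, 180].

    IUPAC/biomolecular sign convention (the one used by standard torsion
    tools): looking down the p2->p3 bond, a clockwise rotation of the far
    bond relative to the near bond is positive.  Implemented with the
    two-plane-normal atan2 construction, numerically stable near 0/180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise DegenerateGeometryError("dihedral: p2 == p3")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError(
            "dihedral: collinear triple, plane undefined")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def angle(p1, p2, p3) -> float:
    """Interior angle at vertex p2, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("angle: coincident points")
    # atan2 of cross/dot is stable where arccos is not
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(v1, v2)),
                                       np.dot(v1, v2))))


def vector_angle(u, v) -> float:
    """Angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(u) < _EPS or np.linalg.norm(v) < _EPS:
        raise DegenerateGeometryError("vector_angle: zero vector")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)),
                                       np.dot(u, v))))


# ---------------------------------------------------------------------------
# centers of mass
# ---------------------------------------------------------------------------

def center_of_mass(atoms: Sequence[AtomRecord],
                   mass_table: AtomicMassTable | None = None,
                   weighting: str = "mass") -> np.ndarray:
    """Center of the atom set: mass-weighted over heavy atoms, or geometric.

    ``mass`` (default) computes sum(m_i x_i)/sum(m_i) over non-hydrogen
    atoms; ``geometric`` is the unweighted mean of the same selection.
    """
    if weighting not in ("mass", "geometric"):
        raise ValueError(f"unknown weighting {weighting!r}")
    heavy = [a for a in atoms if not a.is_hydrogen]
    if not heavy:
        raise EmptySelectionError("center_of_mass: no heavy atoms selected")
    pos = np.array([a.position for a in heavy])
    if weighting == "geometric":
        return pos.mean(axis=0)
    mt = mass_table or AtomicMassTable()
    w = np.array([mt.mass(a.element) for a in heavy])
    return (w[:, None] * pos).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(reference: np.ndarray | Sequence,
              mobile: np.ndarray | Sequence,
              weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of paired point sets (Kabsch).

    Returns the transform that maps ``mobile`` onto ``reference`` (applied
    as x -> R x + t) and the post-fit RMSD in Å.  Reflections are never
    returned; a chiral mismatch therefore leaves a positive RMSD.
    """
    ref = _as_points(reference)
    mob = _as_points(mobile)
    if ref.shape != mob.shape:
        raise PairingError(
            f"superpose: {mob.shape[0]} mobile vs {ref.shape[0]} reference "
            "points")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superpose needs >= 3 point pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0)
    mob_c = (w[:, None] * mob).sum(axis=0)
    X = mob - mob_c
    Y = ref - ref_c
    H = (w[:, None] * X).T @ Y
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise DegenerateGeometryError("superpose: collinear point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    transform = RigidTransform(R, t)
    diff = transform.apply(mob) - ref
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return transform, rmsd


def _as_points(obj) -> np.ndarray:
    if len(obj) and isinstance(obj[0], AtomRecord):
        pts = np.array([a.position for a in obj], dtype=float)
    else:
        pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise PairingError(f"expected (n,3) points, got shape {pts.shape}")
    return pts


def pair_atoms_by_identity(reference: Sequence[AtomRecord],
                           mobile: Sequence[AtomRecord]
                           ) -> tuple[list[AtomRecord], list[AtomRecord], int]:
    """Pair atoms strictly by (residue number, insertion code, atom name).

    Unmatched residues/atoms are dropped; the number of dropped reference
    atoms is returned so callers can log it (deposited and crystal models
    differ in completeness).
    """
    mob_index = {(a.residue_number, a.insertion_code, a.atom_name): a
                 for a in mobile}
    ref_out, mob_out = [], []
    dropped = 0
    for a in reference:
        key = (a.residue_number, a.insertion_code, a.atom_name)
        b = mob_index.get(key)
        if b is None:
            dropped += 1
        else:
            ref_out.append(a)
            mob_out.append(b)
    return ref_out, mob_out, dropped


# ---------------------------------------------------------------------------
# sequence mass
# ---------------------------------------------------------------------------

_WATER_DA = 18.0153


def sequence_mass(sequence: str,
                  residue_masses: dict[str, float] | None = None) -> float:
    """Average molecular mass of a one-letter protein sequence, in kDa.

    Sum of average residue (amino-acid minus water) masses plus one water
    for the free termini.  Average, not monoisotopic, masses: this is the
    convention behind quoted "theoretical molecular weight" figures for
    constructs of this size.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    if residue_masses is None:
        residue_masses = _load_yaml_data("residue_masses.yaml")["masses"]
    total = _WATER_DA
    for letter in seq:
        try:
            total += residue_masses[letter]
        except KeyError:
            raise SequenceError(
                f"unknown residue letter {letter!r} in sequence") from None
    return total / 1000.0
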