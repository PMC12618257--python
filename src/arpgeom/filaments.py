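"""Helical-axis geometry of nucleated actin filaments.

The filaments nucleated off an activated Arp2/3 complex are short — the
actin-related subunits Arp2/Arp3 plus a handful of actins — so instead of a
full helix regression the axis is taken as the first principal direction of
the subunit centers of mass (total least squares), oriented pointed→barbed
by the given subunit order (the Arp end is the pointed end).  The screw
relation between consecutive subunits (rise Å, twist °; canonical F-actin:
~27.5 Å, ~−166.7°) is recovered from the rigid transform that superposes
one subunit onto the next.  The interfilament angle of a bidirectional
assembly is the angle between the two *oriented* axis directions, so
perfectly antiparallel growth reads 180°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import geometry
from .errors import DegenerateGeometryError, PairingError
from .geometry import AtomicMassTable, RigidTransform
from .structure_io import StructureModel, SubunitMap, select_atoms


@dataclass
class AxisFit:
    """A fitted filament axis."""

    point: np.ndarray       # centroid of subunit COMs, on the axis
    direction: np.ndarray   # unit vector, pointed -> barbed
    residual: float         # RMS perpendicular deviation of COMs, Å
    subunits_used: tuple[str, ...]
    method: str = "subunit-COM principal direction (total least squares)"

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateGeometryError("axis direction is zero")
        self.direction = d / n
        self.point = np.asarray(self.point, dtype=float)
        if self.residual < 0:
            raise DegenerateGeometryError("negative residual")


@dataclass(frozen=True)
class ScrewParameters:
    """Per-subunit helical parameters."""

    rise: float   # Å
    twist: float  # degrees, (-180, 180]


def fit_axis(model: StructureModel, smap: SubunitMap,
             subunit_sequence: Sequence[str],
             weighting: str = "mass",
             mass_table: AtomicMassTable | None = None) -> AxisFit:
    """Fit the filament axis through >=3 subunit centers of mass.

    Direction is fixed from the first to the last subunit of
    ``subunit_sequence`` (pointed→barbed), independent of the SVD's sign
    choice.
    """
    names = tuple(subunit_sequence)
    if len(names) < 3:
        raise DegenerateGeometryError(
            f"axis fit needs >= 3 subunits, got {len(names)}")
    coms = []
    for name in names:
        atoms = select_atoms(model, [name], smap, atom_filter="heavy")
        coms.append(geometry.center_of_mass(atoms, mass_table, weighting))
    coms = np.array(coms)
    centroid = coms.mean(axis=0)
    centered = coms - centroid
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError("all subunit COMs coincide")
    direction = vt[0]
    if np.dot(coms[-1] - coms[0], direction) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    residual = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    return AxisFit(point=centroid, direction=direction, residual=residual,
                   subunits_used=names)


def interfilament_angle(fit_a: AxisFit, fit_b: AxisFit) -> float:
    """Angle between the oriented axis directions, degrees in [0, 180]."""
    return geometry.vector_angle(fit_a.direction, fit_b.direction)


def screw_decompose(model: StructureModel, smap: SubunitMap,
                    subunit_i: str, subunit_j: str) -> ScrewParameters:
    """Screw parameters of the i -> j subunit step.

    Superposes subunit i onto subunit j over Cα atoms matched by residue
    number, then reads the twist as the rotation angle about, and the rise
    as the translation along, the screw axis of that transform.  The axis
    is oriented so the rise is non-negative; the twist keeps its sign
    relative to that orientation (left-handed F-actin steps are negative).
    """
    ca_i = select_atoms(model, [subunit_i], smap, atom_filter="calpha")
    ca_j = select_atoms(model, [subunit_j], smap, atom_filter="calpha")
    ref, mob, _dropped = geometry.pair_atoms_by_identity(ca_j, ca_i)
    if len(ref) < 3:
        raise PairingError(
            f"{subunit_i}->{subunit_j}: only {len(ref)} matched Cα")
    transform, _rmsd = geometry.superpose(ref, mob)
    return screw_from_transform(transform)


def screw_from_transform(transform: RigidTransform) -> ScrewParameters:
    """Extract (rise, twist) from a rigid transform."""
    R = transform.rotation
    t = transform.translation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    if theta < 1e-9:
        # pure translation: rise along t, zero twist
        return ScrewParameters(rise=float(np.linalg.norm(t)), twist=0.0)
    # rotation axis from the antisymmetric part (or eigenvector near 180°)
    if np.pi - theta > 1e-6:
        axis = np.array([R[2, 1] - R[1, 2],
                         R[0, 2] - R[2, 0],
                         R[1, 0] - R[0, 1]]) / (2.0 * np.sin(theta))
    else:
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
    axis = axis / np.linalg.norm(axis)
    rise = float(np.dot(t, axis))
    twist = float(np.degrees(theta))
    if rise < 0:
        axis, rise, twist = -axis, -rise, -twist
    # re-sign twist for near-180 case, where the antisymmetric part vanishes
    if np.pi - theta <= 1e-6:
        twist_sign = _twist_sign(R, axis)
        twist = twist_sign * abs(twist)
    if twist <= -180.0:
        twist += 360.0
    return ScrewParameters(rise=rise, twist=twist)


def _twist_sign(R: np.ndarray, axis: np.ndarray) -> float:
    # rotate a vector perpendicular to the axis and read the handedness
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    perp = probe - np.dot(probe, axis) * axis
    perp /= np.linalg.norm(perp)
    s = np.dot(np.cross(perp, R @ perp), axis)
    return 1.0 if s >= 0 else -1.0


def axes_table(entries: Sequence[tuple[StructureModel, SubunitMap,
                                       Sequence[str]]],
               weighting: str = "mass") -> pd.DataFrame:
    """Axis fits for several filaments plus all pairwise angles."""
    rows = []
    fits: list[tuple[str, AxisFit]] = []
    for model, smap, seq in entries:
        label = f"{model.identifier}/{smap.copy_label}"
        try:
            fit = fit_axis(model, smap, seq, weighting)
            fits.append((label, fit))
            rows.append({"kind": "axis", "label": label,
                         "subunits": "+".join(seq),
                         "direction": np.array2string(fit.direction,
                                                      precision=4),
                         "residual_A": round(fit.residual, 3),
                         "value_deg": None, "error": ""})
        except Exception as exc:
            rows.append({"kind": "axis", "label": label,
                         "subunits": "+".join(seq), "direction": None,
                         "residual_A": None, "value_deg": None,
                         "error": f"{type(exc).__name__}: {exc}"})
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            la, fa = fits[i]
            lb, fb = fits[j]
            rows.append({"kind": "interfilament_angle",
                         "label": f"{la} vs {lb}", "subunits": "",
                         "direction": None, "residual_A": None,
                         "value_deg": round(interfilament_angle(fa, fb), 3),
                         "error": ""})
    return pd.DataFrame(rows)
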