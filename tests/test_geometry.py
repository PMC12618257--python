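"""Geometry primitives against hand-derived and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arpgeom import geometry
from arpgeom.errors import (
    DegenerateGeometryError,
    MassTableError,
    PairingError,
    SequenceError,
)
from arpgeom.geometry import (
    AtomicMassTable,
    RigidTransform,
    angle,
    center_of_mass,
    dihedral,
    sequence_mass,
    superpose,
)

from conftest import make_atom, random_rigid


@pytest.mark.parametrize("p4,expected", [
    ((1, 1, 0), 0.0),      # cis
    ((1, -1, 0), 180.0),   # trans
    ((1, 0, 1), -90.0),    # hand-derived cross/atan2 oracle
    ((1, 0, -1), 90.0),
])
def test_dihedral_reference_values(p4, expected):
    val = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), p4)
    assert val == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("p1,p3,expected", [
    ((1, 0, 0), (0, 1, 0), 90.0),
    ((1, 0, 0), (-1, 0, 0), 180.0),
    ((1, 0, 0), (1, 1, 0), 45.0),
])
def test_angle_reference_values(p1, p3, expected):
    assert angle(p1, (0, 0, 0), p3) == pytest.approx(expected, abs=1e-9)


def test_dihedral_degenerate_inputs():
    with pytest.raises(DegenerateGeometryError):
        dihedral((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 1, 0))
    with pytest.raises(DegenerateGeometryError):
        dihedral((2, 0, 0), (1, 0, 0), (0, 0, 0), (1, 1, 0))
    with pytest.raises(DegenerateGeometryError):
        angle((0, 0, 0), (0, 0, 0), (1, 0, 0))


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_dihedral_and_angle_rigid_invariance(seed):
    """Both angle metrics are invariant under common rigid motions."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-10, 10, size=(4, 3))
    try:
        ref_d = dihedral(*pts)
        ref_a = angle(*pts[:3])
    except DegenerateGeometryError:
        return
    Q, t = random_rigid(rng)
    moved = pts @ Q.T + t
    assert dihedral(*moved) == pytest.approx(ref_d, abs=1e-9)
    assert angle(*moved[:3]) == pytest.approx(ref_a, abs=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_dihedral_symmetries(seed):
    """Reversal keeps the sign; point mirroring flips it."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-10, 10, size=(4, 3))
    try:
        ref = dihedral(*pts)
    except DegenerateGeometryError:
        return
    assert dihedral(*pts[::-1]) == pytest.approx(ref, abs=1e-9)
    mirrored = dihedral(*(-pts))
    if abs(abs(ref) - 180.0) > 1e-9:
        assert mirrored == pytest.approx(-ref, abs=1e-9)


# ---------------------------------------------------------------------------
# centers of mass
# ---------------------------------------------------------------------------

def test_center_of_mass_symmetry_and_single():
    atoms = [make_atom(pos=(0, 0, 0)), make_atom(resnum=2, pos=(2, 0, 0))]
    np.testing.assert_allclose(center_of_mass(atoms), [1, 0, 0])
    solo = [make_atom(pos=(5, 5, 5))]
    np.testing.assert_allclose(center_of_mass(solo), [5, 5, 5])


def test_center_of_mass_mass_weighting():
    """C at origin + O at (1,0,0): COM at m_O/(m_C+m_O), by hand."""
    table = AtomicMassTable()
    atoms = [make_atom(element="C", pos=(0, 0, 0)),
             make_atom(resnum=2, element="O", name="O", pos=(1, 0, 0))]
    expected = table.mass("O") / (table.mass("C") + table.mass("O"))
    com = center_of_mass(atoms, table)
    assert com[0] == pytest.approx(expected, abs=1e-12)
    # rounded-mass hand value 16.00/28.01 agrees to ~1e-4
    assert com[0] == pytest.approx(16.00 / 28.01, abs=1e-3)


def test_center_of_mass_skips_hydrogens_and_checks_table():
    atoms = [make_atom(pos=(0, 0, 0)),
             make_atom(resnum=1, name="H1", element="H", pos=(100, 0, 0))]
    np.testing.assert_allclose(center_of_mass(atoms), [0, 0, 0])
    with pytest.raises(MassTableError):
        center_of_mass([make_atom(element="XX")])


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _brute_force_min_rmsd(ref, mob, n_samples=20000, seed=7):
    """Independent oracle: rotation sampling + simplex polish (no Kabsch)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    refc = ref - ref.mean(axis=0)
    mobc = mob - mob.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = mobc @ R.T - refc
        return np.sqrt((d ** 2).sum(axis=1).mean())

    samples = Rotation.random(n_samples, random_state=seed)
    costs = [cost(rv) for rv in samples.as_rotvec()]
    best_rv = samples.as_rotvec()[int(np.argmin(costs))]
    res = minimize(cost, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12,
                            "maxiter": 3000})
    return float(res.fun)


def test_superpose_identity_and_translation(rng):
    pts = rng.uniform(-5, 5, size=(6, 3))
    tr, rmsd = superpose(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
    shifted = pts + np.array([10.0, 0, 0])
    tr, rmsd = superpose(pts, shifted)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(tr.translation, [-10, 0, 0], atol=1e-9)


def test_superpose_matches_brute_force_minimum(rng):
    """Kabsch result equals the brute-force global minimum (<=6 points)."""
    ref = rng.uniform(-5, 5, size=(5, 3))
    Q, t = random_rigid(rng)
    mob = ref @ Q.T + t + rng.normal(scale=0.3, size=(5, 3))
    _, rmsd = superpose(ref, mob)
    brute = _brute_force_min_rmsd(ref, mob)
    assert rmsd <= brute + 1e-6
    assert abs(rmsd - brute) < 1e-6


def test_superpose_rejects_reflection():
    """A chiral 4-point mirror image cannot be superposed: rmsd > 0."""
    ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    mirror = ref * np.array([1, 1, -1])
    _, rmsd = superpose(ref, mirror)
    assert rmsd > 0.1
    brute = _brute_force_min_rmsd(ref, mirror)
    assert rmsd == pytest.approx(brute, abs=1e-6)


def test_superpose_error_paths(rng):
    pts = rng.uniform(-5, 5, size=(4, 3))
    with pytest.raises(PairingError):
        superpose(pts, pts[:3])
    with pytest.raises(DegenerateGeometryError):
        superpose(pts[:2], pts[:2])
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.raises(DegenerateGeometryError):
        superpose(line, line)


def test_rigid_transform_validation():
    with pytest.raises(DegenerateGeometryError):
        RigidTransform(np.eye(3) * 2, np.zeros(3))
    with pytest.raises(DegenerateGeometryError):
        RigidTransform(np.diag([1, 1, -1]), np.zeros(3))


# ---------------------------------------------------------------------------
# sequence mass
# ---------------------------------------------------------------------------

def test_sequence_mass_glycine_and_errors():
    assert sequence_mass("G") == pytest.approx(0.0750672, abs=1e-6)
    with pytest.raises(SequenceError):
        sequence_mass("")
    with pytest.raises(SequenceError):
        sequence_mass("GXB")


def test_sequence_mass_additivity():
    water = 18.0153 / 1000.0
    m_ab = sequence_mass("ACDEFG")
    m_a = sequence_mass("ACD")
    m_b = sequence_mass("EFG")
    assert m_ab == pytest.approx(m_a + m_b - water, abs=1e-9)


def test_sequence_mass_against_biopython():
    """Dual-route check: shipped table vs Bio.SeqUtils average weights."""
    from Bio.SeqUtils import molecular_weight
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
    expected = molecular_weight(seq, seq_type="protein",
                                monoisotopic=False) / 1000.0
    assert sequence_mass(seq) == pytest.approx(expected, rel=2e-4)


def test_mass_table_covers_required_elements():
    table = AtomicMassTable()
    for el in ("C", "N", "O", "S", "P", "H", "MG"):
        assert table.mass(el) > 0
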