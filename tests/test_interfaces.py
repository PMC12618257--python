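"""SASA against analytic oracles; interfaces and contact classes."""

import numpy as np
import pytest

from arpgeom.errors import DisjointnessError, RadiiError
from arpgeom.interfaces import (
    ContactRules,
    SasaParameters,
    buried_area,
    buried_area_detail,
    classify_contacts,
    fibonacci_sphere,
    interface_residues,
    interface_table,
    sasa,
    two_sphere_sasa,
)
from arpgeom.structure_io import SubunitMap
from arpgeom.synthetic import cap_sasa, make_cage, make_sphere_fixture

from conftest import make_atom, model_from_atoms


def test_fibonacci_sphere_is_deterministic_and_unit():
    pts = fibonacci_sphere(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(pts, fibonacci_sphere(960))
    # quasi-uniform: centroid near origin
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


def test_single_carbon_sphere_area():
    """Isolated C (r=1.88, probe 1.4): 4*pi*3.28^2 ~ 135.2 A^2 within 2%."""
    total, per = sasa([make_atom()], SasaParameters())
    analytic = 4 * np.pi * 3.28 ** 2
    assert total == pytest.approx(analytic, rel=0.02)
    assert per[0] == total


def test_distant_atoms_do_not_occlude():
    atoms = [make_atom(pos=(0, 0, 0)),
             make_atom(resnum=2, pos=(100, 0, 0))]
    total, per = sasa(atoms)
    single, _ = sasa([make_atom()])
    assert total == pytest.approx(2 * single, rel=1e-12)


def test_caged_atom_has_zero_area():
    fx = make_cage()
    total, per = sasa(list(fx.model.iter_atoms()))
    assert per[0] == 0.0


def test_sasa_matches_cap_formula_across_separations():
    """Two-sphere SASA vs the closed-form cap oracle, error <= 2%."""
    params = SasaParameters(points_per_atom=960)
    r1 = r2 = 1.88
    d_max = r1 + r2 + 2 * 1.4
    for d in np.linspace(0.0, d_max, 12):
        atoms = [make_atom(pos=(0, 0, 0)),
                 make_atom(chain="B", pos=(d, 0, 0))]
        total, _ = sasa(atoms, params)
        truth = cap_sasa(r1, r2, d)["sasa_union"]
        assert total == pytest.approx(truth, rel=0.02), f"d={d}"
    # package-level closed form agrees with the generator's oracle copy
    a1, a2, union = two_sphere_sasa(r1, r2, 3.0)
    assert union == pytest.approx(cap_sasa(r1, r2, 3.0)["sasa_union"],
                                  rel=1e-12)


def test_sasa_converges_on_point_doubling():
    """Doubling points/atom changes a ~100-atom cluster total by <0.5%."""
    rng = np.random.default_rng(5)
    atoms = [make_atom(resnum=i, pos=p)
             for i, p in enumerate(rng.uniform(0, 12, size=(100, 3)), 1)]
    t1, _ = sasa(atoms, SasaParameters(points_per_atom=960))
    t2, _ = sasa(atoms, SasaParameters(points_per_atom=1920))
    assert abs(t2 - t1) / t2 < 0.005


def test_sasa_unknown_element_raises():
    with pytest.raises(RadiiError):
        sasa([make_atom(element="QQ")])


def _two_chain_model(d):
    return model_from_atoms([make_atom(chain="A", pos=(0, 0, 0)),
                             make_atom(chain="B", pos=(d, 0, 0))])


SPHERE_MAP = SubunitMap({"Ac1": "A", "Ac2": "B"})


def test_buried_area_distant_and_coincident():
    assert buried_area(_two_chain_model(100.0), SPHERE_MAP,
                       ["Ac1"], ["Ac2"]) == pytest.approx(0.0, abs=1e-9)
    # coincident spheres: union = one sphere, buried = half a sphere
    half, full = buried_area_detail(_two_chain_model(0.0), SPHERE_MAP,
                                    ["Ac1"], ["Ac2"])
    single, _ = sasa([make_atom()])
    assert half == pytest.approx(single / 2, rel=1e-9)
    assert full == pytest.approx(2 * half, rel=1e-12)


def test_buried_area_matches_sphere_fixture_truth():
    fx = make_sphere_fixture(separation=3.0, seed=4)
    got = buried_area(fx.model, fx.maps["copy1"], ["Ac1"], ["Ac2"])
    assert got == pytest.approx(fx.truth["buried_half"], rel=0.02)


def test_buried_area_symmetry_and_additivity():
    model = model_from_atoms([
        make_atom(chain="A", pos=(0, 0, 0)),
        make_atom(chain="B", pos=(3, 0, 0)),
        make_atom(chain="C", pos=(-4, 0, 0))])  # B-C 7 Å apart: no B/C overlap
    smap = SubunitMap({"Ac1": "A", "Ac2": "B", "Ac3": "C"})
    ab = buried_area(model, smap, ["Ac1"], ["Ac2"])
    ba = buried_area(model, smap, ["Ac2"], ["Ac1"])
    assert ab == pytest.approx(ba, rel=1e-12) and ab > 0
    # B and C are mutually distant: pair areas add up
    a_bc = buried_area(model, smap, ["Ac1"], ["Ac2", "Ac3"])
    ac = buried_area(model, smap, ["Ac1"], ["Ac3"])
    assert a_bc == pytest.approx(ab + ac, rel=0.01)


def test_buried_area_rejects_overlapping_sides():
    with pytest.raises(DisjointnessError):
        buried_area(_two_chain_model(3.0), SPHERE_MAP, ["Ac1"],
                    ["Ac1", "Ac2"])


def test_interface_residues_threshold_and_monotonicity():
    model = model_from_atoms([make_atom(chain="A", pos=(0, 0, 0)),
                              make_atom(chain="B", pos=(4.9, 0, 0))])
    res_a, res_b = interface_residues(model, SPHERE_MAP, ["Ac1"], ["Ac2"],
                                      ContactRules(interface_cutoff=5.0))
    assert len(res_a) == len(res_b) == 1
    assert res_a[0][2] == pytest.approx(4.9, abs=1e-3)
    empty_a, empty_b = interface_residues(model, SPHERE_MAP, ["Ac1"],
                                          ["Ac2"],
                                          ContactRules(interface_cutoff=4.8))
    assert empty_a == [] and empty_b == []
    far = _two_chain_model(100.0)
    ra, rb = interface_residues(far, SPHERE_MAP, ["Ac1"], ["Ac2"])
    assert ra == [] and rb == []
    # monotone in cutoff: 4 Å list is a subset of the 5 Å list
    rng = np.random.default_rng(8)
    atoms = ([make_atom(chain="A", resnum=i, pos=p) for i, p in
              enumerate(rng.uniform(0, 8, (20, 3)), 1)]
             + [make_atom(chain="B", resnum=i, pos=p + np.array([8, 0, 0]))
                for i, p in enumerate(rng.uniform(0, 8, (20, 3)), 1)])
    model = model_from_atoms(atoms)
    at4 = interface_residues(model, SPHERE_MAP, ["Ac1"], ["Ac2"],
                             ContactRules(interface_cutoff=4.0))
    at5 = interface_residues(model, SPHERE_MAP, ["Ac1"], ["Ac2"],
                             ContactRules(interface_cutoff=5.0))
    assert set(r[0] for r in at4[0]) <= set(r[0] for r in at5[0])
    assert set(r[0] for r in at4[1]) <= set(r[0] for r in at5[1])


@pytest.mark.parametrize("a,b,d,expected", [
    (("LYS", "NZ", "N"), ("GLU", "OE1", "O"), 3.2, "salt_bridge"),
    (("SER", "OG", "O"), ("GLY", "O", "O"), 3.0, "hbond"),
    (("LEU", "CD1", "C"), ("ILE", "CD1", "C"), 4.0, "hydrophobic"),
    (("LEU", "CD1", "C"), ("ILE", "CD1", "C"), 4.8, "other"),
    (("LYS", "NZ", "N"), ("GLU", "OE1", "O"), 4.2, "other"),
])
def test_contact_classification_rules(a, b, d, expected):
    model = model_from_atoms([
        make_atom(chain="A", resname=a[0], name=a[1], element=a[2]),
        make_atom(chain="B", resname=b[0], name=b[1], element=b[2],
                  pos=(d, 0, 0))])
    contacts = classify_contacts(model, SPHERE_MAP, ["Ac1"], ["Ac2"])
    assert len(contacts) == 1
    assert contacts[0]["class"] == expected
    assert contacts[0]["distance"] == pytest.approx(d, abs=1e-3)


def test_salt_bridge_outranks_hbond():
    """A charged N–O pair within both cutoffs is a salt bridge, not hbond."""
    model = model_from_atoms([
        make_atom(chain="A", resname="ARG", name="NH1", element="N"),
        make_atom(chain="B", resname="ASP", name="OD2", element="O",
                  pos=(3.1, 0, 0))])
    contacts = classify_contacts(model, SPHERE_MAP, ["Ac1"], ["Ac2"])
    assert contacts[0]["class"] == "salt_bridge"


def test_sasa_cross_checked_against_biotite():
    """Independent implementation check on a random cluster (Bondi radii)."""
    import biotite.structure as struc
    rng = np.random.default_rng(11)
    coords = rng.uniform(0, 15, size=(60, 3))
    bondi = {"C": 1.70}
    atoms = [make_atom(resnum=i, pos=p) for i, p in enumerate(coords, 1)]
    ours, _ = sasa(atoms, SasaParameters(points_per_atom=960,
                                         radii_set=bondi,
                                         radii_set_name="bondi-test"))
    arr = struc.AtomArray(60)
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(["C"] * 60)
    arr.res_name = np.array(["GLY"] * 60)
    arr.atom_name = np.array(["CA"] * 60)
    arr.res_id = np.arange(1, 61)
    arr.chain_id = np.array(["A"] * 60)
    arr.hetero = np.array([False] * 60)
    theirs = struc.sasa(arr, point_number=960, vdw_radii="Single").sum()
    assert ours == pytest.approx(theirs, rel=0.01)


def test_interface_table_row_errors_do_not_stop_run():
    model = _two_chain_model(3.0)
    pairs = [("good", ["Ac1"], ["Ac2"]),
             ("bad", ["Ac1"], ["Ac1", "Ac2"])]
    df = interface_table(model, SPHERE_MAP, pairs)
    assert len(df) == 2
    good = df[df.interface == "good"].iloc[0]
    assert good.error == "" and good.buried_area_A2 > 0
    bad = df[df.interface == "bad"].iloc[0]
    assert "Disjointness" in bad.error
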