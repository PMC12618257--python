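import numpy as np
import pytest

from arpgeom.structure_io import AtomRecord, StructureModel


def make_atom(chain="A", resnum=1, resname="GLY", name="CA", element="C",
              pos=(0.0, 0.0, 0.0), **kw) -> AtomRecord:
    return AtomRecord(chain_id=chain, residue_number=resnum,
                      insertion_code=kw.pop("icode", ""),
                      residue_name=resname, atom_name=name, element=element,
                      position=np.asarray(pos, dtype=float), **kw)


def model_from_atoms(atoms, identifier="test") -> StructureModel:
    model = StructureModel(identifier)
    for a in atoms:
        model.add_atom(a)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rigid(rng):
    """Seeded random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-30, 30, size=3)
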