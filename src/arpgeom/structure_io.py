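"""Reading, writing and selecting atomic coordinates.

Structures are parsed with gemmi (PDB and mmCIF) and converted into a small
hierarchical container, :class:`StructureModel`, that keeps *author*
chain/residue numbering — all anchor residues used by the activation metrics
(K130, E141, E163 of ArpC4; K18, I244 of ArpC2; ...) are author-numbered.
Alternative locations are resolved deterministically at parse time: the
highest-occupancy altloc wins, ties broken by alphabetical altloc id.

Logical subunit names (Arp2, Arp3, ArpC1–ArpC5, SPIN90, SPIN90*, nucleated
actin Ac1/Ac2, mother-filament MA1–MA6) are bound to chain ids through a
:class:`SubunitMap`, normally loaded from a YAML config.  Because deposited
files do not advertise which chain is which subunit, maps can be *verified*
against a structure by anchor-residue fingerprints (``verify_map``) or
inferred outright (``fingerprint_map``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import yaml

from .errors import (
    AnchorIdentityError,
    AnchorMissingError,
    EmptySelectionError,
    FormatError,
    MappingError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: fixed vocabulary of logical subunit names. Deposited assemblies use
#: Ac1/Ac2 for nucleated actins and MA1-MA6 for the mother filament;
#: Ac3-Ac8 exist so synthetic filaments of up to 8 subunits are mappable.
SUBUNIT_VOCABULARY = frozenset(
    ["Arp2", "Arp3", "ArpC1", "ArpC2", "ArpC3", "ArpC4", "ArpC5",
     "SPIN90", "SPIN90*"]
    + [f"Ac{i}" for i in range(1, 9)]
    + [f"MA{i}" for i in range(1, 7)]
)

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author numbering and resolved altloc."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # (3,) float64, Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ParseError(
                f"non-finite/ill-shaped position for atom {self.atom_name} "
                f"in {self.chain_id}/{self.residue_number}"
            )
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ParseError(f"empty element for atom {self.atom_name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ParseError(
                f"occupancy {self.occupancy} outside [0,1] for {self.atom_name}"
            )


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)
    is_hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


class StructureModel:
    """Hierarchical atomic model: chains -> residues -> atoms."""

    def __init__(self, identifier: str, source_format: str = "pdb") -> None:
        self.identifier = identifier
        self.source_format = source_format
        # chain_id -> {(number, icode) -> Residue}, insertion ordered
        self.chains: dict[str, dict[tuple[int, str], Residue]] = {}

    # -- construction -------------------------------------------------

    def add_atom(self, atom: AtomRecord) -> None:
        chain = self.chains.setdefault(atom.chain_id, {})
        rkey = (atom.residue_number, atom.insertion_code)
        res = chain.get(rkey)
        if res is None:
            res = Residue(atom.chain_id, atom.residue_number,
                          atom.insertion_code, atom.residue_name,
                          is_hetero=atom.is_hetero)
            chain[rkey] = res
        existing = res.atoms.get(atom.atom_name)
        if existing is not None:
            # altloc resolution: highest occupancy, alphabetical tie-break
            keep_new = (atom.occupancy, _altloc_rank(atom.altloc)) > (
                existing.occupancy, _altloc_rank(existing.altloc))
            if not keep_new:
                return
        res.atoms[atom.atom_name] = atom

    # -- queries ------------------------------------------------------

    def iter_atoms(self) -> Iterator[AtomRecord]:
        for chain in self.chains.values():
            for res in chain.values():
                yield from res.atoms.values()

    def get_residue(self, chain_id: str, number: int,
                    insertion_code: str = "") -> Residue | None:
        chain = self.chains.get(chain_id)
        if chain is None:
            return None
        return chain.get((number, insertion_code))

    def chain_residues(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise MappingError(
                f"chain {chain_id!r} not present in {self.identifier} "
                f"(has {sorted(self.chains)})")
        return list(self.chains[chain_id].values())

    def n_atoms(self, heavy_only: bool = False) -> int:
        return sum(1 for a in self.iter_atoms()
                   if not (heavy_only and a.is_hydrogen))

    def n_protein_residues(self) -> int:
        return sum(1 for ch in self.chains.values()
                   for r in ch.values() if not r.is_hetero)

    def hetero_composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for ch in self.chains.values():
            for r in ch.values():
                if r.is_hetero and r.name != "HOH":
                    comp[r.name] = comp.get(r.name, 0) + 1
        return comp


def _altloc_rank(altloc: str) -> float:
    # alphabetical tie-break on occupancy: earlier letter wins, so rank
    # descending; blank altloc outranks any lettered one
    if not altloc:
        return 0.0
    return -ord(altloc[0])


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are resolved (highest occupancy, alphabetical tie-break),
    hydrogens are retained but flagged, hetero records (ADP, Mg, phalloidin,
    waters) are retained with ``is_hetero`` set.  Only the first model of a
    multi-model file is kept.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".cif", ".mmcif"}:
            fmt = "mmcif"
        elif suffix in {".pdb", ".ent"}:
            fmt = "pdb"
        else:
            fmt = "detect"
    if fmt not in {"pdb", "mmcif", "detect"}:
        raise FormatError(f"unknown coordinate format {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
            fmt = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise ParseError(f"{path} contains no coordinate model")

    model = StructureModel(st.name or path.stem, source_format=fmt)
    for chain in st[0]:
        for res in chain:
            is_het = res.het_flag == "H"
            for atom in res:
                occ = min(max(float(atom.occ), 0.0), 1.0)
                model.add_atom(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name or "X",
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=occ,
                    altloc=atom.altloc or "",
                    is_hetero=is_het,
                ))
    if model.n_atoms() == 0:
        raise ParseError(f"{path} parsed but contains no atoms")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (via gemmi, author numbering kept)."""
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues.values():
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.atom_name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.altloc = "\0" if not atom.altloc else atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gm.add_chain(gchain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# subunit maps
# ---------------------------------------------------------------------------

@dataclass
class SubunitMap:
    """Binding of logical subunit names to chain ids of one file."""

    mapping: dict[str, str]
    copy_label: str = "copy1"

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - SUBUNIT_VOCABULARY
        if unknown:
            raise MappingError(
                f"unknown logical subunit name(s) {sorted(unknown)}; "
                f"allowed: {sorted(SUBUNIT_VOCABULARY)}")

    def chain(self, subunit: str) -> str:
        try:
            return self.mapping[subunit]
        except KeyError:
            raise MappingError(
                f"subunit {subunit!r} is not mapped (map {self.copy_label!r} "
                f"covers {sorted(self.mapping)})") from None

    def validate(self, model: StructureModel) -> None:
        missing = [f"{s}->{c}" for s, c in self.mapping.items()
                   if c not in model.chains]
        if missing:
            raise MappingError(
                f"map {self.copy_label!r}: chains absent from "
                f"{model.identifier}: {missing}")


def load_subunit_maps(path: str | Path) -> dict[str, SubunitMap]:
    """Load a YAML map config.

    Format::

        structure: 9I2B
        copies:
          copy1: {SPIN90: A, Arp3: C, ...}
          copy2: {...}

    A flat ``mapping:`` section is accepted for single-copy files.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise MappingError(f"{path}: not a mapping config")
    if "copies" in doc:
        return {label: SubunitMap({str(k): str(v) for k, v in m.items()},
                                  copy_label=label)
                for label, m in doc["copies"].items()}
    if "mapping" in doc:
        return {"copy1": SubunitMap(
            {str(k): str(v) for k, v in doc["mapping"].items()})}
    raise MappingError(f"{path}: needs a 'copies' or 'mapping' section")


def verify_map(model: StructureModel, smap: SubunitMap,
               fingerprints: Mapping[str, Sequence[tuple[int, str]]]) -> list[str]:
    """Check mapped chains against anchor-residue fingerprints.

    ``fingerprints`` gives, per logical subunit, (residue_number,
    residue_name) pairs that must be present on the mapped chain.  Returns a
    list of human-readable mismatch descriptions (empty == verified).
    """
    problems: list[str] = []
    for subunit, pairs in fingerprints.items():
        if subunit not in smap.mapping:
            continue
        chain_id = smap.mapping[subunit]
        if chain_id not in model.chains:
            problems.append(f"{subunit}: chain {chain_id!r} absent")
            continue
        for num, name in pairs:
            res = model.get_residue(chain_id, num)
            if res is None:
                problems.append(
                    f"{subunit} ({chain_id}): residue {num} missing")
            elif res.name != name:
                problems.append(
                    f"{subunit} ({chain_id}): residue {num} is {res.name}, "
                    f"expected {name}")
    return problems


def fingerprint_map(model: StructureModel,
                    fingerprints: Mapping[str, Sequence[tuple[int, str]]],
                    copy_label: str = "copy1",
                    exclude: Iterable[str] = ()) -> SubunitMap:
    """Infer a SubunitMap by scanning chains for anchor fingerprints.

    Each logical subunit is assigned the first chain (alphabetical, not in
    ``exclude``) on which every fingerprint residue matches by number and
    identity.  Raises :class:`MappingError` when a subunit matches nowhere.
    """
    taken = set(exclude)
    mapping: dict[str, str] = {}
    for subunit, pairs in fingerprints.items():
        hit = None
        for chain_id in sorted(set(model.chains) - taken):
            if all((r := model.get_residue(chain_id, num)) is not None
                   and r.name == name for num, name in pairs):
                hit = chain_id
                break
        if hit is None:
            raise MappingError(
                f"no chain of {model.identifier} matches the fingerprint of "
                f"{subunit}: {list(pairs)}")
        mapping[subunit] = hit
        taken.add(hit)
    return SubunitMap(mapping, copy_label=copy_label)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on a logical subunit."""

    subunit: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"ResidueRange start {self.start} > end {self.end}")


ATOM_FILTERS = ("all", "heavy", "calpha", "protein_only")


def select_atoms(model: StructureModel,
                 subunits: Iterable[str] | Iterable[ResidueRange],
                 smap: SubunitMap,
                 atom_filter: str = "heavy",
                 include_hetero: bool = False) -> list[AtomRecord]:
    """Select atoms of logical subunits or residue ranges.

    Output is deterministically ordered by (chain, residue number,
    insertion code, atom name) regardless of map or input ordering.  The
    default ``heavy`` filter drops hydrogens; ``calpha`` keeps carbon CA
    atoms of polymer residues; hetero atoms are excluded unless
    ``include_hetero`` (metrics and SASA operate on protein atoms only by
    default).
    """
    if atom_filter not in ATOM_FILTERS:
        raise FormatError(f"unknown atom filter {atom_filter!r}")
    items = list(subunits)
    out: list[AtomRecord] = []
    for item in items:
        if isinstance(item, ResidueRange):
            chain_id = smap.chain(item.subunit)
            residues = [r for r in model.chain_residues(chain_id)
                        if item.start <= r.number <= item.end]
        else:
            chain_id = smap.chain(str(item))
            residues = model.chain_residues(chain_id)
        for res in residues:
            if res.is_hetero and not include_hetero:
                continue
            for atom in res.atoms.values():
                if atom_filter == "heavy" and atom.is_hydrogen:
                    continue
                if atom_filter == "calpha" and not (
                        atom.atom_name == "CA" and atom.element.upper() == "C"):
                    continue
                if atom_filter == "protein_only" and atom.is_hetero:
                    continue
                out.append(atom)
    out.sort(key=lambda a: (a.chain_id, a.residue_number,
                            a.insertion_code, a.atom_name))
    return out


def resolve_anchor(model: StructureModel, smap: SubunitMap, subunit: str,
                   residue_number: int, expected_residue_name: str,
                   atom_name: str = "CA",
                   permissive: bool = False) -> np.ndarray:
    """Return the position of an identity-checked named anchor atom.

    In strict mode (default) a residue-name mismatch raises
    :class:`AnchorIdentityError`; permissive mode logs a warning and
    proceeds, which is what you want when applying human-numbered anchors to
    a close ortholog.
    """
    chain_id = smap.chain(subunit)
    res = model.get_residue(chain_id, residue_number)
    if res is None:
        raise AnchorMissingError(
            f"{subunit} ({chain_id}) residue {residue_number} not found in "
            f"{model.identifier}")
    if expected_residue_name and res.name != expected_residue_name:
        msg = (f"{subunit} ({chain_id}) residue {residue_number} is "
               f"{res.name}, expected {expected_residue_name}")
        if not permissive:
            raise AnchorIdentityError(msg)
        logger.warning("anchor identity mismatch (permissive): %s", msg)
    atom = res.atoms.get(atom_name)
    if atom is None:
        raise AnchorMissingError(
            f"{subunit} ({chain_id}) {res.name}{residue_number} has no atom "
            f"{atom_name!r}")
    return atom.position.copy()


def atoms_nonempty(atoms: Sequence[AtomRecord], what: str) -> None:
    if len(atoms) == 0:
        raise EmptySelectionError(f"empty atom selection: {what}")
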