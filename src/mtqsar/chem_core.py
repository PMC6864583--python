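"""Molecular graph model, structure ingestion and atomic property assignment.

The descriptor machinery in this package operates on hydrogen-suppressed
molecular graphs: heavy atoms only, with the implicit/explicit hydrogen count
retained per atom (it is still needed for molecular weight, H-bond donor
counts and the charge scheme).  Bond multiplicity is deliberately not part of
the graph — topological distance is counted in bonds regardless of bond order,
so single, double and aromatic bonds are all one edge.

Eight atomic properties feed the quadratic indices:

====  =======================================  ==================
code  property                                 units
====  =======================================  ==================
HYD   Ghose–Crippen logP atomic contribution   logP units
CHR   partial charge (Gasteiger, H folded in)  e
E     Pauling electronegativity                Pauling units
M     atomic mass                              Da
POL   atomic static polarizability             Å^3
PSA   Ertl polar-surface-area contribution     Å^2
R     Ghose–Crippen molar refractivity contr.  cm^3/mol
VDW   van der Waals atomic volume              Å^3
====  =======================================  ==================

HYD, CHR, PSA and R are computed per atom in its actual chemical environment
(RDKit's Crippen atom typing, Gasteiger charges and Ertl TPSA contributions);
E, M, POL and VDW are element-level lookups shipped as versioned CSV tables
under ``mtqsar/data`` and overridable through :class:`PropertyTable`.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors, rdPartialCharges

RDLogger.DisableLog("rdApp.*")

PROPERTY_NAMES = ("HYD", "CHR", "E", "M", "POL", "PSA", "R", "VDW")

#: elements every shipped table must cover
CORE_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Gasteiger iteration count fixed for determinism of the CHR provider
GASTEIGER_ITERATIONS = 8


class ChemError(ValueError):
    """Base class for structure-handling errors."""


class SmilesParseError(ChemError):
    def __init__(self, smiles: str, position: int | None = None):
        self.smiles = smiles
        self.position = position
        loc = f" near position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{loc}")


class MultiFragmentError(ChemError):
    def __init__(self, smiles: str):
        super().__init__(
            f"multi-fragment SMILES {smiles!r}; pass keep_largest_fragment=True "
            "to curate salts/counterions"
        )


class PropertyCoverageError(ChemError):
    def __init__(self, prop: str, element: str, atom_index: int):
        self.property = prop
        self.element = element
        self.atom_index = atom_index
        super().__init__(
            f"property {prop}: element {element!r} (atom {atom_index}) not covered"
        )


@dataclass(frozen=True)
class Atom:
    symbol: str
    formal_charge: int = 0
    n_hydrogens: int = 0


class MolecularGraph:
    """Hydrogen-suppressed molecular graph.

    Atoms are an ordered list of :class:`Atom`; bonds are unordered index
    pairs.  The adjacency is symmetric, self-loop free, and ignores bond
    multiplicity.  Graphs parsed from SMILES/SDF keep a reference to the
    underlying RDKit molecule so the environment-aware property providers
    (HYD, CHR, PSA, R) can be evaluated; hand-built graphs reconstruct one
    on demand.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        bonds: Iterable[tuple[int, int]],
        id: str = "",
        rdmol: Chem.Mol | None = None,
    ):
        self.atoms = list(atoms)
        n = len(self.atoms)
        bset = set()
        for i, j in bonds:
            if i == j:
                raise ChemError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ChemError(f"bond ({i},{j}) out of range for {n} atoms")
            bset.add((min(i, j), max(i, j)))
        self.bonds = frozenset(bset)
        self.id = id
        self._rdmol = rdmol

    # -- basic graph interface -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, i: int) -> int:
        return sum(1 for a, b in self.bonds if i in (a, b))

    def adjacency_matrix(self) -> np.ndarray:
        """Symmetric 0/1 adjacency over heavy atoms (no multiplicity)."""
        A = np.zeros((self.n_atoms, self.n_atoms))
        for i, j in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A

    def relabel(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atom *i* moved to position ``perm[i]``."""
        perm = list(perm)
        inv = [0] * len(perm)
        for old, new in enumerate(perm):
            inv[new] = old
        atoms = [self.atoms[inv[k]] for k in range(self.n_atoms)]
        bonds = [(perm[i], perm[j]) for i, j in self.bonds]
        rdmol = None
        if self._rdmol is not None:
            rdmol = Chem.RenumberAtoms(self._rdmol, inv)
        return MolecularGraph(atoms, bonds, id=self.id, rdmol=rdmol)

    # -- RDKit bridge ----------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, id: str = "") -> "MolecularGraph":
        atoms = [
            Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in mol.GetAtoms()
        ]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        return cls(atoms, bonds, id=id, rdmol=mol)

    def to_rdkit(self) -> Chem.Mol:
        if self._rdmol is not None:
            return self._rdmol
        # rebuild from the heavy-atom graph: single bonds, explicit H counts
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.symbol)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNumExplicitHs(a.n_hydrogens)
            ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        for i, j in sorted(self.bonds):
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        self._rdmol = mol
        return mol

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MolecularGraph)
            and self.atoms == other.atoms
            and self.bonds == other.bonds
        )

    def __repr__(self) -> str:
        return f"MolecularGraph(id={self.id!r}, n_atoms={self.n_atoms}, n_bonds={self.n_bonds})"


# -- parsing -------------------------------------------------------------------


def _offending_position(smiles: str) -> int | None:
    """Best-effort localisation of a SMILES syntax error: first prefix length
    at which even lenient (unsanitised) parsing fails."""
    for i in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:i], sanitize=False) is None:
            return i - 1
    return None


def parse_smiles(
    smiles: str,
    id: str = "",
    keep_largest_fragment: bool = False,
) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed :class:`MolecularGraph`.

    Dot-separated multi-fragment input is an error unless
    ``keep_largest_fragment`` is set, in which case the fragment with the most
    heavy atoms is retained (standard salt/counterion curation).
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles or "")
    smiles = smiles.strip()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, _offending_position(smiles))
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        if not keep_largest_fragment:
            raise MultiFragmentError(smiles)
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    return MolecularGraph.from_rdkit(mol, id=id)


def write_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES of the heavy-atom graph."""
    return Chem.MolToSmiles(g.to_rdkit())


def canonical_smiles(smiles: str) -> str:
    return write_smiles(parse_smiles(smiles, keep_largest_fragment=True))


def read_structure_table(
    path: str | Path,
    format: str | None = None,
    smiles_column: str = "smiles",
    id_column: str | None = "id",
    strict: bool = False,
    keep_largest_fragment: bool = True,
) -> list[tuple[MolecularGraph, dict]]:
    """Read molecules plus annotations from .smi, .sdf (V2000) or .csv.

    Unparseable records are skipped with a warning (``strict=True`` aborts).
    Annotations are carried verbatim: SDF data fields, CSV columns, or the
    trailing id token of a .smi line.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    out: list[tuple[MolecularGraph, dict]] = []

    def _try(smiles: str, rid: str, ann: dict, where: str):
        try:
            out.append((parse_smiles(smiles, id=rid, keep_largest_fragment=keep_largest_fragment), ann))
        except ChemError as exc:
            if strict:
                raise ChemError(f"{where}: {exc}") from exc
            warnings.warn(f"skipping unparseable record {where}: {exc}")

    if format in ("smi", "smiles"):
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            rid = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{ln}"
            _try(parts[0], rid, {"id": rid}, f"{path.name}:{ln}")
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for ri, mol in enumerate(supplier):
            if mol is None:
                if strict:
                    raise ChemError(f"{path.name}: record {ri} unparseable")
                warnings.warn(f"skipping unparseable SDF record {ri} of {path.name}")
                continue
            ann = dict(mol.GetPropsAsDict())
            rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{ri}"
            out.append((MolecularGraph.from_rdkit(mol, id=rid), ann))
    elif format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise ChemError(f"{path.name}: no {smiles_column!r} column declared")
            for ln, row in enumerate(reader, start=2):
                rid = row.get(id_column or "", "") or f"{path.stem}_{ln}"
                _try(row[smiles_column], rid, dict(row), f"{path.name}:{ln}")
    else:
        raise ChemError(f"unknown structure format {format!r}")
    if not out:
        warnings.warn(f"{path.name}: no records read")
    return out


# -- property tables -----------------------------------------------------------


@dataclass
class PropertyTable:
    """Element(+environment)-keyed atomic property values.

    Shipped tables use the single environment class ``default``; the
    environment slot exists so users can load finer-grained tables without a
    code change.  Lookup of an uncovered element raises.
    """

    name: str
    units: str
    values: dict[tuple[str, str], float]
    version: str = "builtin-1"
    source: str = ""

    def lookup(self, element: str, environment: str = "default") -> float:
        for key in ((element, environment), (element, "default")):
            if key in self.values:
                return self.values[key]
        raise KeyError(element)

    @classmethod
    def from_csv(cls, csv_path: str | Path, manifest_path: str | Path) -> "PropertyTable":
        manifest = json.loads(Path(manifest_path).read_text())
        values: dict[tuple[str, str], float] = {}
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                values[(row["element"], row.get("environment", "default") or "default")] = float(row["value"])
        return cls(
            name=manifest["property"],
            units=manifest["units"],
            values=values,
            version=manifest.get("version", "?"),
            source=manifest.get("source", ""),
        )


def _load_builtin(prop: str) -> PropertyTable:
    base = resources.files("mtqsar").joinpath("data")
    return PropertyTable.from_csv(
        base.joinpath(f"{prop.lower()}_table.csv"),
        base.joinpath(f"{prop.lower()}_table.json"),
    )


_TABLE_PROPS = ("E", "M", "POL", "VDW")
_builtin_cache: dict[str, PropertyTable] = {}


def builtin_tables() -> dict[str, PropertyTable]:
    """The shipped element-level tables for E, M, POL and VDW."""
    for prop in _TABLE_PROPS:
        if prop not in _builtin_cache:
            _builtin_cache[prop] = _load_builtin(prop)
    return dict(_builtin_cache)


# -- computed providers --------------------------------------------------------


def gasteiger_charges(g: MolecularGraph) -> np.ndarray:
    """Heavy-atom partial charges with attached-H charges folded in.

    Iterative partial-equalisation of orbital electronegativity, seeded from
    formal charges, run for a fixed 8 iterations so results are deterministic.
    The per-molecule sum equals the net formal charge (electron conservation).
    """
    mol = g.to_rdkit()
    rdPartialCharges.ComputeGasteigerCharges(mol, nIter=GASTEIGER_ITERATIONS)
    q = np.array(
        [
            a.GetDoubleProp("_GasteigerCharge") + a.GetDoubleProp("_GasteigerHCharge")
            for a in mol.GetAtoms()
        ]
    )
    if not np.all(np.isfinite(q)):  # rare Gasteiger breakdown (e.g. bare ions)
        raise ChemError(f"charge scheme failed on {g.id or write_smiles(g)}")
    return q


def _crippen_contribs(g: MolecularGraph) -> list[tuple[float, float]]:
    return Crippen._GetAtomContribs(g.to_rdkit())


def assign_properties(
    g: MolecularGraph,
    tables: Mapping[str, PropertyTable] | None = None,
    properties: Sequence[str] = PROPERTY_NAMES,
) -> dict[str, np.ndarray]:
    """Per-atom vectors for the requested properties.

    Every vector has length ``g.n_atoms``.  Table-driven lookups raise
    :class:`PropertyCoverageError` naming the atom and property when an
    element is not covered.
    """
    tables = {**builtin_tables(), **(tables or {})}
    out: dict[str, np.ndarray] = {}
    crippen = None
    for prop in properties:
        if prop == "CHR":
            out[prop] = gasteiger_charges(g)
        elif prop in ("HYD", "R"):
            if crippen is None:
                crippen = _crippen_contribs(g)
            out[prop] = np.array([c[0 if prop == "HYD" else 1] for c in crippen])
        elif prop == "PSA":
            out[prop] = np.array(rdMolDescriptors._CalcTPSAContribs(g.to_rdkit()))
        elif prop in tables:
            table = tables[prop]
            vals = np.empty(g.n_atoms)
            for i, atom in enumerate(g.atoms):
                try:
                    vals[i] = table.lookup(atom.symbol)
                except KeyError:
                    raise PropertyCoverageError(prop, atom.symbol, i) from None
            out[prop] = vals
        else:
            raise ChemError(f"unknown property {prop!r}")
    return out
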