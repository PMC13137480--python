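"""Annotated molecular graphs for peptide classification.

A molecule is modelled as a finite structure over its heavy atoms: hydrogens
are never graph nodes but are folded into a per-atom hydrogen count, aromatic
rings are kekulized so that every bond is a plain single/double/triple bond,
and each atom carries its formal charge and (where assigned) its CIP stereo
descriptor.  This is exactly the level of description needed by the
charge/amide/residue predicates in the rest of the package: those predicates
quantify over atoms, element sets, bond orders, hydrogen counts and charges,
and nothing else.

Parsing is deliberately non-normalising: tautomers are kept as drawn and
charges are kept as given, because the downstream rules (e.g. the imidic
amide form, zwitterion detection) are written to handle non-standardised
input directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler, rdmolops

__all__ = [
    "Atom",
    "BondRec",
    "MolGraph",
    "ParseError",
    "parse_smiles",
    "read_smiles_file",
    "read_sdf",
    "connected_components",
    "carbon_components",
]

SINGLE = 1
DOUBLE = 2
TRIPLE = 3

_ORDER = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
}


class ParseError(ValueError):
    """Raised when a SMILES/SDF record cannot be turned into a MolGraph."""

    def __init__(self, message: str, text: str = ""):
        super().__init__(message)
        self.text = text


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element, formal charge, folded-in H count, CIP label."""

    index: int
    element: str
    formal_charge: int
    num_hydrogens: int
    stereo_descriptor: Optional[str] = None  # "R", "S" or None


@dataclass(frozen=True)
class BondRec:
    """An undirected bond between two heavy atoms with a kekulé order.

    ``aromatic`` records whether the bond belonged to an aromatic ring
    before kekulization; the kekulé order of such bonds is a deterministic
    but arbitrary alternation, so ring-pattern matching treats aromatic
    bonds as equivalent regardless of assigned order.
    """

    i: int
    j: int
    order: int
    aromatic: bool = False

    def endpoints(self) -> frozenset:
        return frozenset((self.i, self.j))

    def other(self, idx: int) -> int:
        if idx == self.i:
            return self.j
        if idx == self.j:
            return self.i
        raise ValueError(f"atom {idx} not an endpoint of {self}")


@dataclass
class MolGraph:
    """A single molecule as a finite structure over its heavy atoms."""

    atoms: list[Atom]
    bonds: list[BondRec]
    source_id: str = ""
    _rdkit_mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    # -- basic views ------------------------------------------------------
    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def element(self, idx: int) -> str:
        return self.atoms[idx].element

    def is_carbon(self, idx: int) -> bool:
        return self.atoms[idx].element == "C"

    def is_heteroatom(self, idx: int) -> bool:
        # hydrogen is never an atom here, so "not carbon" is enough
        return self.atoms[idx].element != "C"

    def neighbors(self, idx: int) -> list[int]:
        return self._adjacency[idx]

    def bond_between(self, i: int, j: int) -> Optional[BondRec]:
        return self._bond_lookup.get(frozenset((i, j)))

    def has_bond(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self._bond_lookup

    def bond_order(self, i: int, j: int) -> Optional[int]:
        b = self.bond_between(i, j)
        return b.order if b is not None else None

    def atoms_of_element(self, symbol: str) -> list[int]:
        return [a.index for a in self.atoms if a.element == symbol]

    # -- derived structures ----------------------------------------------
    def __post_init__(self) -> None:
        adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        lookup: dict[frozenset, BondRec] = {}
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError("self-bond in molecular graph")
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
            lookup[b.endpoints()] = b
        self._adjacency = adj
        self._bond_lookup = lookup

    def to_networkx(self, carbon_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            if carbon_only and a.element != "C":
                continue
            g.add_node(a.index)
        for b in self.bonds:
            if carbon_only and not (self.is_carbon(b.i) and self.is_carbon(b.j)):
                continue
            g.add_edge(b.i, b.j)
        return g

    def canonical_smiles(self) -> str:
        if self._rdkit_mol is None:
            raise ValueError("no RDKit molecule attached")
        return Chem.MolToSmiles(self._rdkit_mol)


def _from_rdkit(mol: Chem.Mol, source_id: str) -> MolGraph:
    aromatic_pairs = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
        if b.GetIsAromatic()
    }
    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - rdkit detail
        raise ParseError(f"kekulization failed: {exc}", source_id) from exc
    rdCIPLabeler.AssignCIPLabels(kek)
    atoms = []
    for a in kek.GetAtoms():
        cip = a.GetPropsAsDict().get("_CIPCode")
        if cip not in ("R", "S"):
            cip = None
        atoms.append(
            Atom(
                index=a.GetIdx(),
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                num_hydrogens=a.GetTotalNumHs(),
                stereo_descriptor=cip,
            )
        )
    bonds = []
    for b in kek.GetBonds():
        order = _ORDER.get(b.GetBondType())
        if order is None:
            raise ParseError(
                f"unsupported bond type {b.GetBondType()}", source_id
            )
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(BondRec(i, j, order, frozenset((i, j)) in aromatic_pairs))
    return MolGraph(atoms=atoms, bonds=bonds, source_id=source_id, _rdkit_mol=mol)


def parse_smiles(smiles: str, id: str = "") -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph`.

    Implicit hydrogens are computed by the standard valence model, explicit
    ``[H]`` atoms are folded into the hydrogen count of their heavy neighbour,
    and aromatic rings are kekulized to a deterministic alternating
    single/double assignment.  No tautomer or charge standardisation is
    applied.  Isotope labels are ignored.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES", smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}", smiles)
    mol = Chem.RemoveHs(mol)
    for a in mol.GetAtoms():
        a.SetIsotope(0)
    return _from_rdkit(mol, id or smiles)


def read_smiles_file(path) -> Iterator[tuple[str, str]]:
    """Yield ``(smiles, id)`` records from a SMILES file.

    Format: one record per line, ``SMILES<TAB>ID`` (the id column is
    optional); blank lines and ``#`` comment lines are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield smiles, mol_id


def read_sdf(path) -> Iterator[MolGraph]:
    """Yield MolGraphs from an SDF (V2000) file; bad records raise ParseError."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"unreadable SDF record #{i}", str(path))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"
        yield _from_rdkit(mol, name)


def connected_components(mol: MolGraph) -> list[frozenset]:
    """Partition all atoms into maximal bond-connected sets."""
    return sorted(
        (frozenset(c) for c in nx.connected_components(mol.to_networkx())),
        key=min,
    )


def carbon_components(mol: MolGraph) -> list[frozenset]:
    """Maximal connected sets of carbon atoms (edges restricted to C-C bonds)."""
    g = mol.to_networkx(carbon_only=True)
    return sorted((frozenset(c) for c in nx.connected_components(g)), key=min)
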