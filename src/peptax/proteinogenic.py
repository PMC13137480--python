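"""Detection of proteinogenic amino-acid residues in a peptide chain.

A residue of, say, L-alanine inside a peptide no longer has the free amino
acid's NH2 and COOH: depending on its position in the chain these groups are
amide-bonded, acylated, esterified, deprotonated, and so on.  The matching
rule therefore splits every template into two kinds of atoms:

* **flex points** - the amino nitrogen(s) and carboxy carbon(s).  These are
  matched by the amino-residue / carboxy-residue predicates from
  :mod:`peptax.functional_groups`, so any amino or carboxylic-acid
  derivative is a valid match there.
* **literal atoms** - everything else (the side chain and the alpha carbon).
  These must agree exactly: element, formal charge, attached hydrogen
  count, heavy-atom degree, bonds, and the CIP descriptor where the
  template fixes one.  The chirality gate is what keeps D-amino acids out.

Templates live in ``data/proteinogenic.yaml`` (one per proteinogenic amino
acid, 23 in total, with tautomer variants for arginine and histidine).
Three special rules from the class definitions are implemented as
exclusions: an aspartate/glutamate side-chain carboxy must not be an NH2
amide (that would be asparagine/glutamine), a methionine whose backbone
nitrogen is formylated is reported as N-formylmethionine only, and
isopeptide-bonded NH remains a valid aspartate/glutamate derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import networkx as nx
import yaml
from rdkit import Chem
from rdkit.Chem import rdCIPLabeler

from .functional_groups import (
    find_amino_residues,
    find_carboxy_residues,
)
from .molgraph import DOUBLE, SINGLE, MolGraph
from .residues import PeptideChain

__all__ = ["ResidueTemplate", "load_templates", "find_proteinogenic_residues"]


@dataclass(frozen=True)
class _TemplateAtom:
    element: str
    charge: int
    hcount: int
    degree: int
    cip: Optional[str]
    flex: Optional[str]  # "amino", "carboxy", "carboxy_no_nh2" or None


@dataclass
class ResidueTemplate:
    """One proteinogenic amino acid as a matchable residue pattern."""

    amino_acid_name: str
    graphs: list[nx.Graph] = field(repr=False)  # main pattern + variants
    exclusions: tuple[str, ...] = ()


class TemplateConfigError(ValueError):
    """Malformed template data file."""


_FLEX_BY_MAP = {1: "amino", 2: "carboxy", 3: "carboxy_no_nh2", 4: "amino"}


def _compile_pattern(smiles: str, name: str) -> nx.Graph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise TemplateConfigError(f"bad template SMILES for {name}: {smiles}")
    rdCIPLabeler.AssignCIPLabels(mol)

    flex: dict[int, str] = {}
    for atom in mol.GetAtoms():
        mapno = atom.GetAtomMapNum()
        if mapno:
            if mapno not in _FLEX_BY_MAP:
                raise TemplateConfigError(
                    f"unknown atom map {mapno} in template {name}"
                )
            flex[atom.GetIdx()] = _FLEX_BY_MAP[mapno]

    # placeholder oxygens on flex carboxy carbons are not part of the pattern
    drop: set[int] = set()
    for idx, kind in flex.items():
        if kind.startswith("carboxy"):
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetSymbol() == "O" and nb.GetDegree() == 1:
                    drop.add(nb.GetIdx())

    g = nx.Graph(name=name)
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if idx in drop:
            continue
        cip = atom.GetPropsAsDict().get("_CIPCode")
        g.add_node(
            idx,
            spec=_TemplateAtom(
                element=atom.GetSymbol(),
                charge=atom.GetFormalCharge(),
                hcount=atom.GetTotalNumHs(),
                degree=sum(
                    1
                    for nb in atom.GetNeighbors()
                    if nb.GetIdx() not in drop
                ),
                cip=cip if cip in ("R", "S") else None,
                flex=flex.get(idx),
            ),
        )
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in drop or j in drop:
            continue
        if bond.GetIsAromatic():
            order, aromatic = None, True
        else:
            order = {
                Chem.BondType.SINGLE: SINGLE,
                Chem.BondType.DOUBLE: DOUBLE,
                Chem.BondType.TRIPLE: 3,
            }[bond.GetBondType()]
            aromatic = False
        g.add_edge(i, j, order=order, aromatic=aromatic)
    if not any(a["spec"].flex == "amino" for _, a in g.nodes(data=True)):
        raise TemplateConfigError(f"template {name} has no flex amino point")
    if not any(
        (a["spec"].flex or "").startswith("carboxy")
        for _, a in g.nodes(data=True)
    ):
        raise TemplateConfigError(f"template {name} has no flex carboxy point")
    return g


_CACHE: list[ResidueTemplate] | None = None


def load_templates() -> list[ResidueTemplate]:
    """Load the 23 proteinogenic residue templates (cached)."""
    global _CACHE
    if _CACHE is None:
        text = (
            resources.files("peptax.data")
            .joinpath("proteinogenic.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)
        templates = []
        for entry in raw["templates"]:
            name = entry["name"]
            graphs = [_compile_pattern(entry["smiles"], name)]
            for var in entry.get("variants", []):
                graphs.append(_compile_pattern(var, name))
            templates.append(
                ResidueTemplate(
                    amino_acid_name=name,
                    graphs=graphs,
                    exclusions=tuple(entry.get("exclusions", [])),
                )
            )
        _CACHE = templates
    return _CACHE


@dataclass(frozen=True)
class _MolAtomFacts:
    element: str
    charge: int
    hcount: int
    degree: int
    cip: Optional[str]
    is_amino: bool
    is_carboxy: bool
    has_nh2_partner: bool
    has_n_formyl: bool


def _molecule_facts(mol: MolGraph) -> dict[int, _MolAtomFacts]:
    aminos = find_amino_residues(mol)
    carboxies = find_carboxy_residues(mol)
    carboxy_heads = {m.carbonyl_c for m in carboxies}
    nh2_partner = {
        m.carbonyl_c
        for m in carboxies
        if mol.element(m.single_x) == "N"
        and mol.atoms[m.single_x].num_hydrogens == 2
    }
    facts = {}
    for a in mol.atoms:
        formyl = False
        if a.element == "N":
            for nb in mol.neighbors(a.index):
                nba = mol.atoms[nb]
                if (
                    nba.element == "C"
                    and nba.num_hydrogens == 1
                    and any(
                        mol.element(o) == "O" and mol.bond_order(nb, o) == DOUBLE
                        for o in mol.neighbors(nb)
                    )
                ):
                    formyl = True
        facts[a.index] = _MolAtomFacts(
            element=a.element,
            charge=a.formal_charge,
            hcount=a.num_hydrogens,
            degree=len(mol.neighbors(a.index)),
            cip=a.stereo_descriptor,
            is_amino=a.index in aminos,
            is_carboxy=a.index in carboxy_heads,
            has_nh2_partner=a.index in nh2_partner,
            has_n_formyl=formyl,
        )
    return facts


def _node_match_factory(facts: dict[int, _MolAtomFacts]):
    def node_match(mol_attrs, tpl_attrs):
        spec: _TemplateAtom = tpl_attrs["spec"]
        f: _MolAtomFacts = facts[mol_attrs["idx"]]
        if spec.flex == "amino":
            return f.is_amino
        if spec.flex == "carboxy":
            return f.is_carboxy
        if spec.flex == "carboxy_no_nh2":
            return f.is_carboxy and not f.has_nh2_partner
        return (
            f.element == spec.element
            and f.charge == spec.charge
            and f.hcount == spec.hcount
            and f.degree == spec.degree
            and (spec.cip is None or f.cip == spec.cip)
        )

    return node_match


def _edge_match(mol_attrs, tpl_attrs):
    if tpl_attrs["aromatic"]:
        return mol_attrs["aromatic"]
    return (not mol_attrs["aromatic"]) and mol_attrs["order"] == tpl_attrs["order"]


def _mol_graph_for_matching(mol: MolGraph) -> nx.Graph:
    g = nx.Graph()
    for a in mol.atoms:
        g.add_node(a.index, idx=a.index)
    for b in mol.bonds:
        g.add_edge(b.i, b.j, order=b.order, aromatic=b.aromatic)
    return g


def _iter_matches(mol_g: nx.Graph, pattern: nx.Graph, facts):
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        mol_g,
        pattern,
        node_match=_node_match_factory(facts),
        edge_match=_edge_match,
    )
    yield from matcher.subgraph_monomorphisms_iter()


def find_proteinogenic_residues(
    mol: MolGraph, chain: PeptideChain
) -> set[tuple[str, int]]:
    """Names of proteinogenic residues found, with chain-residue attribution.

    Returns pairs ``(amino_acid_name, residue_index)`` where the index
    refers to ``chain.residues``.  A match is attributed to the chain
    residue whose member set contains the template's backbone carboxy
    carbon; matches outside the chain's residues are discarded.
    """
    facts = _molecule_facts(mol)
    mol_g = _mol_graph_for_matching(mol)
    found: set[tuple[str, int]] = set()
    for template in load_templates():
        for pattern in template.graphs:
            carboxy_nodes = [
                n
                for n, d in pattern.nodes(data=True)
                if d["spec"].flex in ("carboxy",)
            ]
            amino_nodes = [
                n
                for n, d in pattern.nodes(data=True)
                if d["spec"].flex == "amino"
            ]
            for mapping in _iter_matches(mol_g, pattern, facts):
                inv = {tpl: m for m, tpl in mapping.items()}
                if "no_n_formyl" in template.exclusions and any(
                    facts[inv[n]].has_n_formyl for n in amino_nodes
                ):
                    continue
                anchor = inv[carboxy_nodes[0]]
                for i, members in enumerate(chain.member_sets):
                    if anchor in members:
                        found.add((template.amino_acid_name, i))
                        break
    return found
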