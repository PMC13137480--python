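"""Amide bonds, amino residues and carboxylic-acid-derivative groups.

These three patterns are the functional vocabulary of the peptide rules:

* An **amide bond** is a (C, O, N) triple in either tautomeric form: the
  amidic form C(=O)-N, or the imidic form C(-OH)=N / C(-O^-)=N where the
  singly bonded oxygen carries one hydrogen or a -1 charge.
* An **amino residue** is a nitrogen whose heavy neighbours are all carbons,
  each attached by a single bond or through an amide bond with that carbon.
  This generalises "amino group" just enough to cover acylated/alkylated
  amines and peptide-bond nitrogens in either tautomer.
* A **carboxy residue** (carboxylic acid or derivative) is a carbon with a
  double-bonded oxygen and a single-bonded heteroatom X: RC(=O)X.  X=H
  (aldehydes) and X=C (ketones) never match - X must be a heteroatom.
"""

from __future__ import annotations

from dataclasses import dataclass

from .molgraph import DOUBLE, SINGLE, MolGraph

__all__ = [
    "AmideBondMatch",
    "CarboxyMatch",
    "find_amide_bonds",
    "find_amino_residues",
    "find_carboxy_residues",
]


@dataclass(frozen=True)
class AmideBondMatch:
    carbonyl_c: int
    oxygen: int
    nitrogen: int
    form: str  # "amidic", "imidic" or "imidic-deprotonated"


@dataclass(frozen=True)
class CarboxyMatch:
    carbonyl_c: int
    double_o: int
    single_x: int


def find_amide_bonds(mol: MolGraph) -> set[AmideBondMatch]:
    """All C/O/N triples forming an amide bond, in either tautomeric form."""
    matches: set[AmideBondMatch] = set()
    for c in mol.atoms_of_element("C"):
        for o in mol.neighbors(c):
            if mol.element(o) != "O":
                continue
            co = mol.bond_order(c, o)
            for n in mol.neighbors(c):
                if mol.element(n) != "N":
                    continue
                cn = mol.bond_order(c, n)
                if co == DOUBLE and cn == SINGLE:
                    matches.add(AmideBondMatch(c, o, n, "amidic"))
                elif co == SINGLE and cn == DOUBLE:
                    oxy = mol.atoms[o]
                    if oxy.num_hydrogens == 1:
                        matches.add(AmideBondMatch(c, o, n, "imidic"))
                    elif oxy.formal_charge == -1 and oxy.num_hydrogens == 0:
                        matches.add(
                            AmideBondMatch(c, o, n, "imidic-deprotonated")
                        )
    return matches


def find_amino_residues(mol: MolGraph) -> set[int]:
    """Nitrogens bonded only to carbons, singly or through an amide bond."""
    amides = find_amide_bonds(mol)
    amide_cn = {(m.carbonyl_c, m.nitrogen) for m in amides}
    result: set[int] = set()
    for n in mol.atoms_of_element("N"):
        ok = True
        for nb in mol.neighbors(n):
            if mol.element(nb) != "C":
                ok = False
                break
            if mol.bond_order(n, nb) == SINGLE:
                continue
            if (nb, n) in amide_cn:
                continue
            ok = False
            break
        if ok:
            result.add(n)
    return result


def find_carboxy_residues(mol: MolGraph) -> set[CarboxyMatch]:
    """All RC(=O)X triples with X a single-bonded heteroatom.

    A carbon with two eligible single-bonded heteroatoms yields one match per
    distinct (C, =O, X) triple.
    """
    matches: set[CarboxyMatch] = set()
    for c in mol.atoms_of_element("C"):
        doubles = [
            o
            for o in mol.neighbors(c)
            if mol.element(o) == "O" and mol.bond_order(c, o) == DOUBLE
        ]
        if not doubles:
            continue
        singles = [
            x
            for x in mol.neighbors(c)
            if mol.is_heteroatom(x) and mol.bond_order(c, x) == SINGLE
        ]
        for o in doubles:
            for x in singles:
                matches.add(CarboxyMatch(c, o, x))
    return matches
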