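"""Charge typing: salt, anion, cation, zwitterion or neutral.

Every molecule falls in exactly one of the five categories:

* **salt** - two distinct connected components exist, one with a positive and
  one with a negative charge sum.  The net charge of the whole assembly is
  *not* required to be zero (e.g. sodium salts of multi-acids).
* **anion / cation** - not a salt, and the net formal charge is negative /
  positive.
* **zwitterion** - net charge zero and some connected component carries a
  positively and a negatively charged atom that are *not* bonded to each
  other.  Ylides (the only charged pair being adjacent) are deliberately not
  zwitterions and fall through to neutral.
* **neutral** - everything else.

The salt test runs first: an assembly of oppositely charged components is a
salt even if one component would qualify as a zwitterion on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .molgraph import MolGraph, connected_components

__all__ = ["ChargeCategory", "ChargeResult", "is_salt", "classify_charge"]

CATEGORIES = ("salt", "anion", "cation", "zwitterion", "neutral")


@dataclass(frozen=True)
class ChargeResult:
    category: str
    # (positive, negative) witness: atom indices for zwitterions,
    # component frozensets for salts, None otherwise.
    witness: Optional[tuple] = None


def _component_charge(mol: MolGraph, component: frozenset) -> int:
    return sum(mol.atoms[i].formal_charge for i in component)


def is_salt(mol: MolGraph) -> tuple[bool, Optional[tuple]]:
    """True iff distinct components with positive / negative charge sums exist."""
    comps = connected_components(mol)
    positives = [c for c in comps if _component_charge(mol, c) > 0]
    negatives = [c for c in comps if _component_charge(mol, c) < 0]
    for pos in positives:
        for neg in negatives:
            if pos is not neg:
                return True, (pos, neg)
    return False, None


def _zwitterion_witness(mol: MolGraph) -> Optional[tuple[int, int]]:
    """First non-adjacent (+,-) atom pair within one component, by index order."""
    for comp in connected_components(mol):
        members = sorted(comp)
        pos = [i for i in members if mol.atoms[i].formal_charge > 0]
        neg = [i for i in members if mol.atoms[i].formal_charge < 0]
        for p in pos:
            for n in neg:
                if not mol.has_bond(p, n):
                    return (p, n)
    return None


def classify_charge(mol: MolGraph) -> ChargeResult:
    """Assign exactly one of salt/anion/cation/zwitterion/neutral."""
    salt, witness = is_salt(mol)
    if salt:
        return ChargeResult("salt", witness)
    net = mol.net_charge
    if net < 0:
        return ChargeResult("anion")
    if net > 0:
        return ChargeResult("cation")
    zw = _zwitterion_witness(mol)
    if zw is not None:
        return ChargeResult("zwitterion", zw)
    return ChargeResult("neutral")
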