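"""The 67-class peptide taxonomy and the classification pipeline.

The registry is built from three orthogonal facets of a peptide structure:

* **size** - the maximal number n of amino-acid residues in one
  amide-linked chain: oligopeptide structure (2-9), polypeptide structure
  (>= 10), and the exact-size di-/tri-/tetra-/pentapeptide structures.
* **charge** - the five-way partition salt / anion / cation / zwitterion /
  neutral, giving peptide salt, peptide anion, peptide cation, peptide
  zwitterion and (neutral) peptide.
* **composition** - one "<amino acid> peptide structure" class per
  proteinogenic amino acid whose residue occurs in the chain.

Size and charge combine pairwise (oligopeptide cation, dipeptide
zwitterion, ...), and two skeleton-defined classes (2,5-diketopiperazines
under dipeptide, emericellamides under pentapeptide) complete the registry:
1 root + 6 size + 5 charge + 30 combinations + 2 skeletons + 23 residue
classes = 67, of which 14 carry ChEBI cross-references.

``classify_molecule`` runs the four classification steps - charge, chain
length, size/charge algebra plus skeletons, proteinogenic residues - and
returns the closure-complete class set with justification witnesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .charge import ChargeResult, classify_charge
from .molgraph import MolGraph
from .proteinogenic import find_proteinogenic_residues, load_templates
from .residues import (
    CapacityError,
    DEFAULT_CARBON_COMPONENT_LIMIT,
    DEFAULT_SEARCH_BUDGET,
    PeptideChain,
    SearchBudgetExceeded,
    find_building_blocks,
    max_chain_length,
)
from .substructures import is_diketopiperazine, is_emericellamide

__all__ = [
    "PeptideClass",
    "ClassificationResult",
    "Taxonomy",
    "build_taxonomy",
    "classify_molecule",
    "check_disjointness",
]

OLIGO_MAX = 9  # oligopeptides have 2..9 residues; polypeptides >= 10

_SIZES = {
    "di": (2, 2),
    "tri": (3, 3),
    "tetra": (4, 4),
    "penta": (5, 5),
    "oligo": (2, OLIGO_MAX),
    "poly": (10, None),
}

# charge facet -> name of the charge-only class and suffix for combinations
_CHARGE_CLASS = {
    "neutral": ("peptide", ""),
    "anion": ("peptide anion", " anion"),
    "cation": ("peptide cation", " cation"),
    "zwitterion": ("peptide zwitterion", " zwitterion"),
    "salt": ("peptide salt", " salt"),
}

_CHEBI_IDS = {
    "peptide": "CHEBI:16670",
    "peptide anion": "CHEBI:60334",
    "peptide cation": "CHEBI:60194",
    "peptide zwitterion": "CHEBI:60466",
    "oligopeptide": "CHEBI:25676",
    "polypeptide": "CHEBI:15841",
    "dipeptide": "CHEBI:46761",
    "tripeptide": "CHEBI:47923",
    "tetrapeptide": "CHEBI:48030",
    "pentapeptide": "CHEBI:48545",
    "dipeptide zwitterion": "CHEBI:90799",
    "tripeptide zwitterion": "CHEBI:155837",
    "2,5-diketopiperazines": "CHEBI:65061",
    "emericellamide": "CHEBI:64372",
}


@dataclass(frozen=True)
class PeptideClass:
    name: str
    charge_facet: str = "any"  # any / neutral / anion / cation / zwitterion / salt
    size_lower: Optional[int] = None
    size_upper: Optional[int] = None
    skeleton_facet: Optional[str] = None
    residue_facet: Optional[str] = None
    parents: tuple[str, ...] = ()
    chebi_id: Optional[str] = None


class Taxonomy:
    """Registry of peptide classes with parent-closure utilities."""

    def __init__(self, classes: list[PeptideClass]):
        self.classes = {c.name: c for c in classes}
        if len(self.classes) != len(classes):
            raise ValueError("duplicate class names in taxonomy")
        for c in classes:
            for p in c.parents:
                if p not in self.classes:
                    raise ValueError(f"unknown parent {p!r} of {c.name!r}")

    def __len__(self) -> int:
        return len(self.classes)

    def __getitem__(self, name: str) -> PeptideClass:
        return self.classes[name]

    def __iter__(self):
        return iter(self.classes.values())

    def ancestors(self, name: str) -> set[str]:
        out: set[str] = set()
        stack = list(self.classes[name].parents)
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.classes[p].parents)
        return out

    def closure(self, names: set[str]) -> set[str]:
        out = set(names)
        for n in names:
            out |= self.ancestors(n)
        return out

    def to_table(self) -> list[tuple[str, str, str]]:
        """(name, parents joined by '|', chebi id or '') rows, sorted by name."""
        return [
            (c.name, "|".join(sorted(c.parents)), c.chebi_id or "")
            for c in sorted(self.classes.values(), key=lambda c: c.name)
        ]

    def to_obo(self) -> str:
        """OBO-flavoured stanza export."""
        lines = ["format-version: 1.2", "ontology: peptax", ""]
        names = sorted(self.classes)
        ident = {n: f"PEPTAX:{i:04d}" for i, n in enumerate(names, 1)}
        for n in names:
            c = self.classes[n]
            lines.append("[Term]")
            lines.append(f"id: {ident[n]}")
            lines.append(f"name: {n}")
            if c.chebi_id:
                lines.append(f"xref: {c.chebi_id}")
            for p in sorted(c.parents):
                lines.append(f"is_a: {ident[p]} ! {p}")
            lines.append("")
        return "\n".join(lines)


def build_taxonomy() -> Taxonomy:
    """Construct the 67-class registry."""
    classes: list[PeptideClass] = []

    def add(name, **kw):
        classes.append(
            PeptideClass(name=name, chebi_id=_CHEBI_IDS.get(name), **kw)
        )

    add("peptide structure", size_lower=2)

    # size-structure classes
    add(
        "oligopeptide structure",
        size_lower=2,
        size_upper=OLIGO_MAX,
        parents=("peptide structure",),
    )
    add("polypeptide structure", size_lower=10, parents=("peptide structure",))
    for stem in ("di", "tri", "tetra", "penta"):
        lo, hi = _SIZES[stem]
        add(
            f"{stem}peptide structure",
            size_lower=lo,
            size_upper=hi,
            parents=("oligopeptide structure",),
        )

    # charge classes
    for facet, (cls_name, _) in _CHARGE_CLASS.items():
        add(
            cls_name,
            charge_facet=facet,
            size_lower=2,
            parents=("peptide structure",),
        )

    # charge x size combinations
    for facet, (cls_name, suffix) in _CHARGE_CLASS.items():
        for stem in ("oligo", "poly"):
            lo, hi = _SIZES[stem]
            add(
                f"{stem}peptide{suffix}",
                charge_facet=facet,
                size_lower=lo,
                size_upper=hi,
                parents=(cls_name, f"{stem}peptide structure"),
            )
        for stem in ("di", "tri", "tetra", "penta"):
            lo, hi = _SIZES[stem]
            add(
                f"{stem}peptide{suffix}",
                charge_facet=facet,
                size_lower=lo,
                size_upper=hi,
                parents=(f"oligopeptide{suffix}", f"{stem}peptide structure"),
            )

    # skeleton classes
    add(
        "2,5-diketopiperazines",
        charge_facet="neutral",
        size_lower=2,
        size_upper=2,
        skeleton_facet="2,5-diketopiperazine",
        parents=("dipeptide",),
    )
    add(
        "emericellamide",
        charge_facet="neutral",
        size_lower=5,
        size_upper=5,
        skeleton_facet="emericellamide",
        parents=("pentapeptide",),
    )

    # proteinogenic residue classes
    for template in load_templates():
        add(
            f"{template.amino_acid_name} peptide structure",
            size_lower=2,
            residue_facet=template.amino_acid_name,
            parents=("peptide structure",),
        )

    return Taxonomy(classes)


@dataclass
class ClassificationResult:
    molecule_id: str
    classes: set[str] = field(default_factory=set)
    chain_length: int = 0
    charge: Optional[ChargeResult] = None
    proteinogenic: set[tuple[str, int]] = field(default_factory=set)
    status: str = "ok"  # ok / unclassified-budget / unclassified-size / parse-error
    justification: dict = field(default_factory=dict)


def _size_class_names(n: int, suffix: str) -> list[str]:
    names = []
    for stem, (lo, hi) in _SIZES.items():
        if n >= lo and (hi is None or n <= hi):
            names.append(f"{stem}peptide{suffix}")
    return names


def classify_molecule(
    mol: MolGraph,
    taxonomy: Optional[Taxonomy] = None,
    budget: int = DEFAULT_SEARCH_BUDGET,
    max_carbon_components: int = DEFAULT_CARBON_COMPONENT_LIMIT,
) -> ClassificationResult:
    """Run the full four-step classification on one molecule."""
    if taxonomy is None:
        taxonomy = build_taxonomy()
    result = ClassificationResult(molecule_id=mol.source_id)

    charge = classify_charge(mol)
    result.charge = charge
    try:
        blocks = find_building_blocks(mol, max_carbon_components)
        n, chain = max_chain_length(mol, blocks, budget=budget)
    except CapacityError as err:
        result.status = "unclassified-size"
        result.justification["error"] = str(err)
        return result
    except SearchBudgetExceeded as err:
        result.status = "unclassified-budget"
        result.justification["error"] = str(err)
        return result
    result.chain_length = n

    if n < 2:
        return result

    direct: set[str] = set()
    _, suffix = _CHARGE_CLASS[charge.category]
    direct.update(_size_class_names(n, " structure"))
    direct.update(_size_class_names(n, suffix))
    closed = taxonomy.closure(direct)

    if is_diketopiperazine(mol, closed):
        closed |= taxonomy.closure({"2,5-diketopiperazines"})
    if is_emericellamide(mol, closed):
        closed |= taxonomy.closure({"emericellamide"})

    if chain is not None:
        residues = find_proteinogenic_residues(mol, chain)
        result.proteinogenic = residues
        for name, _ in residues:
            closed |= taxonomy.closure({f"{name} peptide structure"})
        result.justification["chain_members"] = [
            sorted(ms) for ms in chain.member_sets
        ]
        result.justification["links"] = [
            (m.carbonyl_c, m.oxygen, m.nitrogen, m.form) for m in chain.links
        ]
    if charge.witness is not None:
        result.justification["charge_witness"] = (
            tuple(sorted(w) if isinstance(w, frozenset) else w for w in charge.witness)
        )

    result.classes = closed
    return result


# classes that must be pairwise disjoint: the five charge categories, the
# exact-size classes, and oligo- vs polypeptide, each in every charge variant
def _disjoint_groups() -> list[list[str]]:
    groups = [
        [
            "peptide",
            "peptide anion",
            "peptide cation",
            "peptide zwitterion",
            "peptide salt",
        ]
    ]
    suffixes = [" structure"] + [s for _, s in _CHARGE_CLASS.values()]
    for suffix in suffixes:
        groups.append(
            [f"{stem}peptide{suffix}" for stem in ("di", "tri", "tetra", "penta")]
        )
        groups.append([f"oligopeptide{suffix}", f"polypeptide{suffix}"])
    return groups


_DISJOINT_GROUPS = _disjoint_groups()


def check_disjointness(result) -> list[tuple[str, str]]:
    """Pairs of assigned classes that violate a disjointness axiom.

    Accepts a :class:`ClassificationResult` or a plain class-name set.
    """
    classes = result.classes if isinstance(result, ClassificationResult) else result
    violations = []
    for group in _DISJOINT_GROUPS:
        present = [c for c in group if c in classes]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                violations.append((present[i], present[j]))
    return violations
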