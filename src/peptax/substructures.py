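"""Skeleton-based subclasses: 2,5-diketopiperazines and emericellamides.

Both classes are defined by a fixed substructure *plus* a superclass gate:
a 2,5-diketopiperazine must already be a (neutral) dipeptide and an
emericellamide a pentapeptide.  The gate matters in practice - e.g. the
deprotonated anion of a diketopiperazine still contains the ring but is a
dipeptide *anion*, not a dipeptide, and therefore not a
2,5-diketopiperazine.

Patterns are stored declaratively in ``data/skeletons.yaml`` as SMARTS so
further skeleton classes can be added without code changes.  Matching runs
on the RDKit molecule attached at parse time; the emericellamide pattern is
chirality-sensitive (unassigned stereocentres in the query fail the match).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml
from rdkit import Chem

from .molgraph import MolGraph

__all__ = [
    "SkeletonTemplate",
    "load_skeleton_templates",
    "matches_skeleton",
    "is_diketopiperazine",
    "is_emericellamide",
]


@dataclass(frozen=True)
class SkeletonTemplate:
    name: str
    required_class: str
    smarts: str
    use_chirality: bool

    @property
    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"invalid skeleton SMARTS for {self.name}")
        return q


_CACHE: list[SkeletonTemplate] | None = None


def load_skeleton_templates() -> list[SkeletonTemplate]:
    global _CACHE
    if _CACHE is None:
        text = (
            resources.files("peptax.data").joinpath("skeletons.yaml").read_text()
        )
        raw = yaml.safe_load(text)
        _CACHE = [
            SkeletonTemplate(
                name=entry["name"],
                required_class=entry["required_class"],
                smarts=entry["smarts"],
                use_chirality=bool(entry.get("use_chirality", False)),
            )
            for entry in raw["skeletons"]
        ]
    return _CACHE


def matches_skeleton(mol: MolGraph, template: SkeletonTemplate) -> bool:
    rdmol = mol._rdkit_mol
    if rdmol is None:
        raise ValueError("MolGraph has no RDKit molecule attached")
    return rdmol.HasSubstructMatch(
        template.query, useChirality=template.use_chirality
    )


def _skeleton_class(
    mol: MolGraph, classes_so_far: set[str], name: str
) -> bool:
    tpl = next(t for t in load_skeleton_templates() if t.name == name)
    if tpl.required_class not in classes_so_far:
        return False
    return matches_skeleton(mol, tpl)


def is_diketopiperazine(mol: MolGraph, classes_so_far: set[str]) -> bool:
    """Piperazine-2,5-dione ring present and the molecule is a dipeptide."""
    return _skeleton_class(mol, classes_so_far, "2,5-diketopiperazine")


def is_emericellamide(mol: MolGraph, classes_so_far: set[str]) -> bool:
    """Emericellamide depsipeptide core present and the molecule is a pentapeptide."""
    return _skeleton_class(mol, classes_so_far, "emericellamide")
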