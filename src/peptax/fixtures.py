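"""Curated test molecules and a synthetic peptide generator.

The curated fixtures are SMILES transcriptions of structures discussed in
the peptide-classification literature (worked examples like the Met-beta-Ala
dipeptide, temocapril, methicillin) plus a few constructed edge cases; each
carries a provenance note.  The ``emericellamide-core`` entry is synthetic:
a minimal molecule built from the emericellamide skeleton template itself.

The generator assembles peptides from amino-acid monomers by textual SMILES
concatenation (each monomer contributes an ``N[C@@H](R)C(=O)`` unit, the
chain ends in ``O``), applies terminal modifications, and derives the
expected classification from the construction parameters.  Because the
expected labels are computed from the classification rules and not from the
classifier, generated peptides double as ground-truth test cases.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "CURATED",
    "curated_fixture",
    "GeneratorSpec",
    "SpecError",
    "generate_peptide",
    "random_spec",
    "PROTEINOGENIC_MONOMERS",
]

# name -> (smiles, provenance note)
CURATED: dict[str, tuple[str, str]] = {
    "met-beta-ala": (
        "CSCC[C@H](N)C(=O)NCCC(O)=O",
        "Met-beta-Ala dipeptide (CHEBI:74700), the canonical worked example "
        "of peptide-bond formation from L-methionine and beta-alanine",
    ),
    "temocapril": (
        "O=C1N(CC(O)=O)C[C@@H](c2cccs2)SC[C@@H]1N[C@@H](CCc3ccccc3)C(=O)OCC",
        "temocapril (CHEBI:135771); dipeptide with 5 carbon sections and "
        "heteroatoms shared between sections",
    ),
    "methicillin": (
        "CC1(C)S[C@@H]2[C@H](NC(=O)c3c(OC)cccc3OC)C(=O)N2[C@H]1C(O)=O",
        "methicillin (CHEBI:6827); penicillin classified as a dipeptide by "
        "the heteroatom-splitting rule",
    ),
    "aspartame": (
        "COC(=O)[C@H](Cc1ccccc1)NC(=O)[C@@H](N)CC(O)=O",
        "aspartame (CHEBI:2877); methyl ester of a dipeptide, the ester "
        "counting as a carboxylic-acid derivative",
    ),
    "ala-his-zwitterion": (
        "C[C@H]([NH3+])C(=O)NC(Cc1c[nH]cn1)C([O-])=O",
        "Ala-His zwitterion (CHEBI:74388); protonated N-terminus and "
        "deprotonated C-terminus, histidine drawn in one imidazole tautomer",
    ),
    "beta-alanyl-L-arginium": (
        "NCCC(=O)N[C@@H](CCCNC(N)=[NH2+])C(O)=O",
        "beta-alanyl-L-arginium (CHEBI:143157); dipeptide cation with a "
        "protonated guanidinium, 7 taxonomy classes expected",
    ),
    "boc-gln-ala-arg-amc": (
        "CC(C)(C)OC(=O)N[C@@H](CCC(N)=O)C(=O)N[C@@H](C)C(=O)"
        "N[C@@H](CCCNC(N)=N)C(=O)Nc1ccc2C(C)=CC(=O)Oc2c1",
        "Boc-Gln-Ala-Arg-7-amino-4-methylcoumarin (CHEBI:84832); the "
        "aminocoumarin counts as a fourth residue under the structural rules",
    ),
    "glutaurine": (
        "N[C@@H](CCC(=O)NCCS(O)(=O)=O)C(O)=O",
        "gamma-glutamyltaurine (CHEBI:27694); the taurine block carries a "
        "sulfonate instead of a carboxy group, so only one residue is found",
    ),
    "phosphoramide-fragment": (
        "CNP(=O)(O)O",
        "phosphoramide fragment as in phosphoramidon (CHEBI:45363); the "
        "N-P bond disqualifies the nitrogen as an amino residue",
    ),
    "cyclo-gly-gly": (
        "O=C1CNC(=O)CN1",
        "cyclo(Gly-Gly), glycine anhydride; minimal 2,5-diketopiperazine",
    ),
    "emericellamide-core": (
        "O=C1CNC(=O)[C@H](C)[C@@H](C)OC(=O)[C@H](C)NC(=O)[C@H](C)"
        "NC(=O)[C@H](CC(C)C)NC(=O)[C@H](C(C)C)N1",
        "synthetic minimal emericellamide core: the class skeleton with "
        "methyl groups at the two hydrocarbyl attachment points",
    ),
    "trimethylammonium-ylide": (
        "[CH2-][N+](C)(C)C",
        "constructed ylide: adjacent opposite charges, classified neutral",
    ),
}


def curated_fixture(name: str) -> tuple[str, str]:
    """Return ``(smiles, provenance note)`` for a curated fixture."""
    try:
        return CURATED[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(CURATED)}"
        ) from None


# ---------------------------------------------------------------------------
# synthetic peptide generator
# ---------------------------------------------------------------------------

#: monomer name -> (body SMILES unit ending in C(=O), is_proteinogenic)
#: bodies chain as body1 + body2 + ... + "O"
_MONOMERS: dict[str, str] = {
    "alanine": "N[C@@H](C)C(=O)",
    "arginine": "N[C@@H](CCCNC(N)=N)C(=O)",
    "asparagine": "N[C@@H](CC(N)=O)C(=O)",
    "aspartic acid": "N[C@@H](CC(O)=O)C(=O)",
    "cysteine": "N[C@@H](CS)C(=O)",
    "glutamic acid": "N[C@@H](CCC(O)=O)C(=O)",
    "glutamine": "N[C@@H](CCC(N)=O)C(=O)",
    "glycine": "NCC(=O)",
    "histidine": "N[C@@H](Cc1c[nH]cn1)C(=O)",
    "isoleucine": "N[C@@H]([C@@H](C)CC)C(=O)",
    "leucine": "N[C@@H](CC(C)C)C(=O)",
    "lysine": "N[C@@H](CCCCN)C(=O)",
    "methionine": "N[C@@H](CCSC)C(=O)",
    "N-formylmethionine": "N(C=O)[C@@H](CCSC)C(=O)",
    "phenylalanine": "N[C@@H](Cc1ccccc1)C(=O)",
    "proline": "N1CCC[C@H]1C(=O)",
    "pyrrolysine": "N[C@@H](CCCCNC(=O)[C@H]1[C@H](C)CC=N1)C(=O)",
    "selenocysteine": "N[C@@H](C[SeH])C(=O)",
    "serine": "N[C@@H](CO)C(=O)",
    "threonine": "N[C@@H]([C@@H](C)O)C(=O)",
    "tryptophan": "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)",
    "tyrosine": "N[C@@H](Cc1ccc(O)cc1)C(=O)",
    "valine": "N[C@@H](C(C)C)C(=O)",
    # non-proteinogenic extras
    "beta-alanine": "NCCC(=O)",
}

PROTEINOGENIC_MONOMERS = tuple(
    n for n in _MONOMERS if n != "beta-alanine"
)

#: donor variants used for isopeptide junctions: the chain continues from
#: the side-chain carboxy group, the main carboxy becomes a free branch
_ISO_DONOR: dict[str, str] = {
    "aspartic acid": "N[C@H](C(O)=O)CC(=O)",
    "glutamic acid": "N[C@H](C(O)=O)CCC(=O)",
}

#: acceptor variant: the incoming peptide bond uses the lysine side-chain
#: nitrogen, the alpha amino group stays free
_ISO_ACCEPTOR: dict[str, str] = {
    "lysine": "NCCCC[C@H](N)C(=O)",
}

MODIFICATIONS = (
    "c-terminal ester",
    "n-acyl",
    "n-alkyl",
    "deprotonate c-terminus",
    "protonate n-terminus",
    "counter-ion",
)

_SIZE_STEMS = {
    "di": (2, 2),
    "tri": (3, 3),
    "tetra": (4, 4),
    "penta": (5, 5),
    "oligo": (2, 9),
    "poly": (10, None),
}
_SUFFIX = {
    "neutral": "",
    "anion": " anion",
    "cation": " cation",
    "zwitterion": " zwitterion",
    "salt": " salt",
}


class SpecError(ValueError):
    """Chemically impossible generator specification."""


@dataclass(frozen=True)
class GeneratorSpec:
    monomers: tuple[str, ...]
    bond_plan: tuple[str, ...] = ()  # per junction: "eu" or "iso"
    modifications: frozenset = frozenset()
    seed: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.monomers)


def _expected_charge(mods: frozenset) -> str:
    prot = "protonate n-terminus" in mods
    deprot = "deprotonate c-terminus" in mods
    counter = "counter-ion" in mods
    if counter:
        return "salt"
    if prot and deprot:
        return "zwitterion"
    if prot:
        return "cation"
    if deprot:
        return "anion"
    return "neutral"


def _expected_classes(n: int, charge: str, residues: set[str]) -> set[str]:
    if n < 2:
        return set()
    classes = {"peptide structure"}
    suffix = _SUFFIX[charge]
    charge_cls = "peptide" + (suffix if suffix else "")
    classes.add(charge_cls)
    for stem, (lo, hi) in _SIZE_STEMS.items():
        if n >= lo and (hi is None or n <= hi):
            classes.add(f"{stem}peptide structure")
            classes.add(f"{stem}peptide{suffix}")
    for r in residues:
        classes.add(f"{r} peptide structure")
    return classes


def generate_peptide(spec: GeneratorSpec) -> tuple[str, dict]:
    """Assemble a peptide SMILES and its expected classification.

    Returns ``(smiles, expected)`` with expected keys ``chain_length``,
    ``charge`` and ``classes``.
    """
    n = spec.n_residues
    if n < 1:
        raise SpecError("need at least one monomer")
    unknown = [m for m in spec.monomers if m not in _MONOMERS]
    if unknown:
        raise SpecError(f"unknown monomers: {unknown}")
    plan = spec.bond_plan or ("eu",) * (n - 1)
    if len(plan) != n - 1:
        raise SpecError("bond plan must have one entry per junction")
    mods = frozenset(spec.modifications)
    bad = mods - set(MODIFICATIONS)
    if bad:
        raise SpecError(f"unknown modifications: {sorted(bad)}")
    if "c-terminal ester" in mods and "deprotonate c-terminus" in mods:
        raise SpecError("cannot esterify and deprotonate the C-terminus")
    if "n-acyl" in mods and "n-alkyl" in mods:
        raise SpecError("choose one N-terminal substituent")
    if "counter-ion" in mods and not (
        ("protonate n-terminus" in mods) ^ ("deprotonate c-terminus" in mods)
    ):
        raise SpecError(
            "counter-ion requires exactly one charged terminus to balance"
        )
    if "protonate n-terminus" in mods and mods & {"n-acyl", "n-alkyl"}:
        raise SpecError("cannot protonate a substituted N-terminus")
    if "N-formylmethionine" in spec.monomers:
        if spec.monomers.index("N-formylmethionine") != 0:
            raise SpecError("N-formylmethionine only fits at the N-terminus")
        if mods & {"n-acyl", "n-alkyl", "protonate n-terminus"}:
            raise SpecError("the fMet nitrogen is already formylated")

    bodies = []
    for i, mono in enumerate(spec.monomers):
        body = _MONOMERS[mono]
        if i < n - 1 and plan[i] == "iso":
            if mono in _ISO_DONOR:
                body = _ISO_DONOR[mono]
            elif spec.monomers[i + 1] in _ISO_ACCEPTOR:
                pass  # acceptor side handles the junction
            else:
                raise SpecError(
                    f"no isopeptide linkage available at junction {i}"
                )
        if i > 0 and plan[i - 1] == "iso" and mono in _ISO_ACCEPTOR:
            if spec.monomers[i - 1] not in _ISO_DONOR:
                body = _ISO_ACCEPTOR[mono]
        bodies.append(body)

    smiles = "".join(bodies) + "O"
    if "protonate n-terminus" in mods:
        if smiles.startswith("N1"):
            smiles = "[NH2+]1" + smiles[2:]
        else:
            smiles = "[NH3+]" + smiles[1:]
    if "n-acyl" in mods:
        smiles = "CC(=O)" + smiles
    if "n-alkyl" in mods:
        smiles = "C" + smiles
    if "deprotonate c-terminus" in mods:
        smiles = smiles[:-1] + "[O-]"
    if "c-terminal ester" in mods:
        smiles = smiles + "C"
    if "counter-ion" in mods:
        smiles += ".[Cl-]" if "protonate n-terminus" in mods else ".[Na+]"

    residues = (
        {m for m in spec.monomers if m in PROTEINOGENIC_MONOMERS}
        if n >= 2
        else set()
    )
    # a pyrrolysine residue is an N(epsilon)-acylated lysine, and amino
    # groups admit acyl substituents, so the lysine pattern matches too
    if "pyrrolysine" in residues:
        residues.add("lysine")
    charge = _expected_charge(mods)
    expected = {
        "chain_length": n,
        "charge": charge,
        "classes": _expected_classes(n, charge, residues),
    }
    return smiles, expected


def random_spec(
    rng: random.Random,
    n_range: tuple[int, int] = (2, 12),
    pool: Optional[tuple[str, ...]] = None,
    allow_charge_mods: bool = True,
) -> GeneratorSpec:
    """Draw a random eupeptide GeneratorSpec (reproducible via ``rng``)."""
    if pool is None:
        pool = tuple(m for m in PROTEINOGENIC_MONOMERS if m != "N-formylmethionine")
    n = rng.randint(*n_range)
    monomers = tuple(rng.choice(pool) for _ in range(n))
    mods: set[str] = set()
    if allow_charge_mods:
        mods = set(
            rng.choice(
                [
                    (),
                    ("protonate n-terminus",),
                    ("deprotonate c-terminus",),
                    ("protonate n-terminus", "deprotonate c-terminus"),
                    ("deprotonate c-terminus", "counter-ion"),
                    ("protonate n-terminus", "counter-ion"),
                ]
            )
        )
    return GeneratorSpec(
        monomers=monomers,
        modifications=frozenset(mods),
        seed=rng.randint(0, 2**31 - 1),
    )
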