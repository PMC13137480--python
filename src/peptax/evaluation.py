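"""Inter-rater agreement between two class labelings (Cohen's kappa).

Counts are kept in the four-column form used for ontology comparisons:
``total`` molecules positive under either labeling, ``ours`` / ``chebi``
positives under each labeling separately, and ``neither`` negatives under
both; ``both = ours + chebi - total`` is derived.  Cohen's kappa is then

    kappa = 2 * (Both*Neither + (Both-ChEBI)*(Ours-Both)) /
            (Ours*(Ours-Both+Neither) + ChEBI*(ChEBI-Both+Neither))

which is the standard 2x2 kappa rewritten in these columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd

from .taxonomy import check_disjointness

__all__ = ["AgreementCounts", "UndefinedKappaError", "cohens_kappa", "compare_labelings"]


class UndefinedKappaError(ZeroDivisionError):
    """Kappa denominator is zero for these counts."""


@dataclass(frozen=True)
class AgreementCounts:
    total: int
    ours: int
    chebi: int
    neither: int

    def __post_init__(self):
        if min(self.total, self.ours, self.chebi, self.neither) < 0:
            raise ValueError("counts must be non-negative")
        if self.both < 0:
            raise ValueError("ours + chebi - total must be non-negative")

    @property
    def both(self) -> int:
        return self.ours + self.chebi - self.total


def cohens_kappa(counts: AgreementCounts) -> float:
    """Cohen's kappa for one class, from the Total/Ours/ChEBI/Neither row."""
    both = counts.both
    ours, chebi, neither = counts.ours, counts.chebi, counts.neither
    denom = ours * (ours - both + neither) + chebi * (chebi - both + neither)
    if denom == 0:
        raise UndefinedKappaError(f"kappa undefined for {counts}")
    num = 2 * (both * neither + (both - chebi) * (ours - both))
    return num / denom


def round_half_even(x: float, digits: int = 3) -> float:
    """Report rounding: half-even to table precision."""
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -digits, ROUND_HALF_EVEN))


def compare_labelings(
    ours: dict[str, set],
    reference: dict[str, set],
    universe_size: int,
) -> tuple[pd.DataFrame, int]:
    """Per-class agreement table plus a disjointness-consistency count.

    ``ours`` and ``reference`` map class names to sets of molecule ids over
    one common universe of ``universe_size`` molecules (flattened class
    membership).  Returns the per-class table and the number of molecules
    whose newly assigned classes (in ``ours`` but not ``reference``)
    contradict a reference class under the disjointness axioms.
    """
    universe: set = set()
    for members in list(ours.values()) + list(reference.values()):
        universe |= members
    if len(universe) > universe_size:
        raise ValueError(
            f"{len(universe)} labelled molecules exceed universe size "
            f"{universe_size}"
        )
    rows = []
    for cls in sorted(set(ours) | set(reference)):
        a = ours.get(cls, set())
        b = reference.get(cls, set())
        counts = AgreementCounts(
            total=len(a | b),
            ours=len(a),
            chebi=len(b),
            neither=universe_size - len(a | b),
        )
        try:
            kappa = round_half_even(cohens_kappa(counts))
        except UndefinedKappaError:
            kappa = float("nan")
        rows.append(
            {
                "class": cls,
                "total": counts.total,
                "ours_abs": counts.ours,
                "ours_rel": (
                    round_half_even(counts.ours / counts.total)
                    if counts.total
                    else None
                ),
                "chebi_abs": counts.chebi,
                "chebi_rel": (
                    round_half_even(counts.chebi / counts.total)
                    if counts.total
                    else None
                ),
                "neither": counts.neither,
                "kappa": kappa,
            }
        )
    table = pd.DataFrame(rows)

    # consistency: molecules where a newly assigned class is disjoint with
    # a reference-assigned class
    by_mol_new: dict = {}
    by_mol_ref: dict = {}
    for cls, members in ours.items():
        for m in members:
            if m not in reference.get(cls, set()):
                by_mol_new.setdefault(m, set()).add(cls)
    for cls, members in reference.items():
        for m in members:
            by_mol_ref.setdefault(m, set()).add(cls)
    inconsistent = 0
    for m, new_classes in by_mol_new.items():
        ref_classes = by_mol_ref.get(m, set())
        pairs = check_disjointness(new_classes | ref_classes)
        if any(
            (a in new_classes and b in ref_classes)
            or (b in new_classes and a in ref_classes)
            for a, b in pairs
        ):
            inconsistent += 1
    return table, inconsistent
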