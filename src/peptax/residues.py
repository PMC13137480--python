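"""Building blocks, amino-acid residues and peptide-chain counting.

The residue decomposition follows the heteroatom-splitting rule: a molecule
is mentally cut at every heteroatom, leaving *carbon sections* (maximal
carbon-connected components).  Each section, together with the heteroatoms
directly attached to it, forms a **building block**.  Two exceptions:

* an amide-bond nitrogen never joins a block through the carbonyl carbon of
  that amide (amide bonds can always be cut cleanly in two), and
* heteroatoms with no carbon neighbour at all form blocks of their own.

A heteroatom attached to several carbon sections is *shared*: it may be
assigned to at most one of them, and the chain search below maximises the
chain length over such assignments.

A building block is an **amino-acid residue** when it contains an
amino-residue nitrogen and the carbon of a carboxy group (acid or
derivative).  A **peptide chain** of length n is a set of n pairwise
disjoint residues connected into a single assembly by n-1 amide bonds, each
bond joining the carbonyl carbon in one residue to the nitrogen in another.
``max_chain_length`` computes the largest such n; ``brute_force_chain_oracle``
re-decides the same predicate by exhaustive enumeration and exists to
cross-check the search on small molecules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

from .functional_groups import (
    AmideBondMatch,
    find_amide_bonds,
    find_amino_residues,
    find_carboxy_residues,
)
from .molgraph import MolGraph, carbon_components

__all__ = [
    "BuildingBlock",
    "ResidueCandidate",
    "PeptideChain",
    "CapacityError",
    "SearchBudgetExceeded",
    "DEFAULT_CARBON_COMPONENT_LIMIT",
    "DEFAULT_SEARCH_BUDGET",
    "find_building_blocks",
    "find_amino_acid_residues",
    "max_chain_length",
    "brute_force_chain_oracle",
]

#: Molecules with more carbon sections than this are rejected as too large.
DEFAULT_CARBON_COMPONENT_LIMIT = 10_000

#: Cap on feasibility-search nodes per molecule in the chain search.
DEFAULT_SEARCH_BUDGET = 1_000_000


class CapacityError(RuntimeError):
    """Molecule exceeds the carbon-component size limit."""

    def __init__(self, n_components: int, limit: int):
        super().__init__(
            f"molecule has {n_components} carbon components, "
            f"exceeding the size limit of {limit}"
        )
        self.n_components = n_components
        self.limit = limit


class SearchBudgetExceeded(RuntimeError):
    """Chain search exceeded its node budget; the molecule is unclassified."""


@dataclass(frozen=True)
class BuildingBlock:
    carbon_core: frozenset
    members: frozenset
    shared_heteroatoms: frozenset

    def __post_init__(self):
        assert self.carbon_core <= self.members


@dataclass(frozen=True)
class ResidueCandidate:
    block: BuildingBlock
    amino_nitrogen: int
    carboxy_carbon: int


@dataclass
class PeptideChain:
    """A witness chain: residues with disjoint member sets plus linking amides."""

    residues: list[ResidueCandidate]
    member_sets: list[frozenset]
    links: list[AmideBondMatch]

    def __len__(self) -> int:
        return len(self.residues)


def find_building_blocks(
    mol: MolGraph,
    max_carbon_components: int = DEFAULT_CARBON_COMPONENT_LIMIT,
) -> list[BuildingBlock]:
    """Decompose a molecule into building blocks (carbon sections + borders)."""
    cores = carbon_components(mol)
    if len(cores) > max_carbon_components:
        raise CapacityError(len(cores), max_carbon_components)
    amide_cn = {
        (m.carbonyl_c, m.nitrogen) for m in find_amide_bonds(mol)
    }
    core_of = {}
    for k, core in enumerate(cores):
        for idx in core:
            core_of[idx] = k

    # eligible cores per heteroatom
    eligible: dict[int, set[int]] = {}
    for a in mol.atoms:
        if mol.is_carbon(a.index):
            continue
        h = a.index
        cores_here: set[int] = set()
        for nb in mol.neighbors(h):
            if not mol.is_carbon(nb):
                continue
            if a.element == "N" and (nb, h) in amide_cn:
                continue  # amide nitrogen, carbonyl side
            cores_here.add(core_of[nb])
        if cores_here:
            eligible[h] = cores_here

    blocks: list[BuildingBlock] = []
    for k, core in enumerate(cores):
        hetero = {h for h, cs in eligible.items() if k in cs}
        shared = {h for h in hetero if len(eligible[h]) > 1}
        blocks.append(
            BuildingBlock(
                carbon_core=core,
                members=frozenset(core | hetero),
                shared_heteroatoms=frozenset(shared),
            )
        )

    # heteroatoms with no carbon neighbour: group bonded runs of them
    orphan = {
        a.index
        for a in mol.atoms
        if not mol.is_carbon(a.index)
        and not any(mol.is_carbon(nb) for nb in mol.neighbors(a.index))
    }
    seen: set[int] = set()
    for h in sorted(orphan):
        if h in seen:
            continue
        stack, comp = [h], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(nb for nb in mol.neighbors(x) if nb in orphan)
        seen |= comp
        blocks.append(
            BuildingBlock(
                carbon_core=frozenset(),
                members=frozenset(comp),
                shared_heteroatoms=frozenset(),
            )
        )
    return blocks


def _block_witnesses(
    mol: MolGraph, block: BuildingBlock, aminos: set[int], carboxy_cs: set[int]
) -> tuple[list[int], list[int]]:
    amino_in = sorted(n for n in block.members if n in aminos)
    carboxy_in = sorted(c for c in block.carbon_core if c in carboxy_cs)
    return amino_in, carboxy_in


def find_amino_acid_residues(
    mol: MolGraph,
    blocks: Optional[list[BuildingBlock]] = None,
) -> list[ResidueCandidate]:
    """One canonical residue candidate per qualifying building block."""
    if blocks is None:
        blocks = find_building_blocks(mol)
    aminos = find_amino_residues(mol)
    carboxy_cs = {m.carbonyl_c for m in find_carboxy_residues(mol)}
    out = []
    for block in blocks:
        amino_in, carboxy_in = _block_witnesses(mol, block, aminos, carboxy_cs)
        if amino_in and carboxy_in:
            out.append(ResidueCandidate(block, amino_in[0], carboxy_in[0]))
    return out


class _ChainProblem:
    """Shared state for the chain search over candidate blocks."""

    def __init__(self, mol: MolGraph, blocks: list[BuildingBlock], budget: int):
        self.mol = mol
        self.budget = budget
        self.nodes = 0
        aminos = find_amino_residues(mol)
        carboxy_cs = {m.carbonyl_c for m in find_carboxy_residues(mol)}
        self.amides = sorted(
            find_amide_bonds(mol),
            key=lambda m: (m.carbonyl_c, m.nitrogen, m.oxygen),
        )

        self.cands: list[BuildingBlock] = []
        self.amino_wit: list[list[int]] = []
        self.carboxy_wit: list[list[int]] = []
        for block in blocks:
            amino_in, carboxy_in = _block_witnesses(mol, block, aminos, carboxy_cs)
            if amino_in and carboxy_in:
                self.cands.append(block)
                self.amino_wit.append(amino_in)
                self.carboxy_wit.append(carboxy_in)

        n = len(self.cands)
        # which candidate blocks may own heteroatom h
        self.hetero_owners: dict[int, list[int]] = {}
        for b, block in enumerate(self.cands):
            for h in block.members - block.carbon_core:
                self.hetero_owners.setdefault(h, []).append(b)

        # potential links: (amide, block holding C, block that may hold N)
        core_block = {}
        for b, block in enumerate(self.cands):
            for idx in block.carbon_core:
                core_block[idx] = b
        self.links: list[tuple[AmideBondMatch, int, int]] = []
        for m in self.amides:
            bc = core_block.get(m.carbonyl_c)
            if bc is None:
                continue
            for bn in self.hetero_owners.get(m.nitrogen, []):
                if bn != bc:
                    self.links.append((m, bc, bn))

    def _tick(self):
        self.nodes += 1
        if self.nodes > self.budget:
            raise SearchBudgetExceeded(
                f"chain search exceeded budget of {self.budget} nodes"
            )

    def feasible(self, subset: tuple[int, ...]) -> Optional[PeptideChain]:
        """Try to realise `subset` as one connected chain; return a witness."""
        sset = set(subset)
        # heteroatoms contested between blocks of the subset
        contested: list[tuple[int, list[int]]] = []
        owner_fixed: dict[int, int] = {}
        for h, owners in self.hetero_owners.items():
            inside = [b for b in owners if b in sset]
            if len(inside) == 1:
                owner_fixed[h] = inside[0]
            elif len(inside) > 1:
                # only nitrogens can serve as amino witnesses or link ends;
                # other shared heteroatoms are assigned arbitrarily (say, to
                # the lowest block) since no constraint depends on them
                if self.mol.element(h) == "N":
                    contested.append((h, inside))
                else:
                    owner_fixed[h] = inside[0]

        for combo in itertools.product(*[owners for _, owners in contested]):
            self._tick()
            owner = dict(owner_fixed)
            for (h, _), b in zip(contested, combo):
                owner[h] = b
            chain = self._check_assignment(subset, owner)
            if chain is not None:
                return chain
        return None

    def _check_assignment(
        self, subset: tuple[int, ...], owner: dict[int, int]
    ) -> Optional[PeptideChain]:
        # every block needs an amino nitrogen it actually owns
        amino_choice = {}
        for b in subset:
            got = next(
                (n for n in self.amino_wit[b] if owner.get(n) == b), None
            )
            if got is None:
                return None
            amino_choice[b] = got
        # valid links under this assignment
        valid = [
            (m, bc, bn)
            for (m, bc, bn) in self.links
            if bc in subset and bn in subset and owner.get(m.nitrogen) == bn
        ]
        # connectivity check
        parent = {b: b for b in subset}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        tree: list[tuple[AmideBondMatch, int, int]] = []
        for m, bc, bn in valid:
            ra, rb = find(bc), find(bn)
            if ra != rb:
                parent[ra] = rb
                tree.append((m, bc, bn))
        roots = {find(b) for b in subset}
        if len(roots) != 1:
            return None

        member_sets = []
        residues = []
        for b in subset:
            assigned = frozenset(
                self.cands[b].carbon_core
                | {
                    h
                    for h in self.cands[b].members - self.cands[b].carbon_core
                    if owner.get(h) == b
                }
            )
            member_sets.append(assigned)
            residues.append(
                ResidueCandidate(
                    self.cands[b], amino_choice[b], self.carboxy_wit[b][0]
                )
            )
        return PeptideChain(
            residues=residues,
            member_sets=member_sets,
            links=[m for m, _, _ in tree],
        )


def max_chain_length(
    mol: MolGraph,
    blocks: Optional[list[BuildingBlock]] = None,
    budget: int = DEFAULT_SEARCH_BUDGET,
    max_carbon_components: int = DEFAULT_CARBON_COMPONENT_LIMIT,
) -> tuple[int, Optional[PeptideChain]]:
    """Largest n such that n disjoint residues form one amide-linked chain.

    Returns ``(n, witness)``; n is 0 (no residue) or 1 (isolated residues
    only) with witness ``None`` when no chain of length >= 2 exists.
    """
    if blocks is None:
        blocks = find_building_blocks(mol, max_carbon_components)
    problem = _ChainProblem(mol, blocks, budget)
    n_cand = len(problem.cands)
    if n_cand == 0:
        return 0, None
    if n_cand == 1 or not problem.links:
        return 1, None

    # adjacency between candidate blocks in the potential-link graph
    adj: dict[int, set[int]] = {b: set() for b in range(n_cand)}
    for _, bc, bn in problem.links:
        adj[bc].add(bn)
        adj[bn].add(bc)

    # enumerate connected subsets, largest first, deterministically
    for r in range(n_cand, 1, -1):
        for combo in itertools.combinations(range(n_cand), r):
            problem._tick()
            sset = set(combo)
            seen = {combo[0]}
            stack = [combo[0]]
            while stack:
                x = stack.pop()
                for y in adj[x]:
                    if y in sset and y not in seen:
                        seen.add(y)
                        stack.append(y)
            if seen != sset:
                continue
            chain = problem.feasible(combo)
            if chain is not None:
                return len(combo), chain
    return 1, None


def brute_force_chain_oracle(mol: MolGraph, n: int) -> bool:
    """Decide "contains a peptide chain of >= n residues" by exhaustion.

    Independent cross-check for :func:`max_chain_length`: it enumerates every
    full assignment of shared heteroatoms, every subset of the resulting
    disjoint residues and every residue ordering, and checks the chain
    condition literally (each residue after the first is linked by an amide
    bond, in either orientation, to some earlier residue).  Exponential by
    design; use only on small molecules.
    """
    if n < 2:
        blocks = find_building_blocks(mol)
        return len(find_amino_acid_residues(mol, blocks)) >= n
    blocks = find_building_blocks(mol)
    aminos = find_amino_residues(mol)
    carboxy_cs = {m.carbonyl_c for m in find_carboxy_residues(mol)}
    amides = list(find_amide_bonds(mol))

    shared = sorted({h for b in blocks for h in b.shared_heteroatoms})
    owners_of = {
        h: [k for k, b in enumerate(blocks) if h in b.members] for h in shared
    }
    for combo in itertools.product(*[owners_of[h] + [None] for h in shared]):
        owner = dict(zip(shared, combo))
        assigned = [
            frozenset(
                x for x in b.members if x not in owner or owner[x] == k
            )
            for k, b in enumerate(blocks)
        ]
        residues = [
            ms
            for ms in assigned
            if ms & aminos and ms & carboxy_cs
        ]
        if len(residues) < n:
            continue
        for perm in itertools.permutations(residues, n):
            ok = True
            for i in range(1, n):
                earlier = set().union(*perm[:i])
                linked = any(
                    (m.carbonyl_c in perm[i] and m.nitrogen in earlier)
                    or (m.nitrogen in perm[i] and m.carbonyl_c in earlier)
                    for m in amides
                )
                if not linked:
                    ok = False
                    break
            if ok:
                return True
    return False
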