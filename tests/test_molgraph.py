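"""Molecular-graph construction and component primitives."""

import random
from collections import Counter

import pytest

from peptax.molgraph import (
    Atom,
    BondRec,
    MolGraph,
    ParseError,
    carbon_components,
    connected_components,
    parse_smiles,
)


class TestParseSmiles:
    def test_met_beta_ala_structure(self, fixture_mol):
        """The worked dipeptide: 14 heavy atoms with the documented H counts."""
        mol = fixture_mol("met-beta-ala")
        assert len(mol) == 14
        elements = Counter(a.element for a in mol.atoms)
        assert elements == {"C": 8, "N": 2, "O": 3, "S": 1}
        by_h = Counter(a.num_hydrogens for a in mol.atoms)
        # 0H: carbonyl C, carboxy C, both carbonyl O, S; 1H: alpha-C,
        # hydroxyl O, amide N; 2H: four CH2 and the amine N; 3H: methyl
        assert by_h == {0: 5, 1: 3, 2: 5, 3: 1}
        assert mol.net_charge == 0

    def test_single_atom_molecule(self):
        mol = parse_smiles("O", "water")
        assert len(mol) == 1
        assert mol.atoms[0].num_hydrogens == 2
        assert not mol.bonds

    def test_formal_charge_bookkeeping(self):
        mol = parse_smiles("[NH4+].[Cl-]")
        assert len(mol) == 2
        assert not mol.bonds
        assert sorted(a.formal_charge for a in mol.atoms) == [-1, 1]
        assert mol.net_charge == 0

    @pytest.mark.parametrize("bad", ["", "   ", "C(", "XYZ((("])
    def test_parse_errors(self, bad):
        with pytest.raises(ParseError):
            parse_smiles(bad)

    @pytest.mark.parametrize(
        "name",
        ["met-beta-ala", "temocapril", "methicillin", "ala-his-zwitterion"],
    )
    def test_reparse_idempotence(self, fixture_mol, name):
        """Canonical-write then reparse preserves atoms, bonds and charge."""
        mol = fixture_mol(name)
        again = parse_smiles(mol.canonical_smiles(), name)
        key = lambda m: (
            Counter((a.element, a.formal_charge, a.num_hydrogens) for a in m.atoms),
            Counter(b.order for b in m.bonds),
            m.net_charge,
        )
        assert key(mol) == key(again)

    def test_kekulized_aromatics(self):
        mol = parse_smiles("c1ccccc1", "benzene")
        orders = sorted(b.order for b in mol.bonds)
        assert orders == [1, 1, 1, 2, 2, 2]
        assert all(b.aromatic for b in mol.bonds)


def _random_molgraph(rng, n_atoms=30):
    """A random undirected graph dressed up as a MolGraph (no chemistry)."""
    elements = [rng.choice("CCCNOS") for _ in range(n_atoms)]
    atoms = [Atom(i, e, 0, 0) for i, e in enumerate(elements)]
    bonds = []
    seen = set()
    for _ in range(rng.randint(0, 2 * n_atoms)):
        i, j = rng.sample(range(n_atoms), 2)
        if frozenset((i, j)) not in seen:
            seen.add(frozenset((i, j)))
            bonds.append(BondRec(i, j, 1))
    return MolGraph(atoms=atoms, bonds=bonds)


def _reachability_oracle(mol):
    """Partition by exhaustive transitive closure over all atom pairs."""
    n = len(mol)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for b in mol.bonds:
        reach[b.i][b.j] = reach[b.j][b.i] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if reach[i][k] and reach[k][j]:
                    reach[i][j] = True
    comps, assigned = [], set()
    for i in range(n):
        if i not in assigned:
            comp = frozenset(j for j in range(n) if reach[i][j])
            comps.append(comp)
            assigned |= comp
    return set(comps)


class TestComponents:
    def test_dot_disconnected(self):
        assert len(connected_components(parse_smiles("[NH4+].[Cl-]"))) == 2

    def test_connected_chain(self, fixture_mol):
        assert len(connected_components(fixture_mol("met-beta-ala"))) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reachability_oracle(self, seed):
        mol = _random_molgraph(random.Random(seed))
        assert set(connected_components(mol)) == _reachability_oracle(mol)

    def test_partition_property(self, fixture_mol):
        mol = fixture_mol("temocapril")
        comps = connected_components(mol)
        union = set().union(*comps)
        assert union == {a.index for a in mol.atoms}
        assert sum(len(c) for c in comps) == len(union)


class TestCarbonComponents:
    def test_temocapril_five_sections(self, fixture_mol):
        assert len(carbon_components(fixture_mol("temocapril"))) == 5

    def test_met_beta_ala_three_sections(self, fixture_mol):
        mol = fixture_mol("met-beta-ala")
        comps = carbon_components(mol)
        assert sorted(len(c) for c in comps) == [1, 4, 3] or sorted(
            len(c) for c in comps
        ) == [1, 3, 4]

    def test_carbon_free_molecule(self):
        assert carbon_components(parse_smiles("[NH4+].[Cl-]")) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_in_connected_components(self, seed):
        mol = _random_molgraph(random.Random(100 + seed))
        comps = connected_components(mol)
        for cc in carbon_components(mol):
            assert sum(1 for comp in comps if cc <= comp) == 1
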