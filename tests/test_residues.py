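"""Building blocks, residue identification and peptide-chain counting."""

import random

import pytest

from peptax.fixtures import GeneratorSpec, generate_peptide, random_spec
from peptax.functional_groups import find_amide_bonds
from peptax.molgraph import parse_smiles
from peptax.residues import (
    CapacityError,
    SearchBudgetExceeded,
    brute_force_chain_oracle,
    find_amino_acid_residues,
    find_building_blocks,
    max_chain_length,
)


class TestBuildingBlocks:
    def test_temocapril_blocks_and_sharing(self, fixture_mol):
        mol = fixture_mol("temocapril")
        blocks = find_building_blocks(mol)
        assert len(blocks) == 5
        # border heteroatoms are shared between neighbouring sections
        assert any(b.shared_heteroatoms for b in blocks)
        # the ring amide nitrogen is excluded from the lactam-carbonyl block
        amide = next(iter(find_amide_bonds(mol)))
        carbonyl_block = next(
            b for b in blocks if amide.carbonyl_c in b.carbon_core
        )
        assert amide.nitrogen not in carbonyl_block.members

    def test_met_beta_ala_amide_split(self, fixture_mol):
        mol = fixture_mol("met-beta-ala")
        blocks = find_building_blocks(mol)
        assert len(blocks) == 3
        amide = next(iter(find_amide_bonds(mol)))
        holders = [b for b in blocks if amide.nitrogen in b.members]
        # the amide N belongs only to the beta-alanine-side block
        assert len(holders) == 1
        assert amide.carbonyl_c not in holders[0].carbon_core

    def test_carbon_free_molecule_single_block(self):
        blocks = find_building_blocks(parse_smiles("O=S(=O)(O)O"))
        assert len(blocks) == 1
        assert blocks[0].carbon_core == frozenset()
        assert len(blocks[0].members) == 5

    def test_capacity_limit(self):
        mol = parse_smiles("C.C.C.C")
        with pytest.raises(CapacityError, match="size limit of 3"):
            find_building_blocks(mol, max_carbon_components=3)


class TestAminoAcidResidues:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("met-beta-ala", 2),
            ("methicillin", 2),
            ("glutaurine", 1),  # sulfonate is not a carboxy group
        ],
    )
    def test_residue_counts(self, fixture_mol, name, expected):
        mol = fixture_mol(name)
        assert len(find_amino_acid_residues(mol)) == expected

    def test_sulfonate_analogue_with_carboxy_would_qualify(self):
        # replacing glutaurine's sulfonate by a carboxylate adds the residue
        mol = parse_smiles("N[C@@H](CCC(=O)NCCC(O)=O)C(O)=O")
        assert len(find_amino_acid_residues(mol)) == 2


class TestMaxChainLength:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("met-beta-ala", 2),
            ("temocapril", 2),
            ("methicillin", 2),
            ("aspartame", 2),
            ("boc-gln-ala-arg-amc", 4),
            ("glutaurine", 1),
        ],
    )
    def test_fixture_chain_lengths(self, fixture_mol, name, expected):
        n, chain = max_chain_length(fixture_mol(name))
        assert n == expected
        if expected >= 2:
            assert chain is not None and len(chain) == expected

    def test_disconnected_chains_do_not_merge(self):
        smiles = "CC(N)C(=O)NC(C)C(O)=O.CC(N)C(=O)NC(C)C(O)=O"
        n, _ = max_chain_length(parse_smiles(smiles))
        assert n == 2

    def test_witness_is_disjoint_and_linked(self, fixture_mol):
        _, chain = max_chain_length(fixture_mol("boc-gln-ala-arg-amc"))
        seen = set()
        for members in chain.member_sets:
            assert not (members & seen)
            seen |= members
        assert len(chain.links) == len(chain.residues) - 1

    def test_budget_exhaustion_raises(self, fixture_mol):
        with pytest.raises(SearchBudgetExceeded):
            max_chain_length(fixture_mol("boc-gln-ala-arg-amc"), budget=1)


class TestChainOracle:
    def test_dipeptide_bounds(self, fixture_mol):
        mol = fixture_mol("met-beta-ala")
        assert brute_force_chain_oracle(mol, 2)
        assert not brute_force_chain_oracle(mol, 3)

    def test_single_amino_acid_is_no_chain(self):
        assert not brute_force_chain_oracle(parse_smiles("CC(N)C(O)=O"), 2)

    def test_agreement_with_search_on_generated_molecules(self):
        """Search and exhaustive oracle agree, both directions, 200 cases."""
        rng = random.Random(2024)
        pool = (
            "glycine",
            "alanine",
            "serine",
            "aspartic acid",
            "lysine",
            "beta-alanine",
            "proline",
        )
        for k in range(200):
            spec = random_spec(rng, n_range=(1, 4), pool=pool)
            smiles, _ = generate_peptide(spec)
            mol = parse_smiles(smiles, f"oracle{k}")
            assert len(mol) <= 40
            n, _ = max_chain_length(mol)
            oracle_n = 0
            for m in range(1, spec.n_residues + 2):
                if brute_force_chain_oracle(mol, m):
                    oracle_n = m
            assert n == oracle_n, smiles
            # monotonicity of the chain predicate
            for m in range(2, n + 1):
                assert brute_force_chain_oracle(mol, m)

    def test_generator_round_trip(self):
        """k eupeptide-linked monomers give a chain of exactly k."""
        rng = random.Random(5)
        for _ in range(25):
            spec = random_spec(rng, n_range=(1, 9), allow_charge_mods=False)
            smiles, expected = generate_peptide(spec)
            n, _ = max_chain_length(parse_smiles(smiles))
            assert n == expected["chain_length"]
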