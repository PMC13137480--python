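"""Registry structure, the classification pipeline and disjointness."""

import random

import pytest

from peptax.fixtures import CURATED, generate_peptide, random_spec
from peptax.molgraph import parse_smiles
from peptax.taxonomy import (
    build_taxonomy,
    check_disjointness,
    classify_molecule,
)


class TestRegistry:
    def test_class_and_crossreference_counts(self, taxonomy):
        assert len(taxonomy) == 67
        with_id = [c for c in taxonomy if c.chebi_id]
        assert len(with_id) == 14
        assert len(taxonomy) - len(with_id) == 53

    def test_dipeptide_ancestry(self, taxonomy):
        assert set(taxonomy["dipeptide"].parents) == {
            "oligopeptide",
            "dipeptide structure",
        }
        assert {"oligopeptide", "dipeptide structure", "peptide"} <= (
            taxonomy.ancestors("dipeptide")
        )

    def test_parent_links_are_acyclic(self, taxonomy):
        for cls in taxonomy:
            assert cls.name not in taxonomy.ancestors(cls.name)

    def test_size_bounds_are_consistent(self, taxonomy):
        for cls in taxonomy:
            if cls.size_lower is not None and cls.size_upper is not None:
                assert cls.size_lower <= cls.size_upper

    def test_tsv_export_covers_registry(self, taxonomy):
        rows = taxonomy.to_table()
        assert len(rows) == 67
        assert sum(1 for _, _, chebi in rows if chebi) == 14

    def test_obo_export_has_one_stanza_per_class(self, taxonomy):
        obo = taxonomy.to_obo()
        assert obo.count("[Term]") == 67
        assert obo.count("xref: CHEBI:") == 14


class TestClassifyMolecule:
    def test_beta_alanyl_arginium_exact_class_set(self, fixture_mol, taxonomy):
        result = classify_molecule(fixture_mol("beta-alanyl-L-arginium"), taxonomy)
        assert result.classes == {
            "peptide structure",
            "peptide cation",
            "oligopeptide structure",
            "dipeptide structure",
            "oligopeptide cation",
            "dipeptide cation",
            "arginine peptide structure",
        }

    def test_met_beta_ala_exact_class_set(self, fixture_mol, taxonomy):
        result = classify_molecule(fixture_mol("met-beta-ala"), taxonomy)
        assert result.classes == {
            "peptide structure",
            "oligopeptide structure",
            "dipeptide structure",
            "peptide",
            "oligopeptide",
            "dipeptide",
            "methionine peptide structure",
        }

    @pytest.mark.parametrize("smiles", ["CCO", "CC(N)C(O)=O", "c1ccccc1"])
    def test_non_peptides_get_no_classes(self, smiles, taxonomy):
        result = classify_molecule(parse_smiles(smiles), taxonomy)
        assert result.classes == set()

    def test_zwitterion_fixture_classes(self, fixture_mol, taxonomy):
        result = classify_molecule(fixture_mol("ala-his-zwitterion"), taxonomy)
        assert "dipeptide zwitterion" in result.classes
        assert "peptide zwitterion" in result.classes

    def test_salt_size_classes_use_component_chains(self, taxonomy):
        mol = parse_smiles("CC(N)C(=O)NC(C)C(=O)[O-].[Na+]", "ala-ala-salt")
        result = classify_molecule(mol, taxonomy)
        assert "peptide salt" in result.classes
        assert "dipeptide salt" in result.classes

    def test_all_curated_fixtures_classify_cleanly(self, taxonomy):
        for name, (smiles, _) in CURATED.items():
            result = classify_molecule(parse_smiles(smiles, name), taxonomy)
            assert result.status == "ok"
            assert check_disjointness(result) == []


@pytest.fixture(scope="module")
def generated(taxonomy):
    rng = random.Random(99)
    out = []
    for k in range(60):
        spec = random_spec(rng, n_range=(1, 12))
        smiles, expected = generate_peptide(spec)
        mol = parse_smiles(smiles, f"gen{k}")
        out.append((classify_molecule(mol, taxonomy), expected))
    return out


class TestPipelineInvariants:
    def test_closure_under_parents(self, taxonomy, generated):
        for result, _ in generated:
            assert result.classes == taxonomy.closure(result.classes)

    def test_charge_partition(self, generated):
        charge_classes = {
            "peptide",
            "peptide anion",
            "peptide cation",
            "peptide zwitterion",
            "peptide salt",
        }
        for result, _ in generated:
            if result.chain_length >= 2:
                assert len(result.classes & charge_classes) == 1

    def test_peptide_structures_get_at_least_four_classes(self, generated):
        for result, _ in generated:
            if "peptide structure" in result.classes:
                assert len(result.classes) >= 4

    def test_size_classes_bracket_chain_length(self, taxonomy, generated):
        for result, _ in generated:
            n = result.chain_length
            for name in result.classes:
                cls = taxonomy[name]
                if cls.size_lower is not None:
                    assert n >= cls.size_lower
                if cls.size_upper is not None:
                    assert n <= cls.size_upper

    def test_no_disjointness_violations(self, generated):
        for result, _ in generated:
            assert check_disjointness(result) == []


class TestDisjointnessDetector:
    def test_size_conflict_detected(self):
        assert len(check_disjointness({"dipeptide", "tripeptide"})) == 1

    def test_charge_conflict_detected(self):
        assert len(check_disjointness({"peptide", "peptide anion"})) == 1

    def test_oligo_poly_conflict_detected(self):
        assert (
            len(check_disjointness({"oligopeptide structure", "polypeptide structure"}))
            == 1
        )

    def test_clean_set_passes(self):
        assert check_disjointness({"peptide", "dipeptide", "oligopeptide"}) == []
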