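"""Parsing, role assignment, neutralization, filtering, deduplication."""

import numpy as np
import pytest
from rdkit import Chem

from rxnnet import synthetic as syn
from rxnnet.etl import (
    CleanReaction,
    RejectionReport,
    apply_filters,
    assign_roles,
    canonical_smiles,
    neutralize,
    parse_reaction_line,
    run_etl,
)


def _record(line: str):
    parsed = parse_reaction_line(line)
    assert not isinstance(parsed, RejectionReport), parsed
    return parsed


class TestParse:
    def test_well_formed_line(self):
        rec = _record("[CH3:1]I.[NH2:2][CH3:3]>O>[CH3:1][NH:2][CH3:3]")
        assert len(rec.components_left) == 2
        assert len(rec.components_agent) == 1
        assert len(rec.components_right) == 1

    def test_malformed_smiles_is_parse_error(self):
        out = parse_reaction_line("abc>>")
        assert isinstance(out, RejectionReport)
        assert out.reason == "parse_error"

    def test_empty_agent_slot(self):
        rec = _record("[CH4:1].[CH4:2]>>[CH3:1][CH3:2]")
        assert rec.components_agent == []

    def test_multi_arrow_is_not_single_step(self):
        out = parse_reaction_line("[CH4:1]>>[CH3:1]C>>[CH3:1]CC")
        assert isinstance(out, RejectionReport)
        assert out.reason == "not_single_step"

    def test_metadata_columns(self):
        rec = _record("[CH4:1].[CH4:2]>>[CH3:1][CH3:2]\tRX1\t42.5")
        assert rec.record_id == "RX1"
        assert rec.yield_percent == 42.5


class TestRoles:
    """Every role outcome for a 3-component record, vs a hand truth table."""

    LINE = "[CH3:1]Cl.CCCCCC>[OH:9]C>[CH3:1][O:9]C"
    # product maps: {1, 9}
    # left[0] shares map 1 -> reactant; left[1] unmapped -> reagent
    # agent[0] shares map 9 -> reactant (moved left)

    def test_truth_table(self):
        rec = assign_roles(_record(self.LINE))
        left = {Chem.MolToSmiles(m) for m in rec.components_left}
        agents = {Chem.MolToSmiles(m) for m in rec.components_agent}
        assert Chem.MolToSmiles(Chem.MolFromSmiles("[CH3:1]Cl")) in left
        assert Chem.MolToSmiles(Chem.MolFromSmiles("[OH:9]C")) in left  # promoted
        assert agents == {"CCCCCC"}  # demoted: no shared map

    def test_unmapped_solvent_stays_reagent(self):
        rec = assign_roles(_record("[CH4:1]>CCO>[CH3:1]C"))
        assert [Chem.MolToSmiles(m) for m in rec.components_agent] == ["CCO"]

    def test_exhaustive_left_slot_outcomes(self):
        # left components with and without map overlap with the product
        rec = assign_roles(_record("[CH4:1].[CH4:7]>>[CH3:1]C"))
        assert len(rec.components_left) == 1  # only map 1 overlaps
        assert len(rec.components_agent) == 1


class TestNeutralize:
    def test_carboxylate_protonated(self):
        mol = neutralize(Chem.MolFromSmiles("CC(=O)[O-]"))
        assert Chem.MolToSmiles(mol) == Chem.MolToSmiles(Chem.MolFromSmiles("CC(=O)O"))

    def test_quaternary_nitrogen_retained(self):
        mol = neutralize(Chem.MolFromSmiles("C[N+](C)(C)C"))
        assert Chem.MolToSmiles(mol) == Chem.MolToSmiles(Chem.MolFromSmiles("C[N+](C)(C)C"))

    def test_idempotent_on_generated_charged_molecules(self):
        cfg = syn.GeneratorConfig(n_reactions=200, seed=77, dirt_rates={"charged_atom": 1.0})
        n_charged = 0
        for line in syn.generate_dataset(cfg):
            rec = parse_reaction_line(line)
            for mol in rec.components_left:
                if any(a.GetFormalCharge() for a in mol.GetAtoms()):
                    n_charged += 1
                    once = neutralize(mol)
                    twice = neutralize(once)
                    assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice)
                    assert all(a.GetFormalCharge() == 0 for a in once.GetAtoms())
        assert n_charged >= 150  # the dirt actually produced charged species


class TestFilters:
    def test_multi_product(self):
        rec = assign_roles(_record("[CH4:1]>>[CH3:1]C.O"))
        out = apply_filters(rec)
        assert isinstance(out, RejectionReport) and out.reason == "multi_product"

    def test_no_reactant(self):
        rec = assign_roles(_record("CC.CCC>>CCCC"))  # nothing mapped
        out = apply_filters(rec)
        assert isinstance(out, RejectionReport) and out.reason == "no_reactant"

    def test_product_equals_reactant_after_neutralization(self):
        # charged reactant, neutral identical product: must still collapse and reject
        rec = assign_roles(_record("[CH3:1]C(=O)[O-]>>[CH3:1]C(=O)O"))
        out = apply_filters(rec)
        assert isinstance(out, RejectionReport) and out.reason == "product_equals_reactant"

    def test_dummy_atom(self):
        rec = assign_roles(_record("[CH4:1]>>[CH3:1][*]"))
        out = apply_filters(rec)
        assert isinstance(out, RejectionReport) and out.reason == "dummy_atom"

    def test_yield_threshold(self):
        rec = assign_roles(_record("[CH4:1].[CH4:2]>>[CH3:1][CH3:2]\tR1\t3.0"))
        out = apply_filters(rec, yield_threshold=5.0)
        assert isinstance(out, RejectionReport) and out.reason == "yield_below_threshold"
        ok = apply_filters(rec, yield_threshold=2.0)
        assert isinstance(ok, CleanReaction)

    def test_accepted_reaction_key_shape(self):
        out = apply_filters(assign_roles(_record("[CH4:2].[CH4:1]>O>[CH3:1][CH3:2]")))
        assert isinstance(out, CleanReaction)
        assert out.reaction_key == "C.C>>CC"


class TestReactionKey:
    def test_key_ignores_reagents_and_reactant_order(self):
        a = apply_filters(assign_roles(_record("[CH4:1].[CH3:2]O>O>[CH3:1][CH2:2]O")))
        b = apply_filters(assign_roles(_record("[CH3:2]O.[CH4:1]>CCO.ClCCl>[CH3:1][CH2:2]O")))
        assert isinstance(a, CleanReaction) and isinstance(b, CleanReaction)
        assert a.reaction_key == b.reaction_key
        assert a.reagents != b.reagents


class TestRunEtl:
    def test_conservation_and_determinism(self):
        cfg = syn.GeneratorConfig(
            n_reactions=300,
            seed=5,
            dirt_rates={"multi_product": 0.1, "dummy_atom": 0.1, "no_reactant": 0.05, "charged_atom": 0.2},
        )
        lines = syn.generate_dataset(cfg)
        r1 = run_etl(lines)
        r2 = run_etl(lines)
        assert r1.n_accepted_records + len(r1.rejections) == r1.n_input == 300
        assert [x.reaction_key for x in r1.accepted] == [x.reaction_key for x in r2.accepted]
        assert [(x.record_id, x.reason) for x in r1.rejections] == [
            (x.record_id, x.reason) for x in r2.rejections
        ]

    def test_molecule_table_excludes_reagents(self, clean_etl):
        reagent_set = {smi for rxn in clean_etl.accepted for smi in rxn.reagents}
        participant_set = {smi for rxn in clean_etl.accepted for smi in (*rxn.reactants, rxn.product)}
        for smi in clean_etl.molecules:
            assert smi in participant_set
        # reagent-only species never enter the molecule table
        for smi in reagent_set - participant_set:
            assert smi not in clean_etl.molecules


class TestCanonicalIdentity:
    def test_maps_dropped_stereo_kept(self):
        mapped = Chem.MolFromSmiles("[CH3:5][C@H:2]([NH2:3])[CH3:4]")
        smi = canonical_smiles(mapped)
        assert ":" not in smi
        assert "@" in smi
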