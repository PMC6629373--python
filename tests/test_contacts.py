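"""Contact enumeration: threshold semantics, oracle equivalence, invariances."""

import numpy as np
import pytest

from gprotiface.contacts import ca_distance, residue_contacts, segment_contact_summary
from gprotiface.model import Atom, Chain, ChainRoleAssignment, Residue, ResidueRef, Structure
from gprotiface.synth import (
    HelixSpec,
    PlantedComplexSpec,
    PlantedContact,
    brute_force_contacts,
    galpha_template_map,
    make_planted_complex,
    receptor_template_map,
)

from conftest import CLOUD_ROLES, PAIR_ROLES, random_cloud_structure, random_rotation, two_chain_structure


class TestThresholdSemantics:
    def test_just_inside_counts(self):
        s = two_chain_structure((0, 0, 0), (3.99, 0, 0))
        cm = residue_contacts(s, PAIR_ROLES, threshold=4.0)
        assert len(cm) == 1
        assert cm.contacts[0].min_dist == pytest.approx(3.99)

    def test_exactly_at_threshold_excluded(self):
        s = two_chain_structure((0, 0, 0), (4.0, 0, 0))
        cm = residue_contacts(s, PAIR_ROLES, threshold=4.0)
        assert len(cm) == 0

    def test_nonpositive_threshold_rejected(self):
        s = two_chain_structure((0, 0, 0), (1, 0, 0))
        with pytest.raises(ValueError):
            residue_contacts(s, PAIR_ROLES, threshold=0.0)

    def test_hydrogens_excluded(self):
        s = two_chain_structure((0, 0, 0), (10, 0, 0))
        # hydrogen 2 A from chain A would be a contact if counted
        s.chain("B").residues[0].atoms.append(Atom("H1", "H", (2.0, 0, 0)))
        cm = residue_contacts(s, PAIR_ROLES, threshold=4.0)
        assert len(cm) == 0

    def test_unassigned_role_errors(self):
        s = two_chain_structure((0, 0, 0), (1, 0, 0))
        roles = ChainRoleAssignment("pair", {"A": "receptor"})
        with pytest.raises(ValueError, match="Galpha"):
            residue_contacts(s, roles)


class TestOracleEquivalence:
    def test_planted_complex_matches_truth_and_brute_force(self):
        spec = PlantedComplexSpec(
            "planted",
            chains=[(HelixSpec(20, "R"), "receptor"), (HelixSpec(15, "G"), "Galpha")],
            planted_contacts=[
                PlantedContact(ResidueRef("R", 4), ResidueRef("G", 2), 3.2),
                PlantedContact(ResidueRef("R", 11), ResidueRef("G", 9), 3.9),
                PlantedContact(ResidueRef("R", 17), ResidueRef("G", 14), 4.4),
            ],
        )
        s, truth = make_planted_complex(spec)
        cm = residue_contacts(s, spec.roles(), threshold=4.0)
        assert cm.pair_keys() == truth.pair_keys()
        bf = brute_force_contacts(s, "R", "G", threshold=4.0)
        assert {(a, b) for a, b in bf} == cm.pair_keys()
        for c in cm.contacts:
            key = ((c.res_a.chain_id, c.res_a.seq_id, c.res_a.icode),
                   (c.res_b.chain_id, c.res_b.seq_id, c.res_b.icode))
            assert c.min_dist == pytest.approx(bf[key][0], abs=1e-9)

    def test_random_structures_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            s = random_cloud_structure(rng)
            cm = residue_contacts(s, CLOUD_ROLES, threshold=4.0, prepared=True)
            bf = brute_force_contacts(s, "A", "B", threshold=4.0)
            assert {(a, b) for a, b in bf} == cm.pair_keys()
            for c in cm.contacts:
                key = ((c.res_a.chain_id, c.res_a.seq_id, c.res_a.icode),
                       (c.res_b.chain_id, c.res_b.seq_id, c.res_b.icode))
                d, atom_a, atom_b = bf[key]
                assert c.min_dist == pytest.approx(d, abs=1e-9)
                assert c.atom_pair == (atom_a, atom_b)


class TestContactMapProperties:
    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = random_cloud_structure(rng)
            small = residue_contacts(s, CLOUD_ROLES, threshold=3.0, prepared=True)
            large = residue_contacts(s, CLOUD_ROLES, threshold=5.0, prepared=True)
            assert small.pair_keys() <= large.pair_keys()

    def test_role_swap_transposes(self):
        rng = np.random.default_rng(9)
        s = random_cloud_structure(rng)
        fwd = residue_contacts(s, CLOUD_ROLES, pair=("receptor", "Galpha"), prepared=True)
        rev = residue_contacts(s, CLOUD_ROLES, pair=("Galpha", "receptor"), prepared=True)
        assert rev.pair_keys() == {(b, a) for a, b in fwd.pair_keys()}
        fwd_d = {k: None for k in fwd.pair_keys()}
        for c_f, c_r in zip(sorted(fwd.contacts, key=lambda c: c.min_dist),
                            sorted(rev.contacts, key=lambda c: c.min_dist)):
            assert c_f.min_dist == pytest.approx(c_r.min_dist, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(33)
        s = random_cloud_structure(rng)
        base = residue_contacts(s, CLOUD_ROLES, prepared=True)
        R = random_rotation(rng)
        moved = s.transformed(R, rng.uniform(-50, 50, 3))
        after = residue_contacts(moved, CLOUD_ROLES, prepared=True)
        assert after.pair_keys() == base.pair_keys()
        base_d = {k: c.min_dist for k, c in zip(sorted(base.pair_keys()),
                                                sorted(base.contacts, key=lambda c: (
                                                    c.res_a.chain_id, c.res_a.seq_id,
                                                    c.res_a.icode, c.res_b.chain_id,
                                                    c.res_b.seq_id)))}
        after_d = {((c.res_a.chain_id, c.res_a.seq_id, c.res_a.icode),
                    (c.res_b.chain_id, c.res_b.seq_id, c.res_b.icode)): c.min_dist
                   for c in after.contacts}
        for c in base.contacts:
            key = ((c.res_a.chain_id, c.res_a.seq_id, c.res_a.icode),
                   (c.res_b.chain_id, c.res_b.seq_id, c.res_b.icode))
            assert after_d[key] == pytest.approx(c.min_dist, abs=1e-9)

    def test_output_sorted_by_first_role(self):
        spec = PlantedComplexSpec(
            "sorted",
            chains=[(HelixSpec(20, "R"), "receptor"), (HelixSpec(15, "G"), "Galpha")],
            planted_contacts=[
                PlantedContact(ResidueRef("R", 15), ResidueRef("G", 3), 3.0),
                PlantedContact(ResidueRef("R", 2), ResidueRef("G", 10), 3.0),
            ],
        )
        s, _ = make_planted_complex(spec)
        cm = residue_contacts(s, spec.roles())
        seqs = [c.res_a.seq_id for c in cm.contacts]
        assert seqs == sorted(seqs)


class TestCaDistance:
    def test_residue_against_itself_is_zero(self):
        s = two_chain_structure((1, 2, 3), (9, 9, 9))
        ref = ResidueRef("A", 1)
        assert ca_distance(s, ref, ref) == 0.0

    def test_constructed_five_angstrom_pair(self):
        s = two_chain_structure((0, 0, 0), (3, 4, 0))
        assert ca_distance(s, ResidueRef("A", 1), ResidueRef("B", 1)) == pytest.approx(5.0)
        assert round(ca_distance(s, ResidueRef("A", 1), ResidueRef("B", 1)), 2) == 5.00

    def test_missing_residue_or_ca_errors(self):
        s = two_chain_structure((0, 0, 0), (1, 0, 0))
        with pytest.raises(KeyError):
            ca_distance(s, ResidueRef("A", 99), ResidueRef("B", 1))
        s.chain("B").residues[0].atoms[0].name = "CB"
        with pytest.raises(KeyError):
            ca_distance(s, ResidueRef("A", 1), ResidueRef("B", 1))


class TestSegmentSummary:
    def test_empty_map_empty_table(self):
        s = two_chain_structure((0, 0, 0), (20, 0, 0))
        cm = residue_contacts(s, PAIR_ROLES)
        assert segment_contact_summary(cm).empty

    def test_counts_and_ranking(self):
        spec = PlantedComplexSpec(
            "seg",
            chains=[(HelixSpec(60, "R"), "receptor"),
                    (HelixSpec(26, "G", start_seq_id=329), "Galpha")],
            planted_contacts=[
                # three TM5 residues (template 15-26) and one TM6 (27-38)
                PlantedContact(ResidueRef("R", 16), ResidueRef("G", 340), 3.0),
                PlantedContact(ResidueRef("R", 19), ResidueRef("G", 344), 3.0),
                PlantedContact(ResidueRef("R", 22), ResidueRef("G", 348), 3.0),
                PlantedContact(ResidueRef("R", 30), ResidueRef("G", 352), 3.0),
            ],
            numbering=[receptor_template_map("seg"), galpha_template_map("seg")],
        )
        s, _ = make_planted_complex(spec)
        cm = residue_contacts(s, spec.roles())
        table = segment_contact_summary(cm)
        assert table.iloc[0]["segment_a"] == "TM5" and table.iloc[0]["n_pairs"] == 3
        counts = dict(zip(table["segment_a"], table["n_pairs"]))
        assert counts == {"TM5": 3, "TM6": 1}

    def test_unannotated_grouped_as_unassigned(self):
        s = two_chain_structure((0, 0, 0), (3.5, 0, 0))
        cm = residue_contacts(s, PAIR_ROLES)
        table = segment_contact_summary(cm)
        assert list(table["segment_a"]) == ["unassigned"]
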