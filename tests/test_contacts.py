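import numpy as np
import pytest

from synfold import ValidationError, synthetic
from synfold.contacts import (ContactSet, SaltBridgePair,
                              contact_fraction_series,
                              identify_native_contacts, read_contacts,
                              salt_bridge_probability, salt_bridge_series,
                              write_contacts)
from synfold.structure import Trajectory
from synfold.synthetic import PlannedPair

from conftest import random_rotation


def brute_force_contacts(structure, cutoff, min_separation=5):
    """O(n^2) oracle: residue pairs by minimal heavy-atom distance."""
    groups = [(c, r, idx) for c, r, _, idx in structure.residue_table()]
    heavy = structure.heavy_mask()
    out = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ca, ra, ia = groups[i]
            cb, rb, ib = groups[j]
            ia, ib = ia[heavy[ia]], ib[heavy[ib]]
            d = np.min(np.linalg.norm(
                structure.coords[ia][:, None] - structure.coords[ib][None],
                axis=2))
            if d <= cutoff and (ca != cb or abs(ra - rb) >= min_separation):
                out.add((ca, ra, cb, rb))
    return out


class TestIdentify:
    def test_matches_brute_force_oracle(self, toy_complex):
        cs = identify_native_contacts(toy_complex.structure, cutoff=4.2)
        mine = {(c.chain_a, c.res_a, c.chain_b, c.res_b) for c in cs.pairs}
        assert mine == brute_force_contacts(toy_complex.structure, 4.2)
        assert cs.counts() == {"inter": 5}

    def test_tiny_cutoff_yields_empty_set(self, toy_complex):
        cs = identify_native_contacts(toy_complex.structure, cutoff=0.1)
        assert cs.pairs == []

    def test_independent_of_chain_order(self, toy_complex):
        s = toy_complex.structure
        # reverse the atom table: chain B first
        order = np.argsort(s.chain_ids.astype(str) == "A", kind="stable")
        flipped = type(s)(
            atom_names=s.atom_names[order], elements=s.elements[order],
            res_ids=s.res_ids[order], res_names=s.res_names[order],
            chain_ids=s.chain_ids[order], coords=s.coords[order])
        a = identify_native_contacts(s, cutoff=4.2)
        b = identify_native_contacts(flipped, cutoff=4.2)
        key = lambda c: (c.chain_a, c.res_a, c.chain_b, c.res_b, c.kind)
        assert sorted(map(key, a.pairs)) == sorted(map(key, b.pairs))

    def test_min_separation_filters_intramolecular(self):
        # helix: residues i, i+4 are close but not "tertiary"
        helix = synthetic.build_helix(synthetic.HelixBuildSpec(12))
        cs = identify_native_contacts(helix, cutoff=6.0, min_separation=5)
        assert all(abs(c.res_a - c.res_b) >= 5 for c in cs.pairs)

    def test_invalid_cutoff_nesting_rejected(self):
        with pytest.raises(ValidationError, match="formation"):
            ContactSet(pairs=[], identification_cutoff=5.0,
                       formation_cutoff=4.5, min_separation=5,
                       atom_mode="all-heavy")

    def test_round_trip_through_table(self, toy_complex, tmp_path):
        cs = identify_native_contacts(toy_complex.structure, cutoff=4.2)
        path = tmp_path / "contacts.tsv"
        write_contacts(cs, path)
        back = read_contacts(path)
        assert back.pairs == cs.pairs
        assert back.identification_cutoff == cs.identification_cutoff
        assert back.atom_mode == cs.atom_mode


class TestContactFractions:
    def test_reference_frame_has_q_one(self, toy_complex):
        cs = identify_native_contacts(toy_complex.structure, cutoff=4.2)
        run = Trajectory(coords=toy_complex.structure.coords[None], dt=10.0)
        q = contact_fraction_series(run, toy_complex.structure, cs, "inter")
        assert q.fractions[0] == 1.0

    def test_separated_chains_have_q_zero(self, toy_complex):
        s = toy_complex.structure
        cs = identify_native_contacts(s, cutoff=4.2)
        coords = s.coords.copy()
        coords[s.chain_ids == "B"] += np.array([0.0, 100.0, 0.0])
        run = Trajectory(coords=coords[None], dt=10.0)
        q = contact_fraction_series(run, s, cs, "inter")
        assert q.fractions[0] == 0.0

    def test_scripted_formation_counts(self):
        plan = [PlannedPair(i, i, 4.0) for i in range(1, 6)]
        frame_plan = [set(range(5)), {0, 1}, set(), {2}, {0, 2, 4}]
        toy = synthetic.build_toy_complex(6, 6, plan, frame_plan)
        cs = identify_native_contacts(toy.structure, cutoff=4.2)
        q = contact_fraction_series(toy.trajectory, toy.structure, cs,
                                    "inter")
        expected = [len(f) / 5 for f in toy.formed_per_frame]
        np.testing.assert_allclose(q.fractions, expected)

    def test_invariant_under_rigid_motion(self, toy_complex, rng):
        s = toy_complex.structure
        cs = identify_native_contacts(s, cutoff=4.2)
        rot = random_rotation(rng)
        moved = s.coords @ rot.T + np.array([12.0, -7.0, 3.0])
        run = Trajectory(coords=np.stack([s.coords, moved]), dt=10.0)
        q = contact_fraction_series(run, s, cs, "inter")
        assert q.fractions[0] == q.fractions[1] == 1.0

    def test_empty_class_is_an_error(self, toy_complex):
        cs = identify_native_contacts(toy_complex.structure, cutoff=4.2)
        run = Trajectory(coords=toy_complex.structure.coords[None], dt=10.0)
        with pytest.raises(ValidationError, match="intra:A"):
            contact_fraction_series(run, toy_complex.structure, cs,
                                    "intra:A")


class TestSaltBridges:
    @pytest.mark.parametrize("basic,acid,dist,formed", [
        ("ARG", "ASP", 4.9, True),  # Arg criterion: CZ-carboxylate C <= 5
        ("ARG", "ASP", 5.1, False),
        ("LYS", "GLU", 3.9, True),  # Lys criterion: NZ-carboxylate C <= 4
        ("LYS", "GLU", 4.1, False),
        ("ARG", "GLU", 4.99, True),
    ])
    def test_threshold_application(self, basic, acid, dist, formed):
        plan = [PlannedPair(1, 1, dist, basic, acid)]
        toy = synthetic.build_toy_complex(2, 2, plan, [{0}])
        series = salt_bridge_series(toy.trajectory, toy.structure,
                                    [SaltBridgePair("A", 1, "B", 1)])
        assert series["A1-B1"][0] == formed

    def test_non_charged_residue_rejected(self, toy_complex):
        run = Trajectory(coords=toy_complex.structure.coords[None], dt=10.0)
        with pytest.raises(ValidationError, match="not Arg or Lys"):
            salt_bridge_series(run, toy_complex.structure,
                               [SaltBridgePair("A", 1, "B", 1)])

    def test_ensemble_probability_matches_script(self):
        plan = [PlannedPair(1, 1, 4.9, "ARG", "ASP")]
        run_plans = [[{0}, {0}, set()], [{0}, set(), set()],
                     [{0}, {0}, {0}]]
        structure, ensemble = synthetic.toy_ensemble(run_plans, 2, 2, plan)
        prob = salt_bridge_probability(ensemble, structure,
                                       [SaltBridgePair("A", 1, "B", 1)])
        np.testing.assert_allclose(prob["A1-B1"], [1.0, 2 / 3, 1 / 3])
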