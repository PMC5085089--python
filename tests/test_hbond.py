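"""Hydrogen-bond criterion, contact matrices, D and classification."""

import math

import numpy as np
import pytest

from hbprop import (BackboneStructure, BondKey, DeltaMatrix, DistanceSeries,
                    HBCriterion, PropensityMatrix, ResidueRef,
                    StaticContactMatrix, TrajectoryFrames,
                    classify_chameleonic, delta_matrix, dynamic_propensity,
                    enumerate_candidate_bonds, hb_geometry, is_formed,
                    make_ideal_helix, propensity_from_distance_series,
                    realize_bond_frames, static_contact_matrix,
                    windowed_propensity)
from hbprop.synthetic import SyntheticBondSpec, telegraph_states

from conftest import make_residue


class TestGeometry:
    def test_collinear_gives_straight_angle(self):
        r, theta = hb_geometry((0, 0, 0), (1, 0, 0), (3, 0, 0))
        assert r == pytest.approx(3.0)
        assert theta == pytest.approx(180.0)

    def test_right_angle(self):
        r, theta = hb_geometry((0, 0, 0), (1, 0, 0), (1, 2, 0))
        assert r == pytest.approx(math.sqrt(5))
        assert theta == pytest.approx(90.0)

    def test_random_triples_match_independent_oracle(self):
        # oracle: law-of-cosines style arccos written independently
        def oracle(n, h, o):
            r = math.dist(n, o)
            a = math.dist(h, n)
            b = math.dist(h, o)
            cos_t = (a * a + b * b - r * r) / (2 * a * b)
            return r, math.degrees(math.acos(max(-1.0, min(1.0, cos_t))))

        rng = np.random.default_rng(11)
        for _ in range(100):
            n, h, o = rng.normal(size=(3, 3)) * 3
            r, theta = hb_geometry(n, h, o)
            r_ref, theta_ref = oracle(tuple(n), tuple(h), tuple(o))
            assert r == pytest.approx(r_ref, abs=1e-9)
            assert theta == pytest.approx(theta_ref, abs=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            hb_geometry((0, 0, 0), (0, 0, 0), (3, 0, 0))


class TestIsFormed:
    full = HBCriterion()
    dist = HBCriterion(mode="distance_only")

    @pytest.mark.parametrize("r,theta,crit,expected", [
        (3.4, 150.0, full, True),
        (3.5, 170.0, full, False),   # strict distance boundary
        (2.9, 140.0, full, False),   # strict angle boundary
        (3.4, None, dist, True),
        (3.5, None, dist, False),
    ])
    def test_boundaries_are_strict(self, r, theta, crit, expected):
        assert is_formed(r, theta, crit) is expected

    def test_full_mode_requires_theta(self):
        with pytest.raises(ValueError, match="theta"):
            is_formed(3.0, None, self.full)


class TestEnumerateCandidateBonds:
    def test_matches_nested_loop_oracle(self):
        residues = [make_residue(i + 1, origin=(4.0 * i, 0, 0),
                                 donor=(i > 0)) for i in range(10)]
        st = BackboneStructure(residues)
        got = enumerate_candidate_bonds(st, min_separation=2)
        oracle = []
        for d in range(1, 11):
            for a in range(1, 11):
                if d == 1 or d == a or abs(d - a) < 2:
                    continue
                oracle.append((d, a))
        assert [(k.donor.seq_number, k.acceptor.seq_number)
                for k in got] == sorted(oracle)

    def test_two_residues_yield_nothing(self):
        st = BackboneStructure([make_residue(1, donor=False),
                                make_residue(2, origin=(4, 0, 0))])
        assert enumerate_candidate_bonds(st, min_separation=2) == []

    def test_proline_never_donates(self):
        residues = [make_residue(i + 1, origin=(4.0 * i, 0, 0),
                                 donor=(i > 0)) for i in range(8)]
        residues[4].ref = ResidueRef("A", 5, "", "PRO")
        residues[4].donor_capable = False
        got = enumerate_candidate_bonds(BackboneStructure(residues))
        assert all(k.donor.seq_number != 5 for k in got)
        assert any(k.acceptor.seq_number == 5 for k in got)  # still accepts


class TestStaticContactMatrix:
    def test_ideal_helix_gives_exact_i_to_i_minus_4_ladder(self, helix18):
        matrix = static_contact_matrix(helix18)
        formed = {(k.donor.seq_number, k.acceptor.seq_number)
                  for k, v in matrix.entries.items() if v == 1}
        assert formed == {(i, i - 4) for i in range(5, 19)}

    def test_helix_ladder_agrees_with_geometric_oracle(self, helix18):
        # oracle: evaluate the criterion over all pairs directly
        crit = HBCriterion()
        matrix = static_contact_matrix(helix18, crit)
        for key, state in matrix.entries.items():
            don = helix18.residue(key.donor)
            acc = helix18.residue(key.acceptor)
            r, theta = hb_geometry(don.coord("N"), don.coord("H"),
                                   acc.coord("O"))
            expected = int(r < 3.5 and theta > 140.0)
            assert state == expected, key

    def test_extended_chain_is_all_zero(self, extended_chain):
        matrix = static_contact_matrix(extended_chain)
        assert set(matrix.entries.values()) == {0}

    def test_first_residue_never_donates(self, helix18):
        matrix = static_contact_matrix(helix18)
        assert all(k.donor.seq_number != 1 for k in matrix.entries)


class TestDynamicPropensity:
    bond = BondKey.from_seq(5, 1)

    def test_identical_formed_frames_give_one(self):
        spec = SyntheticBondSpec(p_form=1.0, n_frames=4, seed=2)
        frames = realize_bond_frames(spec)
        pm = dynamic_propensity(frames, [self.bond])
        assert pm.entries[self.bond] == 1.0

    def test_three_of_four_frames_give_075(self):
        spec = SyntheticBondSpec(p_form=0.5, n_frames=400, seed=9)
        frames = realize_bond_frames(spec)
        states = telegraph_states(spec)
        pm = dynamic_propensity(frames, [self.bond])
        assert pm.entries[self.bond] == pytest.approx(states.mean())
        # and a literal 3-in-4 sub-trajectory
        idx = list(np.where(states)[0][:3]) + list(np.where(~states)[0][:1])
        sub = TrajectoryFrames([frames.frames[i] for i in idx])
        assert dynamic_propensity(sub, [self.bond]).entries[self.bond] == 0.75

    def test_equals_mean_of_per_frame_static_matrices(self):
        spec = SyntheticBondSpec(p_form=0.6, n_frames=10, seed=4)
        frames = realize_bond_frames(spec)
        pm = dynamic_propensity(frames, [self.bond])
        per_frame = [static_contact_matrix(f, min_separation=4).entries[
            self.bond] for f in frames.frames]
        assert pm.entries[self.bond] == pytest.approx(np.mean(per_frame))

    def test_unresolvable_bond_is_named(self):
        spec = SyntheticBondSpec(p_form=1.0, n_frames=1, seed=0)
        frames = realize_bond_frames(spec)
        with pytest.raises(Exception, match="99"):
            dynamic_propensity(frames, [BondKey.from_seq(99, 1)])

    def test_telegraph_recovery_within_3_sigma(self):
        spec = SyntheticBondSpec(p_form=0.7, n_frames=4000, seed=123)
        frames = realize_bond_frames(spec)
        pm = dynamic_propensity(frames, [self.bond])
        sigma = math.sqrt(0.7 * 0.3 * spec.autocorr_factor / 4000)
        assert abs(pm.entries[self.bond] - 0.7) < 3 * sigma


class TestDistanceSeriesPropensity:
    def test_fraction_below_cutoff(self):
        series = DistanceSeries.from_mapping({"57-53": [3.0, 3.2, 4.0, 3.4]})
        pm = propensity_from_distance_series(series)
        assert pm.entries[BondKey.from_seq(57, 53)] == 0.75

    def test_boundary_distances_count_as_broken(self):
        series = DistanceSeries.from_mapping({"57-53": [3.5, 3.5]})
        pm = propensity_from_distance_series(series)
        assert pm.entries[BondKey.from_seq(57, 53)] == 0.0

    def test_ragged_series_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            DistanceSeries.from_mapping({"57-53": [3.0, 3.2],
                                         "62-58": [3.0]})

    def test_csv_round_trip(self, tmp_path):
        series = DistanceSeries.from_mapping(
            {"57-53": [3.0, 3.2, 4.0], "62-58": [2.9, 5.0, 2.95]})
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = DistanceSeries.from_csv(path)
        pm1 = propensity_from_distance_series(series)
        pm2 = propensity_from_distance_series(back)
        assert pm1.entries == pm2.entries

    def test_distance_only_propensity_dominates_full(self):
        # the angle test can only remove formations, never add them
        spec = SyntheticBondSpec(p_form=0.5, n_frames=300, seed=21)
        frames = realize_bond_frames(spec)
        bond = BondKey.from_seq(5, 1)
        full = dynamic_propensity(frames, [bond], HBCriterion())
        dist = dynamic_propensity(frames, [bond],
                                  HBCriterion(mode="distance_only"))
        assert dist.entries[bond] >= full.entries[bond]


class TestDeltaMatrix:
    def test_formed_in_pdb_broken_in_dynamics(self):
        key = BondKey.from_seq(62, 58)
        delta = delta_matrix(
            StaticContactMatrix({key: 1}, HBCriterion()),
            PropensityMatrix({key: 0.3081}, 10000, HBCriterion()))
        assert delta.entries[key] == pytest.approx(0.6919)

    def test_absent_from_pdb_formed_in_dynamics(self):
        key = BondKey.from_seq(57, 53)
        delta = delta_matrix(
            StaticContactMatrix({}, HBCriterion()),
            PropensityMatrix({key: 0.9007}, 10000, HBCriterion()))
        assert delta.entries[key] == pytest.approx(-0.9007)

    def test_always_formed_bond_has_zero_delta(self):
        key = BondKey.from_seq(10, 6)
        delta = delta_matrix(
            StaticContactMatrix({key: 1}, HBCriterion()),
            PropensityMatrix({key: 1.0}, 100, HBCriterion()))
        assert delta.entries[key] == 0.0

    def test_delta_plus_propensity_recovers_static_exactly(self):
        rng = np.random.default_rng(5)
        keys = [BondKey.from_seq(i + 5, i) for i in range(1, 30)]
        static = StaticContactMatrix(
            {k: int(rng.random() < 0.5) for k in keys}, HBCriterion())
        prop = PropensityMatrix(
            {k: round(float(rng.random()), 4) for k in keys}, 10000,
            HBCriterion())
        delta = delta_matrix(static, prop)
        for k in keys:
            assert delta.entries[k] + prop.entries[k] == static.entries[k]
            assert -1.0 <= delta.entries[k] <= 1.0


class TestClassifyChameleonic:
    apo = {BondKey.from_seq(57, 53): -0.9007,
           BondKey.from_seq(62, 58): 0.6919,
           BondKey.from_seq(99, 95): 0.5632,
           BondKey.from_seq(100, 96): 0.4481,
           BondKey.from_seq(103, 99): 0.8451,
           BondKey.from_seq(30, 26): 0.0725}

    def test_apo_values_classify_as_published_set(self):
        report = classify_chameleonic(DeltaMatrix(dict(self.apo)))
        cham = {k.label for k, _ in report.chameleonic}
        assert cham == {"57-53", "62-58", "99-95", "103-99"}
        assert [k.label for k, _ in report.borderline] == ["100-96"]

    def test_sorted_by_magnitude_descending(self):
        report = classify_chameleonic(DeltaMatrix(dict(self.apo)))
        mags = [abs(d) for _, d in report.chameleonic]
        assert mags == sorted(mags, reverse=True)

    def test_low_delta_is_neither(self):
        report = classify_chameleonic(DeltaMatrix(dict(self.apo)))
        labels = {k.label for k, _ in report.chameleonic} | \
                 {k.label for k, _ in report.borderline}
        assert "30-26" not in labels

    def test_invariant_under_relabeling(self):
        relabeled = {BondKey.from_seq(k.donor.seq_number + 200,
                                      k.acceptor.seq_number + 200): d
                     for k, d in self.apo.items()}
        a = classify_chameleonic(DeltaMatrix(dict(self.apo)))
        b = classify_chameleonic(DeltaMatrix(relabeled))
        assert [d for _, d in a.chameleonic] == [d for _, d in b.chameleonic]

    def test_stable_under_tiny_perturbation(self):
        base = classify_chameleonic(DeltaMatrix(dict(self.apo)))
        for eps in (-1e-9, 1e-9):
            shifted = {k: d + eps for k, d in self.apo.items()}
            rep = classify_chameleonic(DeltaMatrix(shifted))
            assert [k for k, _ in rep.chameleonic] == \
                   [k for k, _ in base.chameleonic]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_chameleonic(DeltaMatrix({}), threshold=0.3, band_low=0.4)


class TestWindowedPropensity:
    bond = BondKey.from_seq(5, 1)

    def test_constant_formed_series(self):
        frames = realize_bond_frames(
            SyntheticBondSpec(p_form=1.0, n_frames=8, seed=1))
        assert windowed_propensity(frames, self.bond,
                                   n_windows=2) == [1.0, 1.0]

    def test_first_half_formed_only(self):
        spec = SyntheticBondSpec(p_form=0.5, n_frames=600, seed=14)
        frames = realize_bond_frames(spec)
        states = telegraph_states(spec)
        formed = list(np.where(states)[0][:4])
        broken = list(np.where(~states)[0][:4])
        sub = TrajectoryFrames([frames.frames[i] for i in formed + broken])
        assert windowed_propensity(sub, self.bond, n_windows=2) == [1.0, 0.0]

    def test_remainder_goes_to_last_window(self):
        spec = SyntheticBondSpec(p_form=0.5, n_frames=10, seed=3)
        frames = realize_bond_frames(spec)
        states = telegraph_states(spec).astype(float)
        got = windowed_propensity(frames, self.bond, n_windows=3)
        # hand split: blocks of 3, 3, 4
        expected = [states[0:3].mean(), states[3:6].mean(),
                    states[6:10].mean()]
        assert got == pytest.approx(expected)

    def test_more_windows_than_frames_rejected(self):
        frames = realize_bond_frames(
            SyntheticBondSpec(p_form=1.0, n_frames=3, seed=0))
        with pytest.raises(ValueError):
            windowed_propensity(frames, self.bond, n_windows=4)
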