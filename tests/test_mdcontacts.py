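"""Contact detection, occupancy accounting, DAFS calling and the auxiliary
force/energy/superposition operations."""

import numpy as np
import pandas as pd
import pytest

import catchquant as cq
from catchquant.mdcontacts import (
    PICONEWTON_PER_KCAL_MOL_A,
    PmfProfile,
    _bond_presence,
)
from catchquant.synth import BondPlan, TrajectorySpec, gen_pulling_ensemble, gen_pmf_profile
from catchquant.synth.trajectory import reference_frame
from catchquant.trajectory import Topology


def _pair_topology():
    atoms = pd.DataFrame(
        {
            "name": ["N", "H", "O"],
            "element": ["N", "H", "O"],
            "res_id": [1, 1, 2],
            "res_name": ["ASN", "ASN", "GLU"],
            "chain": ["V", "V", "A"],
            "molecule": ["VT", "VT", "ACTIN"],
            "charge": [0, 0, 0],
        }
    )
    return Topology(atoms=atoms, donor_pairs=np.array([[0, 1]]), acceptors=np.array([2]))


def _triad_coords(distance, angle_deg):
    a = np.radians(angle_deg)
    return np.array([[0, 0, 0], [1, 0, 0], [distance * np.cos(a), distance * np.sin(a), 0]])


class TestDetectHbonds:
    @pytest.mark.parametrize(
        "distance, angle, expected",
        [(3.4, 20.0, 1), (3.6, 10.0, 0), (3.4, 31.0, 0), (3.5, 30.0, 1)],
    )
    def test_distance_and_angle_cutoffs(self, distance, angle, expected):
        bonds = cq.detect_hbonds(_triad_coords(distance, angle), _pair_topology())
        assert len(bonds) == expected

    def test_missing_hydrogen_skipped_with_warning(self):
        top = _pair_topology()
        top = Topology(atoms=top.atoms, donor_pairs=np.array([[0, -1]]), acceptors=np.array([2]))
        with pytest.warns(UserWarning, match="no hydrogen"):
            assert cq.detect_hbonds(_triad_coords(3.0, 5.0), top) == []

    def test_matches_bruteforce_oracle_on_random_frames(self):
        # independent all-pairs re-implementation of the geometric criterion
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_don, n_acc = 8, 9
            rows, donor_pairs, acceptors = [], [], []
            idx = 0
            for i in range(n_don):
                rows.append({"name": "N", "element": "N", "res_id": 10 + i, "res_name": "DON",
                             "chain": "V", "molecule": "VT", "charge": 0})
                rows.append({"name": "H", "element": "H", "res_id": 10 + i, "res_name": "DON",
                             "chain": "V", "molecule": "VT", "charge": 0})
                donor_pairs.append((idx, idx + 1))
                idx += 2
            for j in range(n_acc):
                rows.append({"name": "O", "element": "O", "res_id": 50 + j, "res_name": "ACC",
                             "chain": "A", "molecule": "ACTIN", "charge": 0})
                acceptors.append(idx)
                idx += 1
            top = Topology(atoms=pd.DataFrame(rows), donor_pairs=np.array(donor_pairs),
                           acceptors=np.array(acceptors))
            coords = rng.uniform(0, 8, size=(idx, 3))
            got = {(b.donor_index, b.acceptor_index) for b in cq.detect_hbonds(coords, top)}
            expected = set()
            for d, h in donor_pairs:
                for a in acceptors:
                    da = coords[a] - coords[d]
                    dh = coords[h] - coords[d]
                    dist = np.linalg.norm(da)
                    cosang = da @ dh / (dist * np.linalg.norm(dh))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if dist <= 3.5 and ang <= 30.0:
                        expected.add((d, a))
            assert got == expected


class TestInterfaceMetrics:
    def _topology(self):
        atoms = pd.DataFrame(
            {
                "name": ["NH1", "OE1"],
                "element": ["N", "O"],
                "res_id": [1, 2],
                "res_name": ["ARG", "GLU"],
                "chain": ["V", "A"],
                "molecule": ["VT", "ACTIN"],
                "charge": [1, -1],
            }
        )
        return Topology(atoms=atoms, donor_pairs=np.zeros((0, 2)), acceptors=np.zeros(0))

    def test_salt_bridge_inside_cutoff(self):
        m = cq.interface_metrics(np.array([[0, 0, 0], [3.0, 0, 0.0]]), self._topology())
        assert m["salt_bridges"] == 1

    def test_salt_bridge_outside_cutoff(self):
        m = cq.interface_metrics(np.array([[0, 0, 0], [3.3, 0, 0.0]]), self._topology())
        assert m["salt_bridges"] == 0

    def test_isolated_atoms_no_contacts(self):
        m = cq.interface_metrics(np.array([[0, 0, 0], [8.0, 0, 0.0]]), self._topology())
        assert m["vdw_contacts"] == 0
        assert m["buried_area"] == pytest.approx(0.0, abs=1e-6)

    def test_vdw_contact_within_5A(self):
        m = cq.interface_metrics(np.array([[0, 0, 0], [4.5, 0, 0.0]]), self._topology())
        assert m["vdw_contacts"] == 1
        assert m["buried_area"] > 0


def _occupancy_spec(occ, n_frames=10):
    return TrajectorySpec(
        n_frames=n_frames,
        bonds=[BondPlan("b", {"pointed": {0.0: occ}})],
        forces=[0.0],
        directions=("pointed",),
    )


class TestOccupancyTable:
    def test_four_of_ten_frames_is_forty_percent(self):
        ens = gen_pulling_ensemble(_occupancy_spec(40.0))
        table = cq.occupancy_table(ens)
        assert len(table) == 1
        assert table["occupancy"].iloc[0] == 40.0

    def test_never_formed_bond_absent_from_table(self):
        ens = gen_pulling_ensemble(_occupancy_spec(0.0))
        assert len(cq.occupancy_table(ens)) == 0

    def test_planted_profile_recovered_exactly(self):
        spec, _ = __import__("catchquant.workflows", fromlist=["x"]).dafs_benchmark_spec(
            n_frames=20, n_replicates=2, seed=5
        )
        ens = gen_pulling_ensemble(spec)
        table = cq.occupancy_table(ens, reference=reference_frame(spec))
        truth = ens.metadata["planted_occupancy"]
        merged = table.merge(truth, on=["bond", "direction", "force"], suffixes=("", "_t"))
        assert len(merged) == (truth["occupancy"] > 0).sum()
        np.testing.assert_allclose(merged["occupancy"], merged["occupancy_t"])
        assert (merged["native"] == merged["native_t"]).all()

    def test_vectorised_presence_agrees_with_per_frame_detector(self):
        spec, _ = __import__("catchquant.workflows", fromlist=["x"]).dafs_benchmark_spec(
            n_frames=10, n_replicates=1, flip_probability=0.3, seed=9
        )
        ens = gen_pulling_ensemble(spec)
        traj = ens.trajectories[0]
        fast = _bond_presence(traj.coords, ens.topology)
        for f, frame in enumerate(traj.coords):
            slow = {b.pair_id for b in cq.detect_hbonds(frame, ens.topology)}
            assert {pid for pid, pres in fast.items() if pres[f]} == slow


class TestNativeFraction:
    def _table(self, occupancies):
        return pd.DataFrame(
            {
                "bond": [f"b{i}" for i in range(len(occupancies))],
                "direction": "pointed",
                "force": 0.0,
                "occupancy": occupancies,
                "native": True,
            }
        )

    def test_all_native_persist(self):
        table = self._table([50.0] * 10)
        assert cq.native_fraction(table, 0.0, "pointed", [f"b{i}" for i in range(10)]) == 1.0

    def test_half_native_persist(self):
        table = self._table([50.0] * 5)  # other five native bonds have no rows (occupancy 0)
        assert cq.native_fraction(table, 0.0, "pointed", [f"b{i}" for i in range(10)]) == 0.5

    def test_reference_native_count_sets_denominator(self):
        # ten interface residues in the reference contact list -> N_total = 10
        native = [f"VT:RES{i}|ACTIN:ACC{i}" for i in (976, 980, 983, 987, 1008, 1018, 1026, 1039, 1040, 1042)]
        table = pd.DataFrame({"bond": native[:3], "direction": "pointed", "force": 124.0,
                              "occupancy": 30.0, "native": True})
        assert cq.native_fraction(table, 124.0, "pointed", native) == pytest.approx(0.3)

    def test_empty_native_set_rejected(self):
        with pytest.raises(ValueError):
            cq.native_fraction(self._table([50.0]), 0.0, "pointed", [])


class TestClassifyDafs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["bond", "direction", "force", "occupancy", "native"])

    def test_occupancy_45_is_long_lived(self):
        rows = [("b", d, f, occ, False) for d in ("pointed", "barbed", "normal")
                for f, occ in [(0.0, 40.0), (128.0, 45.0)]]
        (call,) = cq.classify_dafs(self._table(rows))
        assert call.lifetime == "long"

    def test_ratio_above_threshold_is_strengthening(self):
        rows = [("b", "pointed", 0.0, 30.0, False), ("b", "pointed", 128.0, 34.0, False)]
        (call,) = cq.classify_dafs(self._table(rows))
        assert call.response_by_direction["pointed"] == "strengthening"  # 34/30 = 1.133

    def test_ratio_within_band_is_stable(self):
        rows = [("b", "pointed", 0.0, 30.0, False), ("b", "pointed", 128.0, 32.0, False)]
        (call,) = cq.classify_dafs(self._table(rows))
        assert call.response_by_direction["pointed"] == "stable"

    def test_pointed_only_strengthening_is_dafs(self):
        rows = []
        for d, occ in [("pointed", 50.0), ("barbed", 30.0), ("normal", 30.0)]:
            rows += [("b", d, 0.0, 30.0, False), ("b", d, 128.0, occ, False)]
        (call,) = cq.classify_dafs(self._table(rows))
        assert call.is_dafs and call.strengthening_directions == ("pointed",)

    def test_all_direction_strengthening_is_not_dafs(self):
        rows = []
        for d in ("pointed", "barbed", "normal"):
            rows += [("b", d, 0.0, 30.0, False), ("b", d, 128.0, 50.0, False)]
        (call,) = cq.classify_dafs(self._table(rows))
        assert not call.is_dafs

    def test_single_force_response_indeterminate(self):
        rows = [("b", "pointed", 128.0, 45.0, False)]
        (call,) = cq.classify_dafs(self._table(rows))
        assert call.response_by_direction["pointed"] == "indeterminate"
        assert call.lifetime == "long"


class TestForceConversion:
    def test_zero_energy_zero_force(self):
        assert cq.force_from_energy_step(0.0, 2.0) == 0.0

    def test_unit_conversion_constant(self):
        # 1 kcal/mol/A in pN via N_A and the thermochemical calorie
        expected = 1e12 * 4184.0 / 6.02214076e23 / 1e-10
        assert cq.force_from_energy_step(1.0, 1.0) == pytest.approx(expected, rel=1e-9)
        assert PICONEWTON_PER_KCAL_MOL_A == pytest.approx(69.48, abs=0.01)

    def test_discrete_step_magnitude(self):
        # the 0.015 kcal/mol jump per 1 A step corresponds to ~1 pN sampling
        assert cq.force_from_energy_step(0.015, 1.0) == pytest.approx(1.042, abs=0.001)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            cq.force_from_energy_step(1.0, 0.0)


class TestPullingPlan:
    def test_single_entry(self):
        assert cq.plan_pulling_batch(0, 0, 1, ("pointed",), 1).n_simulations == 1

    def test_three_forces_two_directions_three_replicates(self):
        plan = cq.plan_pulling_batch(0, 10, 5, ("pointed", "barbed"), 3)
        assert plan.n_simulations == 18
        assert sorted(plan.entries["force"].unique()) == [0.0, 5.0, 10.0]

    def test_empty_directions_rejected(self):
        with pytest.raises(ValueError):
            cq.plan_pulling_batch(0, 10, 1, (), 1)


class TestPmfDeltaG:
    def test_flat_curve_zero(self):
        p = PmfProfile(xi=np.linspace(0, 2, 50), energy=np.zeros(50))
        assert cq.pmf_delta_g(p) == 0.0

    def test_depth_recovered_from_synthetic_well(self):
        p = gen_pmf_profile(54.73)
        assert cq.pmf_delta_g(p) == pytest.approx(54.73, rel=1e-3)

    def test_invariant_to_constant_offset(self):
        p = gen_pmf_profile(25.02)
        shifted = PmfProfile(xi=p.xi, energy=p.energy + 17.3)
        assert cq.pmf_delta_g(shifted) == pytest.approx(cq.pmf_delta_g(p), abs=1e-9)

    def test_non_monotonic_coordinate_rejected(self):
        with pytest.raises(ValueError):
            cq.pmf_delta_g(PmfProfile(xi=np.array([0.0, 1.0, 0.5]), energy=np.zeros(3)))


class TestSuperposeRmsd:
    def test_identical_structures_zero(self):
        a = np.random.default_rng(0).normal(size=(20, 3))
        assert cq.superpose_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        b = a @ rot.T + np.array([5.0, -3.0, 2.0])
        assert cq.superpose_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_scipy_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        a = rng.normal(size=(25, 3))
        b = a + rng.normal(scale=0.5, size=a.shape)
        rot, rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0), return_sensitivity=False
        )
        expected = rssd / np.sqrt(a.shape[0])
        assert cq.superpose_rmsd(a, b) == pytest.approx(expected, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cq.superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
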