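import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gating_metrics.geometry import (
    AngleMetric,
    DistanceMetric,
    SiteSpec,
    SuperpositionError,
    align_structures,
    kabsch_superpose,
    metric_over_trajectory,
    residue_displacement,
    sidechain_axis_angle,
    site_center_distance,
)
from gating_metrics.structure import EmptySelectionError, Selection, Structure, Trajectory
from gating_metrics.synthetic import DriftPlan, demo_config, build_tetramer, simulate_trajectory

from conftest import make_structure
from _oracles import horn_quaternion_rmsd


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_identical_sets_give_identity_transform(self, rng):
        pts = rng.normal(size=(8, 3))
        fit = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-12)
        assert fit.rmsd < 1e-12

    def test_recovers_constructed_transform(self, rng):
        pts = rng.normal(size=(10, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([1.0, 2.0, 3.0])
        target = pts @ Rz.T + t
        fit = kabsch_superpose(pts, target)
        np.testing.assert_allclose(fit.rotation, Rz, atol=1e-10)
        np.testing.assert_allclose(fit.translation, t, atol=1e-10)
        assert fit.rmsd < 1e-10

    def test_rotation_is_proper_orthonormal(self, rng):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        fit = kabsch_superpose(a, b)
        np.testing.assert_allclose(fit.rotation.T @ fit.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_reflection_excluded(self, rng):
        """Mirroring one set must not be undone by an improper rotation."""
        pts = rng.normal(size=(20, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        fit = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-10)
        assert fit.rmsd > 0.1

    def test_matches_quaternion_oracle_on_many_random_sets(self):
        """SVD-route RMSD equals Horn's quaternion eigenvalue method to 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(120):
            n = rng.integers(4, 30)
            a = rng.normal(size=(n, 3)) * rng.uniform(0.5, 5.0)
            b = a @ random_rotation(rng).T + rng.normal(size=3) + rng.normal(
                scale=0.3, size=(n, 3)
            )
            fit = kabsch_superpose(a, b)
            assert fit.rmsd == pytest.approx(horn_quaternion_rmsd(a, b), abs=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self, rng):
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        base = kabsch_superpose(a, b).rmsd
        R = random_rotation(rng)
        moved = a @ R.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_superpose(moved, b).rmsd == pytest.approx(base, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(SuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(SuperpositionError):
            kabsch_superpose(line, line)


class TestAlignStructures:
    def test_self_alignment_is_identity(self, wt_tetramer):
        sel = Selection.make(res_seq_ranges=demo_config().tm_ranges, backbone_only=True)
        aligned, fit = align_structures(wt_tetramer, wt_tetramer, sel)
        assert fit.rmsd < 1e-12
        np.testing.assert_allclose(aligned.coords, wt_tetramer.coords, atol=1e-9)

    def test_fit_on_tm_preserves_ctd_displacement(self, wt_tetramer):
        """Moving the cytoplasmic region must survive a TM-only alignment."""
        cfg = demo_config()
        sel = Selection.make(res_seq_ranges=cfg.tm_ranges, backbone_only=True)
        coords = wt_tetramer.coords.copy()
        ctd = [i for i, a in enumerate(wt_tetramer.atoms) if a.res_seq >= 215]
        coords[ctd] += np.array([0.0, 0.0, -3.0])
        moved = wt_tetramer.with_coords(coords)
        aligned, fit = align_structures(moved, wt_tetramer, sel)
        assert fit.rmsd < 1e-9  # TM region untouched
        shift = aligned.coords[ctd] - wt_tetramer.coords[ctd]
        np.testing.assert_allclose(np.linalg.norm(shift, axis=1), 3.0, atol=1e-9)

    def test_unresolvable_fit_selection_is_an_error(self, wt_tetramer):
        sel = Selection.make(res_seq_ranges=[(9000, 9001)])
        with pytest.raises(EmptySelectionError):
            align_structures(wt_tetramer, wt_tetramer, sel)


class TestResidueDisplacement:
    def test_identical_structures_give_zero_profile(self, wt_tetramer):
        sel = Selection.make(res_seq_ranges=demo_config().tm_ranges, backbone_only=True)
        prof = residue_displacement(wt_tetramer, wt_tetramer, sel)
        assert max(d for *_, d in prof.entries) < 1e-9

    def test_three_four_five_translation(self, wt_tetramer):
        """One residue rigidly moved by (3,4,0) shows displacement exactly 5."""
        cfg = demo_config()
        sel = Selection.make(res_seq_ranges=cfg.tm_ranges, backbone_only=True)
        coords = wt_tetramer.coords.copy()
        target = [
            i for i, a in enumerate(wt_tetramer.atoms)
            if a.chain_id == "A" and a.res_seq == 220
        ]
        coords[target] += np.array([3.0, 4.0, 0.0])
        moved = wt_tetramer.with_coords(coords)
        prof = residue_displacement(wt_tetramer, moved, sel)
        disp = prof.as_dict()
        assert disp[("A", 220)] == pytest.approx(5.0, abs=1e-9)
        others = [v for k, v in disp.items() if k != ("A", 220)]
        assert max(others) < 1e-9

    def test_profile_is_symmetric(self, wt_tetramer, rng):
        sel = Selection.make(res_seq_ranges=demo_config().tm_ranges, backbone_only=True)
        coords = wt_tetramer.coords + rng.normal(scale=0.2, size=wt_tetramer.coords.shape)
        other = wt_tetramer.with_coords(coords)
        ab = residue_displacement(wt_tetramer, other, sel).as_dict()
        ba = residue_displacement(other, wt_tetramer, sel).as_dict()
        for key in ab:
            assert ab[key] == pytest.approx(ba[key], abs=1e-6)

    def test_matches_hand_computed_heavy_centers(self, wt_tetramer, rng):
        """Aligned-frame displacement equals a direct center-of-geometry calc."""
        sel = Selection.make(res_seq_ranges=demo_config().tm_ranges, backbone_only=True)
        coords = wt_tetramer.coords + rng.normal(scale=0.3, size=wt_tetramer.coords.shape)
        other = wt_tetramer.with_coords(coords)
        prof = residue_displacement(wt_tetramer, other, sel)
        aligned, _ = align_structures(other, wt_tetramer, sel)
        by_res = {}
        for i, a in enumerate(wt_tetramer.atoms):
            if not a.is_hydrogen:
                by_res.setdefault(a.residue, []).append(i)
        for chain, res, _, d in prof.entries:
            idx = by_res[(chain, res)]
            expected = np.linalg.norm(
                wt_tetramer.coords[idx].mean(axis=0) - aligned.coords[idx].mean(axis=0)
            )
            assert d == pytest.approx(expected, abs=1e-9)

    def test_missing_residues_are_skipped_and_reported(self, wt_tetramer):
        sel = Selection.make(res_seq_ranges=demo_config().tm_ranges, backbone_only=True)
        keep = [a for a in wt_tetramer.atoms if not (a.chain_id == "D" and a.res_seq == 304)]
        partial = Structure(keep)
        prof = residue_displacement(wt_tetramer, partial, sel)
        assert ("D", 304) in prof.skipped
        assert ("D", 304) not in prof.as_dict()


class TestSiteCenterDistance:
    def test_hand_computed_three_four_five(self):
        s = make_structure(
            [
                ("NH1", (0, 0, 0), {"res_seq": 78, "res_name": "ARG"}),
                ("NH2", (0, 0, 2), {"res_seq": 78, "res_name": "ARG"}),
                ("NH1", (3, 4, 0), {"res_seq": 186, "res_name": "ARG"}),
                ("NH2", (3, 4, 2), {"res_seq": 186, "res_name": "ARG"}),
            ]
        )
        d = site_center_distance(
            s,
            SiteSpec.make(78, ["NH1", "NH2"], chain_id="A"),
            SiteSpec.make(186, ["NH1", "NH2"], chain_id="A"),
        )
        assert d == pytest.approx(5.0, abs=1e-12)

    def test_coincident_centers_give_zero(self):
        s = make_structure(
            [
                ("NH1", (1, 1, 1), {"res_seq": 1}),
                ("NH2", (3, 3, 3), {"res_seq": 1}),
                ("CA", (2, 2, 2), {"res_seq": 2}),
            ]
        )
        d = site_center_distance(
            s,
            SiteSpec.make(1, ["NH1", "NH2"], chain_id="A"),
            SiteSpec.make(2, ["CA"], chain_id="A"),
        )
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, wt_tetramer, rng):
        sa = SiteSpec.make(78, ["NH1", "NH2"], chain_id="A")
        sb = SiteSpec.make(186, ["NH1", "NH2"], chain_id="A")
        base = site_center_distance(wt_tetramer, sa, sb)
        R = random_rotation(rng)
        moved = wt_tetramer.with_coords(wt_tetramer.coords @ R.T + np.array([3.0, -7.0, 1.0]))
        assert site_center_distance(moved, sa, sb) == pytest.approx(base, abs=1e-9)

    def test_unresolved_site_names_the_site(self, wt_tetramer):
        with pytest.raises(EmptySelectionError, match="9999"):
            site_center_distance(
                wt_tetramer,
                SiteSpec.make(9999, ["CA"], chain_id="A"),
                SiteSpec.make(78, ["NH1"], chain_id="A"),
            )

    def test_cross_subunit_offset_follows_ring_order(self, wt_tetramer):
        """TMD-CTD style metric: D76-CA of one subunit to K220-CA of the next."""
        sa = SiteSpec.make(76, ["CA"])
        sb = SiteSpec.make(220, ["CA"], chain_offset=1)
        d_ab = site_center_distance(
            wt_tetramer, sa, sb, ring_order=["A", "B", "C", "D"], subunit="A"
        )
        ia = wt_tetramer.atom_index("A", 76, "CA")
        ib = wt_tetramer.atom_index("B", 220, "CA")
        expected = np.linalg.norm(wt_tetramer.coords[ia] - wt_tetramer.coords[ib])
        assert d_ab == pytest.approx(expected, abs=1e-12)
        # reversing the declared direction picks the other neighbour
        sb_rev = SiteSpec.make(220, ["CA"], chain_offset=-1)
        d_rev = site_center_distance(
            wt_tetramer, sa, sb_rev, ring_order=["A", "B", "C", "D"], subunit="A"
        )
        idx = wt_tetramer.atom_index("D", 220, "CA")
        expected_rev = np.linalg.norm(wt_tetramer.coords[ia] - wt_tetramer.coords[idx])
        assert d_rev == pytest.approx(expected_rev, abs=1e-12)


class TestSidechainAxisAngle:
    @pytest.mark.parametrize(
        "cg2,expected",
        [((0, 0, 1), 0.0), ((1, 0, 0), 90.0), ((1, 0, 1), 45.0), ((0, 0, -1), 180.0)],
    )
    def test_unit_geometries(self, cg2, expected):
        s = make_structure(
            [
                ("CG1", (0, 0, 0), {"res_seq": 223, "res_name": "ILE"}),
                ("CG2", cg2, {"res_seq": 223, "res_name": "ILE"}),
            ]
        )
        angle = sidechain_axis_angle(s, "A", 223, "CG1", "CG2")
        assert angle == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_antiparallel_vectors_sum_to_180(self, seed):
        v = np.random.default_rng(seed).normal(size=3)
        if np.linalg.norm(v) < 1e-6:
            v = np.array([1.0, 0.0, 0.0])
        s = make_structure(
            [
                ("CG1", (0, 0, 0), {"res_seq": 1}),
                ("CG2", tuple(v), {"res_seq": 1}),
                ("CD1", (0, 0, 0), {"res_seq": 2}),
                ("CD2", tuple(-v), {"res_seq": 2}),
            ]
        )
        fwd = sidechain_axis_angle(s, "A", 1, "CG1", "CG2")
        bwd = sidechain_axis_angle(s, "A", 2, "CD1", "CD2")
        assert fwd + bwd == pytest.approx(180.0, abs=1e-7)

    def test_missing_atom_is_an_error(self, wt_tetramer):
        with pytest.raises(KeyError):
            sidechain_axis_angle(wt_tetramer, "A", 223, "CG1", "CG9")

    def test_zero_axis_is_an_error(self, wt_tetramer):
        with pytest.raises(ValueError, match="axis"):
            sidechain_axis_angle(wt_tetramer, "A", 223, "CG1", "CG2", axis=(0, 0, 0))

    def test_planted_orientations_recovered(self, wt_tetramer, mutant_tetramer):
        """The demo topologies plant Ile at 75° and Leu at 20° from +Z."""
        wt = sidechain_axis_angle(wt_tetramer, "A", 223, "CG1", "CG2")
        mut = sidechain_axis_angle(mutant_tetramer, "A", 223, "CD1", "CD2")
        assert wt == pytest.approx(75.0, abs=1e-6)
        assert mut == pytest.approx(20.0, abs=1e-6)


class TestMetricOverTrajectory:
    def test_static_trajectory_gives_constant_series(self, wt_tetramer):
        traj = simulate_trajectory(wt_tetramer, n_frames=4, fluctuation_sd=0.0, seed=0)
        metric = DistanceMetric(
            "r78_r186",
            SiteSpec.make(78, ["NH1", "NH2"]),
            SiteSpec.make(186, ["NH1", "NH2"]),
        )
        series = metric_over_trajectory(traj, metric)
        assert set(series.per_subunit) == {"A", "B", "C", "D"}
        for vals in series.per_subunit.values():
            assert np.ptp(vals) < 1e-12

    def test_planted_drift_recovered_on_affected_subunits(self, wt_tetramer):
        sa = SiteSpec.make(76, ["CA"])
        sb = SiteSpec.make(220, ["CA"], chain_offset=1)
        plan = DriftPlan(
            site_a=sa, site_b=sb, total_change=-2.0, affected_subunits=("A", "B", "C")
        )
        traj = simulate_trajectory(
            wt_tetramer, n_frames=21, fluctuation_sd=0.0, drifts=[plan]
        )
        series = metric_over_trajectory(traj, DistanceMetric("tmd_ctd", sa, sb))
        deltas = {c: v[-1] - v[0] for c, v in series.per_subunit.items()}
        for chain in ("A", "B", "C"):
            assert deltas[chain] == pytest.approx(-2.0, abs=1e-6)
        assert deltas["D"] == pytest.approx(0.0, abs=1e-9)

    def test_angle_metric_per_subunit(self, wt_tetramer):
        traj = simulate_trajectory(wt_tetramer, n_frames=3, fluctuation_sd=0.0, seed=0)
        series = metric_over_trajectory(
            traj, AngleMetric("i223", 223, "CG1", "CG2")
        )
        assert len(series.per_subunit) == 4
        for vals in series.per_subunit.values():
            np.testing.assert_allclose(vals, 75.0, atol=1e-6)
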