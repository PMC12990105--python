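"""Progress/deviation variables, arched path construction, restraints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epathcv import (
    AtomSelection, DeviationWall, Milestone2D, PathDefinition, ValidationError,
    WindowedHarmonic, analysis_lambda, build_arched_path, endpoint_distance,
    epath_distance, epath_sz, load_path_config, make_transition_trajectory,
    project_trajectory, restraint_energy, rpath_sz, save_path_config,
    suggest_lambda,
)

from oracles import bezier_arc_lengths, naive_epath_sz, naive_sz, rotation_search_rmsd


def two_milestone_path(lam=1.0):
    return PathDefinition("EPATH", [Milestone2D(1, 0.0, 1.0),
                                    Milestone2D(2, 1.0, 0.0)], lam)


def random_epath(rng, n=None, lam=None):
    n = n or int(rng.integers(2, 10))
    pts = np.cumsum(0.1 + rng.random((n, 2)) * 0.3, axis=0)
    ms = [Milestone2D(i + 1, pts[i, 0], pts[i, 1]) for i in range(n)]
    return PathDefinition("EPATH", ms, lam or float(rng.uniform(0.5, 50.0)))


class TestEpathDistance:
    def test_identity(self):
        assert epath_distance((0.3, 0.4), Milestone2D(1, 0.3, 0.4)) == 0.0

    def test_3_4_5_triangle(self):
        assert epath_distance((0.0, 0.0), (0.3, 0.4)) == pytest.approx(0.5)

    def test_matches_componentwise_arithmetic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.random(2), rng.random(2)
            expect = math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)
            assert epath_distance(a, b) == pytest.approx(expect, rel=1e-14)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c = rng.random(2), rng.random(2), rng.random(2)
            assert epath_distance(a, c) <= \
                epath_distance(a, b) + epath_distance(b, c) + 1e-12

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            epath_distance((-0.1, 0.2), (0.0, 0.0))


class TestEpathSZ:
    def test_symmetric_midpoint(self):
        s, _ = epath_sz((0.5, 0.5), two_milestone_path())
        assert s == pytest.approx(1.5, abs=1e-14)

    def test_z_hand_value(self):
        # d^2 = 0.5 to both milestones: z = -ln(2 e^{-0.5}) = 0.5 - ln 2
        _, z = epath_sz((0.5, 0.5), two_milestone_path(lam=1.0))
        assert z == pytest.approx(0.5 - math.log(2.0), abs=1e-14)

    def test_large_lambda_snaps_to_milestone(self):
        path = two_milestone_path(lam=1e6)
        s, z = epath_sz((1.0, 0.0), path)
        assert s == pytest.approx(2.0, abs=1e-6)
        assert z == pytest.approx(0.0, abs=1e-6)

    def test_matches_naive_summation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            path = random_epath(rng)
            pt = rng.random(2) * 2
            s, z = epath_sz(pt, path)
            s0, z0 = naive_epath_sz(pt, path.milestone_points(), path.lam)
            assert s == pytest.approx(s0, rel=1e-10)
            assert z == pytest.approx(z0, rel=1e-10, abs=1e-13)

    def test_s_bounded_by_index_range(self):
        # strictly interior for moderate lambda; inclusive under float saturation
        rng = np.random.default_rng(3)
        for _ in range(50):
            path = random_epath(rng)
            s, _ = epath_sz(rng.random(2) * 2, path)
            assert 1.0 <= s <= path.n_milestones
            moderate = random_epath(rng, lam=2.0)
            s2, _ = epath_sz(rng.random(2) * 2, moderate)
            assert 1.0 < s2 < moderate.n_milestones

    def test_z_nonpositive_at_any_milestone(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            path = random_epath(rng)
            for m in path.milestones:
                _, z = epath_sz(m.point, path)
                assert z <= 1e-12

    def test_nonfinite_point_rejected(self):
        with pytest.raises(ValidationError):
            epath_sz((np.nan, 0.1), two_milestone_path())

    def test_monotone_s_walking_the_milestones(self):
        rng = np.random.default_rng(5)
        path = random_epath(rng, n=7)
        path.lam = analysis_lambda(path)
        s_seq = [epath_sz(m.point, path)[0] for m in path.milestones]
        rounded = np.round(s_seq)
        assert np.all(np.diff(rounded) >= 0)

    @settings(max_examples=50, deadline=None)
    @given(lam=st.floats(0.1, 100.0), px=st.floats(0, 2), py=st.floats(0, 2))
    def test_stability_matches_naive_where_naive_is_finite(self, lam, px, py):
        from hypothesis import assume
        path = two_milestone_path(lam=lam)
        d2 = np.sum((path.milestone_points() - np.array([px, py])) ** 2, axis=1)
        assume(np.max(-lam * d2) > -500.0)  # naive summation stays normal
        s, z = epath_sz((px, py), path)
        s0, z0 = naive_epath_sz((px, py), path.milestone_points(), lam)
        assert s == pytest.approx(s0, rel=1e-12, abs=1e-12)
        assert z == pytest.approx(z0, rel=1e-12, abs=1e-12)


@pytest.fixture(scope="module")
def rpath(toy_endstates, toy_selection):
    ina, act = toy_endstates
    traj = make_transition_trajectory(ina, act, 4, noise=0.0, seed=0)
    ms = [traj.frame_structure(i) for i in range(4)]
    path = PathDefinition("RPATH", ms, lam=1.0,
                          align=toy_selection, measure=toy_selection)
    path.lam = suggest_lambda(path)
    return path


class TestRpathSZ:

    def test_frame_at_milestone_large_lambda(self, rpath):
        sharp = PathDefinition("RPATH", rpath.milestones, lam=1e6,
                               align=rpath.align, measure=rpath.measure)
        for k, m in enumerate(rpath.milestones, start=1):
            s, _ = rpath_sz(m.coordinates, sharp)
            assert s == pytest.approx(k, abs=1e-6)

    def test_two_milestone_hand_formula(self, rpath, toy_selection):
        from scipy.spatial.transform import Rotation
        from epathcv import rmsd_superposed
        two = PathDefinition("RPATH", [rpath.milestones[0], rpath.milestones[-1]],
                             lam=5.0, align=toy_selection, measure=toy_selection)
        # frame is a rigid-motion copy of X_1, so R1 = 0 exactly
        frame = Rotation.from_euler("y", 40, degrees=True).apply(
            two.milestones[0].coordinates) + 0.3
        r2 = rmsd_superposed(frame, two.milestones[1].coordinates, toy_selection)
        expect = (1.0 + 2.0 * math.exp(-5.0 * r2)) / (1.0 + math.exp(-5.0 * r2))
        s, _ = rpath_sz(frame, two)
        assert s == pytest.approx(expect, rel=1e-9)

    def test_matches_naive_summation(self, rpath, toy_selection):
        from epathcv import rmsd_superposed
        rng = np.random.default_rng(6)
        for _ in range(5):
            frame = rpath.milestones[1].coordinates + \
                0.05 * rng.standard_normal(rpath.milestones[1].coordinates.shape)
            r = np.array([rmsd_superposed(frame, m.coordinates, toy_selection)
                          for m in rpath.milestones])
            s0, z0 = naive_sz(r, rpath.lam)
            s, z = rpath_sz(frame, rpath)
            assert s == pytest.approx(s0, rel=1e-10)
            assert z == pytest.approx(z0, rel=1e-10, abs=1e-13)

    def test_squared_flag_changes_metric(self, rpath):
        sq = PathDefinition("RPATH", rpath.milestones, lam=rpath.lam,
                            align=rpath.align, measure=rpath.measure, squared=True)
        frame = rpath.milestones[1].coordinates
        assert rpath_sz(frame, sq) != rpath_sz(frame, rpath)


class TestArchedPath:
    def test_n2_is_just_the_endpoints(self):
        path = build_arched_path(1.0, 2, arch=0.7)
        assert np.allclose(path.milestone_points(), [[0, 1], [1, 0]])

    def test_midpoint_identity(self):
        path = build_arched_path(1.0, 3, arch=0.3)
        assert path.milestones[1].rmsd_inactive == pytest.approx(0.65, abs=1e-12)
        assert path.milestones[1].rmsd_active == pytest.approx(0.65, abs=1e-12)

    def test_equal_arc_length_gaps(self):
        d, n, arch = 1.0, 8, 0.3
        path = build_arched_path(d, n, arch)
        p0, p2 = np.array([0.0, d]), np.array([d, 0.0])
        c = np.array([(1 + 2 * arch) * d / 2] * 2)
        # recover Bezier parameters of the milestones from their x coordinate
        pts = path.milestone_points()
        t_nodes = []
        for x, _ in pts:
            coeff = [p0[0] - 2 * c[0] + p2[0], 2 * (c[0] - p0[0]), p0[0] - x]
            roots = np.roots(coeff)
            t = [r.real for r in roots if abs(r.imag) < 1e-9 and -1e-9 <= r.real <= 1 + 1e-9]
            t_nodes.append(min(t, key=lambda v: abs(v - 0.5)) if len(t) > 1 else t[0])
        gaps = bezier_arc_lengths(p0, c, p2, np.clip(t_nodes, 0, 1))
        assert np.ptp(gaps) < 1e-4

    def test_zero_arch_is_straight_chord(self):
        path = build_arched_path(2.0, 6, arch=0.0)
        pts = path.milestone_points()
        expect = np.linspace([0, 2], [2, 0], 6)
        assert np.allclose(pts, expect, atol=1e-9)

    def test_bows_away_from_origin(self):
        path = build_arched_path(1.0, 8, arch=0.3)
        sums = path.milestone_points().sum(axis=1)
        assert np.all(sums >= 1.0 - 1e-12)

    def test_axis_swap_reversal_symmetry(self):
        pts = build_arched_path(1.0, 7, arch=0.4).milestone_points()
        assert np.allclose(pts, pts[::-1, ::-1], atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            build_arched_path(1.0, 8, arch=-0.1)
        with pytest.raises(ValidationError):
            build_arched_path(1.0, 1)
        with pytest.raises(ValidationError):
            build_arched_path(0.0, 8)


class TestEndpointDistance:
    def test_identical_structures(self, toy_endstates, toy_selection):
        ina = toy_endstates[0]
        assert endpoint_distance(ina, ina, toy_selection) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copies(self, toy_endstates, toy_selection):
        from scipy.spatial.transform import Rotation
        ina = toy_endstates[0]
        moved = ina.with_coordinates(
            Rotation.from_euler("x", 70, degrees=True).apply(ina.coordinates) + 2.0)
        assert endpoint_distance(ina, moved, toy_selection) == pytest.approx(0.0, abs=1e-9)

    def test_bent_vs_straight_matches_search(self, toy_endstates, toy_selection):
        ina, act = toy_endstates
        got = endpoint_distance(ina, act, toy_selection)
        rng = np.random.default_rng(7)
        ref = rotation_search_rmsd(act.coordinates, ina.coordinates, 20000, rng,
                                   polish=True)
        assert got == pytest.approx(ref, abs=1e-3)


class TestSuggestLambda:
    def test_epath_formula(self):
        # consecutive d^2 = 0.01 nm^2 everywhere
        ms = [Milestone2D(i + 1, 0.1 * i, 0.0) for i in range(5)]
        path = PathDefinition("EPATH", ms, lam=1.0)
        assert suggest_lambda(path) == pytest.approx(100 * math.log(2), rel=1e-12)

    def test_rpath_formula(self, toy_endstates, toy_selection):
        from epathcv import rmsd_superposed
        ina, act = toy_endstates
        traj = make_transition_trajectory(ina, act, 3, noise=0.0, seed=0)
        ms = [traj.frame_structure(i) for i in range(3)]
        path = PathDefinition("RPATH", ms, lam=1.0,
                              align=toy_selection, measure=toy_selection)
        gaps = [rmsd_superposed(ms[i].coordinates, ms[i + 1].coordinates, toy_selection)
                for i in range(2)]
        assert suggest_lambda(path) == pytest.approx(math.log(2) / np.mean(gaps))

    def test_doubling_spacing_quarters_epath_lambda(self):
        ms1 = [Milestone2D(i + 1, 0.1 * i, 0.0) for i in range(4)]
        ms2 = [Milestone2D(i + 1, 0.2 * i, 0.0) for i in range(4)]
        l1 = suggest_lambda(PathDefinition("EPATH", ms1, 1.0))
        l2 = suggest_lambda(PathDefinition("EPATH", ms2, 1.0))
        assert l1 == pytest.approx(4 * l2, rel=1e-12)

    def test_coincident_milestones_rejected(self):
        ms = [Milestone2D(1, 0, 0), Milestone2D(2, 0.1, 0), Milestone2D(3, 0.1, 0)]
        with pytest.raises(ValidationError):
            PathDefinition("EPATH", ms, 1.0)


class TestRestraintEnergy:
    SPEC = [WindowedHarmonic("pif", center=0.5, kappa=10.0, s_lo=2.0, s_hi=7.0)]

    def test_zero_at_end_state(self):
        assert restraint_energy(1.0, {"pif": 99.0}, self.SPEC) == 0.0

    def test_zero_at_harmonic_minimum(self):
        assert restraint_energy(4.5, {"pif": 0.5}, self.SPEC) == 0.0

    def test_plateau_arithmetic(self):
        # mid-window, kappa 10, displacement 0.2 -> 10 * 0.04 = 0.4
        assert restraint_energy(4.5, {"pif": 0.7}, self.SPEC) == pytest.approx(0.4)

    def test_taper_is_continuous_and_bounded(self):
        s_grid = np.linspace(1.5, 7.5, 2401)  # step 0.0025 in s
        e = [restraint_energy(s, {"pif": 0.7}, self.SPEC) for s in s_grid]
        assert max(e) <= 0.4 + 1e-12
        assert np.all(np.abs(np.diff(e)) < 0.01)  # bounded slope, no jumps

    def test_deviation_wall(self):
        spec = [DeviationWall(upper=0.1, kappa=100.0)]
        assert restraint_energy(3.0, {"z": 0.05}, spec) == 0.0
        assert restraint_energy(3.0, {"z": 0.3}, spec) == pytest.approx(100 * 0.04)

    def test_unknown_cv_rejected(self):
        with pytest.raises(ValidationError):
            restraint_energy(4.0, {"z": 0.0}, self.SPEC)


class TestProjectionAndSerialization:
    def test_projection_ends_near_end_indices(self, toy_endstates, toy_selection):
        ina, act = toy_endstates
        d = endpoint_distance(ina, act, toy_selection)
        path = build_arched_path(d, 6, align=toy_selection, measure=toy_selection)
        path.lam = analysis_lambda(path)
        traj = make_transition_trajectory(ina, act, 15, noise=0.0, seed=1)
        series = project_trajectory(traj, ina, act, path)
        assert abs(series["s"].iloc[0] - 1.0) < 0.1
        assert abs(series["s"].iloc[-1] - 6.0) < 0.1
        assert np.all(np.diff(np.round(series["s"])) >= 0)

    def test_config_roundtrip(self, tmp_path):
        path = build_arched_path(0.8, 8, arch=0.25)
        f = tmp_path / "path.txt"
        save_path_config(path, str(f))
        back = load_path_config(str(f))
        assert back.lam == path.lam
        assert np.allclose(back.milestone_points(), path.milestone_points())
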