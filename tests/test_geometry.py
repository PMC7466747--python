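import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntckit.geometry import (
    DegenerateGeometryError,
    StepParameters,
    UndefinedTorsionError,
    circular_difference,
    compute_step_parameters,
    dihedral,
    superpose_rmsd,
    wrap_angle,
)

from conftest import random_rotation, transform_step


def oracle_dihedral(p1, p2, p3, p4):
    """Independent IUPAC-sign torsion via the two-plane atan2 construction."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))


class TestDihedral:
    @pytest.mark.parametrize("p4,expected", [
        ((1.0, 1.0, 0.0), 0.0),     # cis planar
        ((1.0, -1.0, 0.0), 180.0),  # trans planar
        ((1.0, 0.0, 1.0), -90.0),   # right-hand rule sign
    ])
    def test_planar_and_sign_conventions(self, p4, expected):
        p1, p2, p3 = (0, 1, 0), (0, 0, 0), (1, 0, 0)
        assert dihedral(p1, p2, p3, p4) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_quadruples(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            pts = rng.normal(scale=2.0, size=(4, 3))
            expected = oracle_dihedral(*pts)
            got = dihedral(*pts)
            assert circular_difference(got, expected) < 1e-9

    def test_collinear_raises(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_invariance_and_mirror_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=2.0, size=(4, 3))
        try:
            ref = dihedral(*pts)
        except UndefinedTorsionError:
            return
        R = random_rotation(rng)
        t = rng.normal(scale=5.0, size=3)
        moved = pts @ R.T + t
        assert circular_difference(dihedral(*moved), ref) < 1e-8
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        assert circular_difference(dihedral(*mirrored), -ref) < 1e-8


class TestCircularDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (350.0, 10.0, 20.0),
        (42.0, 42.0, 0.0),
        (-180.0, 180.0, 0.0),
        (0.0, 180.0, 180.0),
        (-170.0, 170.0, 20.0),
    ])
    def test_examples(self, a, b, expected):
        assert circular_difference(a, b) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(-720, 720), b=st.floats(-720, 720), c=st.floats(-720, 720))
    def test_triangle_inequality_on_circle(self, a, b, c):
        assert circular_difference(a, c) <= \
            circular_difference(a, b) + circular_difference(b, c) + 1e-9

    def test_wrap_angle_range(self):
        vals = wrap_angle(np.array([-180.0, 180.0, 360.0, -540.0, 190.0]))
        assert np.all(vals > -180.0) and np.all(vals <= 180.0)
        assert vals[0] == 180.0 and vals[1] == 180.0


def oracle_superpose_rmsd(X, Y, levels=((15.0, 24), (1.5, 10), (0.15, 10), (0.015, 10))):
    """Coarse-to-fine Euler-angle grid search over proper rotations."""

    def rot(ax, ay, az):
        cx, sx, cy, sy, cz, sz = (f(v) for v in (ax, ay, az) for f in (math.cos, math.sin))
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    best = (np.inf, (0.0, 0.0, 0.0))
    center = (0.0, 0.0, 0.0)
    for step_deg, n in levels:
        h = math.radians(step_deg)
        axs = [center[0] + h * k for k in range(-n, n + 1)]
        ays = [center[1] + h * k for k in range(-n, n + 1)]
        azs = [center[2] + h * k for k in range(-n, n + 1)]
        for ax in axs:
            for ay in ays:
                for az in azs:
                    r = math.sqrt(np.mean(np.sum((Yc @ rot(ax, ay, az).T - Xc) ** 2, axis=1)))
                    if r < best[0]:
                        best = (r, (ax, ay, az))
        center = best[1]
    return best[0]


class TestSuperpose:
    def test_self_is_zero(self, b_like_step):
        X = b_like_step.coords()
        assert superpose_rmsd(X, X).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, b_like_step):
        rng = np.random.default_rng(11)
        X = b_like_step.coords()
        Y = X @ random_rotation(rng).T + rng.normal(scale=10.0, size=3)
        res = superpose_rmsd(X, Y)
        assert res.rmsd <= 1e-9
        assert np.allclose(res.transform(Y), X, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_symmetric_and_bounded_by_raw_rmsd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        Y = X + rng.normal(scale=0.3, size=(10, 3))
        r_xy = superpose_rmsd(X, Y).rmsd
        r_yx = superpose_rmsd(Y, X).rmsd
        assert r_xy == pytest.approx(r_yx, abs=1e-9)
        raw = math.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1)))
        assert r_xy <= raw + 1e-12

    def test_mirror_image_does_not_superpose_exactly(self, b_like_step):
        X = b_like_step.coords()
        assert superpose_rmsd(X, X * np.array([-1.0, 1.0, 1.0])).rmsd > 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_four_point_toy_matches_rotation_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]])
        Y = X.copy()
        Y[3] += rng.normal(scale=0.5, size=3)  # one displaced point
        R = random_rotation(rng)
        Y = Y @ R.T + rng.normal(scale=3.0, size=3)
        assert superpose_rmsd(X, Y).rmsd == pytest.approx(
            oracle_superpose_rmsd(X, Y), abs=1e-4)

    def test_degenerate_inputs_raise(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose_rmsd(line, line)
        with pytest.raises(DegenerateGeometryError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(DegenerateGeometryError):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestStepParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            StepParameters(**{**dict.fromkeys(
                ("delta1", "epsilon1", "zeta1", "alpha2", "beta2", "gamma2",
                 "delta2", "chi1", "chi2", "mu"), 0.0),
                "dist_NN": -1.0, "dist_CC": 5.0})
        p = StepParameters.from_array([190.0] + [0.0] * 9 + [4.0, 5.0])
        assert p.delta1 == pytest.approx(-170.0)  # wrapped into (-180, 180]

    def test_rigid_invariance_of_step_parameters(self, b_like_step):
        rng = np.random.default_rng(2)
        moved = transform_step(b_like_step, random_rotation(rng),
                               rng.normal(scale=8.0, size=3))
        a = compute_step_parameters(b_like_step).as_array()
        b = compute_step_parameters(moved).as_array()
        assert np.all(circular_difference(a[:10], b[:10]) < 1e-9)
        assert np.allclose(a[10:], b[10:], atol=1e-9)

    def test_mirror_negates_torsions_keeps_distances(self, b_like_step):
        mirrored = transform_step(b_like_step, np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
        a = compute_step_parameters(b_like_step).as_array()
        b = compute_step_parameters(mirrored).as_array()
        assert np.all(circular_difference(a[:10], -b[:10]) < 1e-9)
        assert np.allclose(a[10:], b[10:], atol=1e-9)
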