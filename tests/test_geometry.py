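"""Rigid base-pair geometry: frame fitting, parameter extraction, rebuilding."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from modflex.basegeom import standard_atoms
from modflex.geometry import (
    FLIP,
    IntraBpParams,
    ReferenceFrame,
    StepParams,
    base_frames_from_pair,
    base_pair_frame,
    fit_base_frame,
    rebuild_frames,
    step_params,
)


def random_step(rng) -> StepParams:
    return StepParams(
        shift=rng.normal(0, 1),
        slide=rng.normal(0, 1),
        rise=rng.normal(3.4, 0.5),
        tilt=rng.normal(0, 15),
        roll=rng.normal(0, 15),
        twist=rng.normal(36, 30),
    )


def oracle_step_params(f1: ReferenceFrame, f2: ReferenceFrame) -> np.ndarray:
    """Independent geometric recovery of the six step parameters.

    Uses the hinge construction directly with scipy rotations: bend angle and
    hinge from the two z-axes, half-rotation of both frames onto the common
    mid z, twist between the co-aligned x-axes, roll/tilt as the hinge
    components along the mid-frame y/x axes.
    """
    z1, z2 = f1.axes[:, 2], f2.axes[:, 2]
    cosg = np.clip(z1 @ z2, -1, 1)
    gamma = np.degrees(np.arccos(cosg))
    if gamma < 1e-10:
        hinge = f1.axes[:, 1]
    else:
        hinge = np.cross(z1, z2)
        hinge /= np.linalg.norm(hinge)
    half = Rotation.from_rotvec(np.radians(gamma / 2) * hinge)
    x1p = half.apply(f1.axes[:, 0])
    x2p = half.inv().apply(f2.axes[:, 0])
    zm = half.apply(z1)
    twist = np.degrees(np.arctan2(np.cross(x1p, x2p) @ zm, x1p @ x2p))
    xm = x1p + x2p
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    mid = np.column_stack([xm, ym, zm])
    trans = mid.T @ (f2.origin - f1.origin)
    roll = gamma * (hinge @ ym)
    tilt = gamma * (hinge @ xm)
    return np.array([trans[0], trans[1], trans[2], tilt, roll, twist])


class TestFitBaseFrame:
    def test_self_superposition_is_identity(self):
        frame = fit_base_frame(standard_atoms("G"), "G")
        assert np.allclose(frame.axes, np.eye(3), atol=1e-12)
        assert np.allclose(frame.origin, 0, atol=1e-12)

    @pytest.mark.parametrize("base", ["A", "C", "G", "T", "5mC", "5fC"])
    def test_known_transform_recovered(self, base):
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        observed = {name: R @ xyz + t for name, xyz in standard_atoms(base).items()}
        frame = fit_base_frame(observed, base)
        assert np.allclose(frame.axes, R, atol=1e-9)
        assert np.allclose(frame.origin, t, atol=1e-9)

    def test_rigid_motion_covariance(self, rng):
        """The fitted frame transforms exactly with the observed atoms."""
        atoms = standard_atoms("C")
        base_frame = fit_base_frame(atoms, "C")
        for _ in range(10):
            R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
            t = rng.normal(0, 10, 3)
            moved = {n: R @ x + t for n, x in atoms.items()}
            frame = fit_base_frame(moved, "C")
            assert np.allclose(frame.axes, R @ base_frame.axes, atol=1e-9)
            assert np.allclose(frame.origin, R @ base_frame.origin + t, atol=1e-9)

    def test_too_few_atoms_rejected(self):
        atoms = standard_atoms("C")
        two = {k: atoms[k] for k in ["N1", "C2"]}
        with pytest.raises(ValueError, match=">=3"):
            fit_base_frame(two, "C")

    def test_collinear_atoms_rejected(self):
        collinear = {"N1": np.array([0.0, 0, 0]), "C2": np.array([1.0, 0, 0]),
                     "N3": np.array([2.0, 0, 0])}
        with pytest.raises(ValueError, match="collinear"):
            fit_base_frame(collinear, "C")


class TestBasePairFrame:
    def test_ideal_pair_gives_zero_parameters(self):
        w = ReferenceFrame.identity()
        c = ReferenceFrame(np.zeros(3), np.eye(3) @ FLIP)
        bp, params = base_pair_frame(w, c)
        assert np.allclose(params.as_array(), 0, atol=1e-12)
        assert np.allclose(bp.axes, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize(
        "params",
        [
            IntraBpParams(0, 0, 0, 0, 10.0, 0),  # pure propeller
            IntraBpParams(0.5, 0, 0, 0, 0, 0),  # pure shear
            IntraBpParams(-0.3, 0.2, 0.1, 5.0, -12.0, 3.0),
        ],
    )
    def test_build_then_measure_roundtrip(self, params):
        w, c = base_frames_from_pair(ReferenceFrame.identity(), params)
        _, out = base_pair_frame(w, c)
        assert np.allclose(out.as_array(), params.as_array(), atol=1e-9)

    def test_roundtrip_from_random_bp_frame(self, rng):
        for _ in range(20):
            R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
            bp = ReferenceFrame(rng.normal(0, 5, 3), R)
            params = IntraBpParams(*rng.normal(0, 0.4, 3), *rng.normal(0, 8, 3))
            w, c = base_frames_from_pair(bp, params)
            bp2, out = base_pair_frame(w, c)
            assert np.allclose(out.as_array(), params.as_array(), atol=1e-8)
            assert np.allclose(bp2.axes, bp.axes, atol=1e-8)
            assert np.allclose(bp2.origin, bp.origin, atol=1e-8)


class TestStepParams:
    def test_null_step(self):
        f = ReferenceFrame.identity()
        assert np.allclose(step_params(f, f).as_array(), 0, atol=1e-12)

    def test_pure_twist_rise(self):
        f1 = ReferenceFrame.identity()
        f2 = ReferenceFrame(
            np.array([0, 0, 3.4]), Rotation.from_euler("z", 36, degrees=True).as_matrix()
        )
        out = step_params(f1, f2)
        assert np.allclose(
            out.as_array(), [0, 0, 3.4, 0, 0, 36], atol=1e-9
        )

    def test_oracle_equivalence_on_random_frames(self, rng):
        """Mid-frame decomposition agrees with the independent hinge oracle."""
        for _ in range(200):
            sp = random_step(rng)
            f1_axes = Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))
            ).as_matrix()
            f1 = ReferenceFrame(rng.normal(0, 5, 3), f1_axes)
            f2 = rebuild_frames(f1, [sp])[1]
            ours = step_params(f1, f2).as_array()
            oracle = oracle_step_params(f1, f2)
            assert np.max(np.abs(ours - oracle)) < 1e-6

    def test_step_reversal_symmetry(self, rng):
        """Reversing a step (frame swap + strand flip) negates tilt and shift
        only."""
        for _ in range(50):
            sp = random_step(rng)
            f1, f2 = rebuild_frames(ReferenceFrame.identity(), [sp])
            r1 = ReferenceFrame(f2.origin, f2.axes @ FLIP)
            r2 = ReferenceFrame(f1.origin, f1.axes @ FLIP)
            rev = step_params(r1, r2).as_array()
            fwd = sp.as_array()
            expected = fwd * np.array([-1, 1, 1, -1, 1, 1])
            assert np.allclose(rev, expected, atol=1e-9)

    def test_non_orthonormal_frames_rejected(self):
        with pytest.raises(ValueError):
            ReferenceFrame(np.zeros(3), np.eye(3) * 1.01)


class TestRebuildFrames:
    def test_null_chain(self):
        frames = rebuild_frames(ReferenceFrame.identity(), [StepParams(0, 0, 0, 0, 0, 0)] * 5)
        assert len(frames) == 6
        for f in frames:
            assert np.allclose(f.origin, 0, atol=1e-12)
            assert np.allclose(f.axes, np.eye(3), atol=1e-12)

    def test_ideal_bdna_period_ten(self):
        """One full helical turn: 10 steps of 36 deg twist / 3.4 Å rise."""
        steps = [StepParams(0, 0, 3.4, 0, 0, 36.0)] * 10
        frames = rebuild_frames(ReferenceFrame.identity(), steps)
        assert np.allclose(frames[-1].origin, [0, 0, 34.0], atol=1e-9)
        assert np.allclose(frames[-1].axes, np.eye(3), atol=1e-9)

    def test_roundtrip_identity_random_chains(self, rng):
        """rebuild then re-extract reproduces step parameters to < 1e-8."""
        for _ in range(30):
            steps = [random_step(rng) for _ in range(15)]
            frames = rebuild_frames(ReferenceFrame.identity(), steps)
            assert len(frames) == 16
            for k, sp in enumerate(steps):
                out = step_params(frames[k], frames[k + 1]).as_array()
                assert np.max(np.abs(out - sp.as_array())) < 1e-8

    def test_orthonormality_preserved(self, rng):
        steps = [random_step(rng) for _ in range(50)]
        for f in rebuild_frames(ReferenceFrame.identity(), steps):
            assert f.is_orthonormal(1e-9)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            rebuild_frames(ReferenceFrame.identity(), [StepParams(0, 0, np.nan, 0, 0, 36)])
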