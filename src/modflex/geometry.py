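"""Rigid base-pair description of duplex DNA.

Implements the mid-frame (CEHS-style) decomposition used by standard helical
analysis software: the rotation between two frames is factored as

    A = Rz(omega/2 - phi) . Ry(Gamma) . Rz(omega/2 + phi)

where ``omega`` is the twist about the mid-frame z-axis, ``Gamma`` the bend
(RollTilt) angle about a hinge in the mid-frame xy-plane and ``phi`` the
hinge phase, giving roll = Gamma cos(phi) and tilt = Gamma sin(phi).
Translations (shift, slide, rise) are the origin displacement expressed in
the mid frame.  The same decomposition, applied between the (flipped)
complementary-base frame and the reference-strand frame, yields the six
intra-base-pair parameters (shear, stretch, stagger, buckle, propeller,
opening).

Angles are degrees, distances Å, everywhere.  All operations preserve frame
orthonormality, and ``rebuild_frames`` is the exact inverse of
``step_params`` (round trip < 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basegeom import ring_atom_coords, standard_atoms

__all__ = [
    "ReferenceFrame",
    "IntraBpParams",
    "StepParams",
    "fit_base_frame",
    "base_pair_frame",
    "base_frames_from_pair",
    "step_params",
    "rebuild_frames",
    "step_rotation",
    "mid_frame_rotation",
]

_ORTHO_TOL = 1e-9
#: y/z flip applied to the complementary base's frame so the two frames of a
#: Watson-Crick pair co-align (anti-parallel strands).
FLIP = np.diag([1.0, -1.0, -1.0])


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass(frozen=True)
class ReferenceFrame:
    """A rigid-body frame: origin (Å) plus right-handed orthonormal axes.

    ``axes`` columns are the x, y, z unit vectors expressed in the lab frame.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)
        if not np.all(np.isfinite(origin)) or not np.all(np.isfinite(axes)):
            raise ValueError("frame contains non-finite values")
        if np.max(np.abs(axes.T @ axes - np.eye(3))) > 1e-6:
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame axes are left-handed (det < 0)")

    @classmethod
    def identity(cls) -> "ReferenceFrame":
        return cls(np.zeros(3), np.eye(3))

    def is_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        return (
            np.max(np.abs(self.axes.T @ self.axes - np.eye(3))) <= tol
            and abs(np.linalg.det(self.axes) - 1.0) <= tol
        )


@dataclass(frozen=True)
class IntraBpParams:
    """Shear, stretch, stagger (Å); buckle, propeller, opening (degrees)."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shear, self.stretch, self.stagger, self.buckle, self.propeller, self.opening]
        )


@dataclass(frozen=True)
class StepParams:
    """Shift, slide, rise (Å); tilt, roll, twist (degrees)."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist])

    @classmethod
    def from_array(cls, a) -> "StepParams":
        a = np.asarray(a, dtype=float).reshape(6)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite step parameters")
        return cls(*a)


def _check_frame(frame: ReferenceFrame) -> None:
    if not frame.is_orthonormal(1e-6):
        raise ValueError("frame axes are not orthonormal")


def _wrap_deg(a: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def step_rotation(tilt: float, roll: float, twist: float) -> np.ndarray:
    """Rotation matrix of the mid-frame decomposition for given angles (deg)."""
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.rad2deg(np.arctan2(tilt, roll))) if gamma > 0 else 0.0
    return _rz(twist / 2.0 - phi) @ _ry(gamma) @ _rz(twist / 2.0 + phi)


def mid_frame_rotation(tilt: float, roll: float, twist: float) -> np.ndarray:
    """Orientation of the mid frame relative to the first frame."""
    gamma = float(np.hypot(roll, tilt))
    phi = float(np.rad2deg(np.arctan2(tilt, roll))) if gamma > 0 else 0.0
    return _rz(twist / 2.0 - phi) @ _ry(gamma / 2.0) @ _rz(phi)


def _decompose(R1: np.ndarray, o1: np.ndarray, R2: np.ndarray, o2: np.ndarray):
    """Six rigid-body parameters of frame2 relative to frame1, plus mid frame.

    Returns ``(translations, angles, mid_R, mid_o)`` with translations in the
    mid frame and angles (x-rot, y-rot, z-rot) = (tilt, roll, twist)-like.
    """
    A = R1.T @ R2
    cos_g = np.clip(A[2, 2], -1.0, 1.0)
    gamma = np.rad2deg(np.arccos(cos_g))
    if np.hypot(A[0, 2], A[1, 2]) < 1e-12:
        # no bend: pure z-rotation
        twist = np.rad2deg(np.arctan2(A[1, 0], A[0, 0]))
        phi = 0.0
        gamma = 0.0
    else:
        a = np.arctan2(A[1, 2], A[0, 2])  # twist/2 - phi
        b = np.arctan2(A[2, 1], -A[2, 0])  # twist/2 + phi
        twist = _wrap_deg(np.rad2deg(a + b))
        # phi from the wrapped twist (phi = twist/2 - a); (b-a)/2 alone is
        # only defined mod 180 and can land on the (-Gamma, phi+180) branch.
        phi = _wrap_deg(twist / 2.0 - np.rad2deg(a))
    roll = gamma * np.cos(np.deg2rad(phi))
    tilt = gamma * np.sin(np.deg2rad(phi))
    mid_R = R1 @ mid_frame_rotation(tilt, roll, twist)
    mid_o = 0.5 * (o1 + o2)
    trans = mid_R.T @ (o2 - o1)
    return trans, (tilt, roll, _wrap_deg(twist)), mid_R, mid_o


def _compose(R1: np.ndarray, o1: np.ndarray, trans, tilt: float, roll: float, twist: float):
    """Inverse of :func:`_decompose`: place frame2 from frame1 and parameters."""
    R2 = R1 @ step_rotation(tilt, roll, twist)
    mid_R = R1 @ mid_frame_rotation(tilt, roll, twist)
    o2 = o1 + mid_R @ np.asarray(trans, dtype=float)
    return R2, o2


# ---------------------------------------------------------------------------
# Frame fitting

def fit_base_frame(observed_atoms: dict[str, np.ndarray], base_type: str) -> ReferenceFrame:
    """Least-squares fit of the standard base onto observed coordinates.

    Only ring atoms participate; ≥3 matching, non-collinear atoms are
    required.  The returned frame is the image of the standard reference
    frame under the optimal rigid transform (Kabsch superposition), so it
    transforms covariantly with any rigid motion of the observed atoms.
    """
    names, std = ring_atom_coords(base_type)
    matched = [(std[i], observed_atoms[n]) for i, n in enumerate(names) if n in observed_atoms]
    if len(matched) < 3:
        raise ValueError(
            f"need >=3 matched ring atoms for {base_type}, got {len(matched)}"
        )
    X = np.stack([m[0] for m in matched])  # standard
    Y = np.stack([np.asarray(m[1], dtype=float) for m in matched])  # observed
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-8:
        raise ValueError("matched atoms are (near-)collinear; frame is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    return ReferenceFrame(origin=t, axes=R)


# ---------------------------------------------------------------------------
# Base-pair (intra) parameters

def base_pair_frame(
    frame_w: ReferenceFrame, frame_c: ReferenceFrame
) -> tuple[ReferenceFrame, IntraBpParams]:
    """Mid base-pair frame and intra-bp parameters of a Watson-Crick pair.

    ``frame_c`` (complementary, anti-parallel base) is flipped (y and z
    negated) to co-align with ``frame_w``; parameters describe the reference
    strand's base relative to the flipped complementary base, decomposed in
    their half-way frame.
    """
    _check_frame(frame_w)
    _check_frame(frame_c)
    Rc = frame_c.axes @ FLIP
    trans, (x_rot, y_rot, z_rot), mid_R, mid_o = _decompose(
        Rc, frame_c.origin, frame_w.axes, frame_w.origin
    )
    params = IntraBpParams(
        shear=trans[0], stretch=trans[1], stagger=trans[2],
        buckle=x_rot, propeller=y_rot, opening=z_rot,
    )
    return ReferenceFrame(mid_o, mid_R), params


def base_frames_from_pair(
    bp_frame: ReferenceFrame, params: IntraBpParams
) -> tuple[ReferenceFrame, ReferenceFrame]:
    """Inverse of :func:`base_pair_frame`: the two base frames of a pair."""
    _check_frame(bp_frame)
    tilt_l, roll_l, twist_l = params.buckle, params.propeller, params.opening
    trans = np.array([params.shear, params.stretch, params.stagger])
    # bp_frame is the mid frame between the flipped-C frame (1) and W frame (2)
    mid_rel = mid_frame_rotation(tilt_l, roll_l, twist_l)
    R1 = bp_frame.axes @ mid_rel.T
    half = bp_frame.axes @ trans / 2.0
    o1 = bp_frame.origin - half
    R2, o2 = _compose(R1, o1, trans, tilt_l, roll_l, twist_l)
    frame_w = ReferenceFrame(o2, R2)
    frame_c = ReferenceFrame(o1, R1 @ FLIP)
    return frame_w, frame_c


# ---------------------------------------------------------------------------
# Step parameters

def step_params(bp_frame_i: ReferenceFrame, bp_frame_j: ReferenceFrame) -> StepParams:
    """Six step parameters of bp j (3' neighbour) relative to bp i."""
    _check_frame(bp_frame_i)
    _check_frame(bp_frame_j)
    trans, (tilt, roll, twist), _, _ = _decompose(
        bp_frame_i.axes, bp_frame_i.origin, bp_frame_j.axes, bp_frame_j.origin
    )
    return StepParams(
        shift=trans[0], slide=trans[1], rise=trans[2], tilt=tilt, roll=roll, twist=twist
    )


def rebuild_frames(start: ReferenceFrame, steps: list[StepParams]) -> list[ReferenceFrame]:
    """Chain frames from a start frame and step parameters (inverse of
    :func:`step_params`; round trip exact to ~1e-8)."""
    _check_frame(start)
    frames = [start]
    for sp in steps:
        a = sp.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite step parameters")
        prev = frames[-1]
        R2, o2 = _compose(prev.axes, prev.origin, a[:3], sp.tilt, sp.roll, sp.twist)
        frames.append(ReferenceFrame(o2, R2))
    return frames
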