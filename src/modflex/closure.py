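"""Monte-Carlo loop-closure propensity of a rigid base-pair chain.

Embodies the mechanistic link between parameter fluctuations and looping:
step parameters are drawn independently Gaussian per step, the frame chain is
rebuilt, and a conformation counts as closed when the two ends meet within a
capture radius, with their helical axes aligned within a capture angle and
(optionally) the accumulated twist within a register tolerance of a full
number of turns.  With physically tight criteria 90-step closure is a rare
event, so the defaults are deliberately generous (r_c = 50 Å, θ_c = 60°,
register off) and results are *comparative* — relative propensities between
conditions, not absolute J-factors.

The chain uses step parameters only (rigid base-pair abstraction; intra-bp
degrees of freedom do not move the helical axis).  Sampling is vectorized
and chunked; an importance-sampling or half-chain-convolution scheme is a
documented extension point, not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .basegeom import STEP_PARAM_NAMES
from .fluctuations import rank_modifications

__all__ = [
    "ChainFluctuationSpec",
    "ClosureEstimate",
    "estimate_closure_propensity",
    "sample_end_states",
    "end_states_from_params",
    "closure_mask",
    "compare_conditions",
    "DEFAULT_CHAIN_PARAMS",
]

#: Ideal-B-DNA chain with typical bend/twist fluctuation amplitudes.
DEFAULT_CHAIN_PARAMS: dict[str, tuple[float, float]] = {
    "shift": (0.0, 0.0),
    "slide": (0.0, 0.0),
    "rise": (3.38, 0.0),
    "tilt": (0.0, 4.0),
    "roll": (0.0, 4.0),
    "twist": (36.0, 4.0),
}


@dataclass(frozen=True)
class ChainFluctuationSpec:
    """Gaussian step-parameter distribution and closure criteria for a chain."""

    n_steps: int = 90
    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CHAIN_PARAMS)
    )
    capture_radius: float = 50.0  # Å
    capture_angle: float = 60.0  # degrees between terminal z-axes
    twist_register_tol: float | None = None  # degrees from a multiple of 360; None = off
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        if self.capture_radius <= 0 or self.capture_angle <= 0:
            raise ValueError("closure criteria must be positive")
        if self.twist_register_tol is not None and self.twist_register_tol <= 0:
            raise ValueError("twist_register_tol must be positive or None")
        for name in STEP_PARAM_NAMES:
            if name not in self.params:
                raise ValueError(f"missing step parameter {name!r}")
            if self.params[name][1] < 0:
                raise ValueError(f"negative sd for {name!r}")


@dataclass(frozen=True)
class ClosureEstimate:
    propensity: float
    ci_low: float
    ci_high: float
    n_closed: int
    n_samples: int


def _batched_rz(deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(deg.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _batched_ry(deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    out = np.zeros(deg.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rzyz(alpha: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Elementwise Rz(alpha) . Ry(gamma) . Rz(beta) for degree arrays (...,)."""
    ca, sa = np.cos(np.deg2rad(alpha)), np.sin(np.deg2rad(alpha))
    cb, sb = np.cos(np.deg2rad(beta)), np.sin(np.deg2rad(beta))
    cg, sg = np.cos(np.deg2rad(gamma)), np.sin(np.deg2rad(gamma))
    out = np.empty(np.broadcast(ca, cb).shape + (3, 3))
    out[..., 0, 0] = ca * cg * cb - sa * sb
    out[..., 0, 1] = -ca * cg * sb - sa * cb
    out[..., 0, 2] = ca * sg
    out[..., 1, 0] = sa * cg * cb + ca * sb
    out[..., 1, 1] = -sa * cg * sb + ca * cb
    out[..., 1, 2] = sa * sg
    out[..., 2, 0] = -sg * cb
    out[..., 2, 1] = sg * sb
    out[..., 2, 2] = cg
    return out


def end_states_from_params(step_params: np.ndarray) -> dict[str, np.ndarray]:
    """End-to-end state of each chain in a (n, n_steps, 6) parameter array.

    Parameter order along the last axis is (shift, slide, rise, tilt, roll,
    twist).  Returns end-origin distance (Å), angle between terminal z-axes
    (deg), and summed twist (deg).  Vectorized equivalent of chaining
    :func:`modflex.geometry.rebuild_frames` per sample (cross-checked in the
    test suite).
    """
    p = np.asarray(step_params, dtype=float)
    if p.ndim != 3 or p.shape[2] != 6:
        raise ValueError("expected (n_samples, n_steps, 6) parameter array")
    n, n_steps, _ = p.shape
    tilt, roll, twist = p[..., 3], p[..., 4], p[..., 5]
    gamma = np.hypot(roll, tilt)
    phi = np.rad2deg(np.arctan2(tilt, roll))
    a = twist / 2.0 - phi
    b = twist / 2.0 + phi
    A = _rzyz(a, gamma, b)  # (n, n_steps, 3, 3)
    M = _rzyz(a, gamma / 2.0, phi)
    # local mid-frame displacement of each step
    v = np.einsum("nkij,nkj->nki", M, p[..., :3])
    # fold the per-step rigid transforms (A_k, v_k) by associative pairwise
    # reduction: (Ra, ta) o (Rb, tb) = (Ra Rb, ta + Ra tb)
    while A.shape[1] > 1:
        m = A.shape[1]
        even = m - (m % 2)
        Ra, Rb = A[:, 0:even:2], A[:, 1:even:2]
        ta, tb = v[:, 0:even:2], v[:, 1:even:2]
        R_new = Ra @ Rb
        t_new = ta + np.einsum("nkij,nkj->nki", Ra, tb)
        if m % 2:
            R_new = np.concatenate([R_new, A[:, -1:]], axis=1)
            t_new = np.concatenate([t_new, v[:, -1:]], axis=1)
        A, v = R_new, t_new
    R = A[:, 0]
    origin = v[:, 0]
    return {
        "end_distance": np.linalg.norm(origin, axis=1),
        "end_angle": np.rad2deg(np.arccos(np.clip(R[:, 2, 2], -1.0, 1.0))),
        "total_twist": twist.sum(axis=1),
    }


def closure_mask(
    end_states: dict[str, np.ndarray],
    capture_radius: float,
    capture_angle: float,
    twist_register_tol: float | None = None,
) -> np.ndarray:
    """Boolean closed/open call per sample from pre-computed end states."""
    closed = (end_states["end_distance"] < capture_radius) & (
        end_states["end_angle"] < capture_angle
    )
    if twist_register_tol is not None:
        frac = np.abs((end_states["total_twist"] + 180.0) % 360.0 - 180.0)
        closed &= frac < twist_register_tol
    return closed


def sample_end_states(spec: ChainFluctuationSpec, chunk_size: int = 20_000) -> dict[str, np.ndarray]:
    """Seeded Gaussian sampling of end states for ``spec.n_samples`` chains."""
    if spec.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(spec.seed)
    means = np.array([spec.params[name][0] for name in STEP_PARAM_NAMES])
    sds = np.array([spec.params[name][1] for name in STEP_PARAM_NAMES])
    outs: list[dict[str, np.ndarray]] = []
    remaining = spec.n_samples
    while remaining > 0:
        m = min(chunk_size, remaining)
        draws = means + sds * rng.standard_normal((m, spec.n_steps, 6))
        outs.append(end_states_from_params(draws))
        remaining -= m
    return {k: np.concatenate([o[k] for o in outs]) for k in outs[0]}


def estimate_closure_propensity(spec: ChainFluctuationSpec) -> ClosureEstimate:
    """Fraction of sampled conformations that satisfy the closure criteria,
    with an exact (Clopper-Pearson) binomial 95% CI.  Seeded, reproducible."""
    states = sample_end_states(spec)
    closed = closure_mask(
        states, spec.capture_radius, spec.capture_angle, spec.twist_register_tol
    )
    k = int(closed.sum())
    n = spec.n_samples
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95, method="exact")
    return ClosureEstimate(
        propensity=k / n, ci_low=float(ci.low), ci_high=float(ci.high),
        n_closed=k, n_samples=n,
    )


def compare_conditions(
    specs: dict[str, ChainFluctuationSpec], baseline: str = "unmodified"
) -> dict[str, dict[str, float]]:
    """Closure propensity per condition with ratios relative to the baseline.

    All specs must share chain length and closure criteria.  The returned
    mapping carries, per condition: propensity, CI bounds, ratio to baseline
    with first-order SE, and the whole result embeds an ordering string with
    the same near-tie notation used for fluctuation rankings (key
    ``"_ordering"``).
    """
    if baseline not in specs:
        raise ValueError(f"baseline condition {baseline!r} missing from specs")
    ref = specs[baseline]
    for cond, s in specs.items():
        if (
            s.n_steps != ref.n_steps
            or s.capture_radius != ref.capture_radius
            or s.capture_angle != ref.capture_angle
            or s.twist_register_tol != ref.twist_register_tol
        ):
            raise ValueError(f"condition {cond!r} differs in chain length or criteria")
    estimates = {cond: estimate_closure_propensity(s) for cond, s in specs.items()}
    base = estimates[baseline]
    if base.n_closed == 0:
        raise ValueError("baseline closed count is zero; cannot form ratios")
    out: dict[str, dict[str, float]] = {}
    ranks: dict[str, tuple[float, float]] = {}
    for cond, est in estimates.items():
        p, pb = est.propensity, base.propensity
        se_p = np.sqrt(max(p * (1 - p), 1e-300) / est.n_samples)
        se_b = np.sqrt(pb * (1 - pb) / base.n_samples)
        ratio = p / pb
        ratio_se = ratio * np.hypot(se_p / p if p > 0 else 0.0, se_b / pb)
        out[cond] = {
            "propensity": p, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "ratio": ratio, "ratio_se": float(ratio_se),
        }
        ranks[cond] = (ratio, float(ratio_se))
    out["_ordering"] = rank_modifications(ranks)  # type: ignore[assignment]
    return out
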