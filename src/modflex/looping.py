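"""Single-molecule DNA cyclization (looping) kinetics.

A population of surface-tethered molecules starts unlooped (salt-jump start)
and each interconverts between unlooped and looped as a two-state Markov
chain with rates ``k_loop`` and ``k_unloop``.  The expected looped fraction
follows

    f(t) = f_eq * (1 - exp(-t / tau)),   f_eq = k_loop / (k_loop + k_unloop),
                                         tau  = 1 / (k_loop + k_unloop)

and the apparent looping time ``tau`` from an exponential fit of looped
fraction vs time is the operational flexibility measure: more flexible DNA
loops faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LoopingTimeCourse",
    "LoopingFit",
    "simulate_looping",
    "fit_looping",
    "fold_change",
    "default_sample_times",
    "read_time_course_tsv",
    "write_time_course_tsv",
]


@dataclass(frozen=True)
class LoopingTimeCourse:
    """Looped fraction vs time for a population of molecules."""

    times: np.ndarray  # s, strictly increasing
    looped_fraction: np.ndarray  # in [0, 1]
    n_molecules: int
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        frac = np.asarray(self.looped_fraction, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "looped_fraction", frac)
        if times.ndim != 1 or times.size != frac.size:
            raise ValueError("times and looped_fraction must be 1-D and equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((frac < 0) | (frac > 1)):
            raise ValueError("looped_fraction values must lie in [0, 1]")


@dataclass(frozen=True)
class LoopingFit:
    """Exponential-fit result: apparent looping time and plateau."""

    tau: float  # s
    f_eq: float
    tau_se: float
    f_eq_se: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.f_eq <= 1.0:
            raise ValueError("f_eq must lie in [0, 1]")


def default_sample_times(t_max: float, n_points: int = 25, t_min: float | None = None) -> np.ndarray:
    """Salt-jump-style grid: t=0 then log-spaced points up to ``t_max``."""
    if t_min is None:
        t_min = t_max / 1000.0
    return np.concatenate([[0.0], np.geomspace(t_min, t_max, n_points - 1)])


def simulate_looping(
    n_molecules: int,
    k_loop: float,
    k_unloop: float,
    sample_times: np.ndarray,
    seed: int = 0,
    condition: str = "",
    dropout_rate: float = 0.0,
) -> LoopingTimeCourse:
    """Two-state Markov simulation observed at the given sample times.

    State propagation between observations uses the exact two-state
    transition probabilities, so the sampling grid introduces no
    discretization error.  ``dropout_rate`` (1/s) optionally censors
    molecules (photobleaching-style); censored molecules leave the
    denominator.  All molecules start unlooped.
    """
    if k_loop <= 0 or k_unloop <= 0:
        raise ValueError("rates must be positive")
    sample_times = np.asarray(sample_times, dtype=float)
    rng = np.random.default_rng(seed)
    k_tot = k_loop + k_unloop
    f_eq = k_loop / k_tot
    looped = np.zeros(n_molecules, dtype=bool)
    alive = np.ones(n_molecules, dtype=bool)
    fractions = np.empty(sample_times.size)
    prev_t = 0.0
    for i, t in enumerate(sample_times):
        dt = t - prev_t
        if dt > 0:
            decay = np.exp(-k_tot * dt)
            p_looped = np.where(looped, f_eq + (1.0 - f_eq) * decay, f_eq * (1.0 - decay))
            looped = rng.random(n_molecules) < p_looped
            if dropout_rate > 0:
                alive &= rng.random(n_molecules) >= 1.0 - np.exp(-dropout_rate * dt)
        n_alive = int(alive.sum())
        fractions[i] = looped[alive].mean() if n_alive else np.nan
        prev_t = t
    return LoopingTimeCourse(
        times=sample_times, looped_fraction=fractions, n_molecules=n_molecules,
        condition=condition,
    )


def _model(t, f_eq, tau):
    return f_eq * (1.0 - np.exp(-t / tau))


def _lsq_fit(t, y, tau0, f0, fix_plateau):
    if fix_plateau is not None:
        popt, pcov = curve_fit(
            lambda tt, tau: _model(tt, fix_plateau, tau), t, y, p0=[tau0],
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        return float(fix_plateau), float(popt[0]), 0.0, float(np.sqrt(pcov[0, 0]))
    popt, pcov = curve_fit(
        _model, t, y, p0=[f0, tau0],
        bounds=([0.0, 1e-12], [1.0, np.inf]), maxfev=10000,
    )
    ses = np.sqrt(np.diag(pcov))
    return float(popt[0]), float(popt[1]), float(ses[0]), float(ses[1])


def fit_looping(
    tc: LoopingTimeCourse,
    fix_plateau: float | None = None,
    se_method: str = "bootstrap",
    n_bootstrap: int = 200,
    bootstrap_seed: int = 0,
) -> LoopingFit:
    """Least-squares exponential fit of the looped fraction vs time.

    The plateau floats by default; ``fix_plateau`` pins it (e.g. at the
    observed equilibrium) and fits only the looping time.  The fit itself is
    unweighted least squares.

    Standard errors: because the same molecules are followed through time,
    the fractions at successive sample times are strongly correlated and the
    naive least-squares covariance badly understates the uncertainty.  The
    default ``se_method="bootstrap"`` therefore re-simulates ``n_bootstrap``
    populations of ``tc.n_molecules`` two-state molecules at the fitted
    rates, refits each, and reports the spread (parametric bootstrap);
    ``se_method="lsq"`` gives the naive curve-fit errors.
    """
    if se_method not in ("bootstrap", "lsq"):
        raise ValueError("se_method must be 'bootstrap' or 'lsq'")
    t = tc.times
    y = tc.looped_fraction
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    f0 = min(max(float(y[-1]), 1e-3), 1.0)
    # crude tau guess: first time the curve passes 63% of its plateau
    above = np.flatnonzero(y >= 0.632 * f0)
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1] / 3.0)
    try:
        f_eq, tau, f_eq_se, tau_se = _lsq_fit(t, y, tau0, f0, fix_plateau)
    except RuntimeError as exc:
        raise RuntimeError(f"looping fit did not converge: {exc}") from exc
    if se_method == "bootstrap" and tc.n_molecules > 1:
        k_tot = 1.0 / tau
        k_loop = np.clip(f_eq, 1e-9, 1 - 1e-9) * k_tot
        k_unloop = k_tot - k_loop
        taus, feqs = [], []
        for b in range(n_bootstrap):
            sim = simulate_looping(
                tc.n_molecules, k_loop, k_unloop, t, seed=bootstrap_seed + b
            )
            try:
                fb, tb, _, _ = _lsq_fit(t, sim.looped_fraction, tau, f_eq, fix_plateau)
            except RuntimeError:
                continue
            taus.append(tb)
            feqs.append(fb)
        if len(taus) >= max(10, n_bootstrap // 2):
            tau_se = float(np.std(taus, ddof=1))
            if fix_plateau is None:
                f_eq_se = float(np.std(feqs, ddof=1))
    resid = y - _model(t, f_eq, tau)
    return LoopingFit(
        tau=tau, f_eq=f_eq, tau_se=tau_se, f_eq_se=f_eq_se,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fold_change(fit_a: LoopingFit, fit_b: LoopingFit) -> tuple[float, float]:
    """tau_a / tau_b with first-order propagated standard error."""
    if fit_b.tau <= 0:
        raise ValueError("denominator tau must be positive")
    ratio = fit_a.tau / fit_b.tau
    se = abs(ratio) * np.hypot(fit_a.tau_se / fit_a.tau, fit_b.tau_se / fit_b.tau)
    return float(ratio), float(se)


def write_time_course_tsv(path: str | Path, tc: LoopingTimeCourse) -> None:
    df = pd.DataFrame(
        {"time_s": tc.times, "looped_fraction": tc.looped_fraction,
         "n_molecules": tc.n_molecules}
    )
    with open(path, "w") as fh:
        fh.write(f"# condition={tc.condition}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_time_course_tsv(path: str | Path) -> LoopingTimeCourse:
    condition = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "condition=" in first:
            condition = first.split("condition=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return LoopingTimeCourse(
        times=df["time_s"].to_numpy(),
        looped_fraction=df["looped_fraction"].to_numpy(),
        n_molecules=int(df["n_molecules"].iloc[0]),
        condition=condition,
    )
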