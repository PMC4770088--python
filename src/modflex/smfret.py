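"""smFRET nucleosome force-spectroscopy: efficiencies, histograms, stretching
traces and unwrapping-behaviour classification.

FRET efficiency is the ratiometric E = IA / (IA + γ·ID) with a detection
correction factor γ (default 1).  Stretching traces — FRET efficiency vs a
monotonically increasing applied force — are classified into three exhaustive
unwrapping behaviours:

* ``high_force_drop``: stable high FRET until a sudden drop at high force
  (~15 pN), the signature of an intact outer wrap releasing late;
* ``gradual_then_drop``: an additional gradual FRET decline before the final
  high-force drop (progressive end peeling);
* ``low_force_drop``: the major FRET drop already in the low force range
  (~5 pN), an end that releases early.

The classifier is a change-point rule: locate the largest windowed FRET
decrease along the force axis; a drop below the low/high force boundary
(default 8 pN, midway between the ~5 and ~15 pN landmarks) is a
``low_force_drop``; otherwise the pre-drop segment's fitted slope decides
between ``gradual_then_drop`` and ``high_force_drop``.  The rule is this
package's operationalization — classification is differential, so adding a
constant to all FRET values never changes the call.  Only the stretch
segment of a pull is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "TRACE_CLASSES",
    "FretRecord",
    "StretchTrace",
    "UnclassifiableTraceError",
    "fret_efficiency",
    "fit_fret_histogram",
    "simulate_stretch_traces",
    "classify_trace",
    "average_traces",
    "class_percentages",
    "read_traces_tsv",
    "write_traces_tsv",
]

TRACE_CLASSES = ("high_force_drop", "gradual_then_drop", "low_force_drop")

FORCE_MIN_PN = 0.4
FORCE_MAX_PN = 30.0


@dataclass(frozen=True)
class FretRecord:
    """One donor/acceptor intensity pair with detection correction γ."""

    donor_intensity: float
    acceptor_intensity: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.donor_intensity < 0 or self.acceptor_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class StretchTrace:
    """FRET efficiency vs applied force for one nucleosome pull (stretch
    segment; 20 ms dwell per point by default)."""

    force: np.ndarray  # pN, non-decreasing
    fret: np.ndarray  # [0, 1]
    molecule_id: str = ""
    condition: str = ""
    dwell_ms: float = 20.0

    def __post_init__(self) -> None:
        force = np.asarray(self.force, dtype=float)
        fret = np.asarray(self.fret, dtype=float)
        object.__setattr__(self, "force", force)
        object.__setattr__(self, "fret", fret)
        if force.size != fret.size:
            raise ValueError("force and fret must have equal length")
        if np.any(np.diff(force) < 0):
            raise ValueError("force must be non-decreasing in the stretch segment")
        if np.any((force < FORCE_MIN_PN) | (force > FORCE_MAX_PN)):
            raise ValueError(f"forces outside instrument range [{FORCE_MIN_PN}, {FORCE_MAX_PN}] pN")
        if np.any((fret < 0) | (fret > 1)):
            raise ValueError("FRET efficiencies must lie in [0, 1]")


class UnclassifiableTraceError(ValueError):
    """Raised when a trace shows no detectable FRET drop."""


def fret_efficiency(record: FretRecord) -> float:
    """Ratiometric efficiency E = IA / (IA + γ·ID)."""
    total = record.acceptor_intensity + record.gamma * record.donor_intensity
    if total <= 0:
        raise ValueError("zero total intensity")
    return record.acceptor_intensity / total


def _gauss_sum(x, *params):
    y = np.zeros_like(x)
    for amp, mu, sigma in zip(params[0::3], params[1::3], params[2::3]):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return y


def fit_fret_histogram(
    efficiencies: np.ndarray, n_bins: int = 40, n_components: int = 1
) -> dict[str, float]:
    """Gaussian fit to the binned efficiency histogram.

    Returns the fitted peak mean with its standard error and the fitted
    width; with ``n_components > 1`` a sum of Gaussians is fitted and the
    dominant (largest-amplitude) component is reported.
    """
    e = np.asarray(efficiencies, dtype=float).ravel()
    if e.size < 100:
        raise ValueError("need at least 100 efficiency values")
    if np.ptp(e) <= 0:
        raise ValueError("degenerate input: all efficiency values identical")
    counts, edges = np.histogram(e, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = []
    for i in range(n_components):
        q = np.quantile(e, (i + 0.5) / n_components)
        p0 += [counts.max() / (i + 1), q, max(e.std(), 1e-3)]
    try:
        popt, pcov = curve_fit(_gauss_sum, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"histogram fit did not converge: {exc}") from exc
    amps = popt[0::3]
    k = int(np.argmax(np.abs(amps)))
    return {
        "mean": float(popt[3 * k + 1]),
        "mean_se": float(np.sqrt(pcov[3 * k + 1, 3 * k + 1])),
        "width": float(abs(popt[3 * k + 2])),
        "amplitude": float(popt[3 * k]),
    }


_E_HIGH = 0.8
_E_LOW = 0.1
_SIGMOID_WIDTH_PN = 0.8
_GRADUAL_SLOPE = 0.015  # E per pN, generative decline of the gradual class


def simulate_stretch_traces(
    n_traces: int,
    class_mix: tuple[float, float, float],
    drop_force_low: float = 5.0,
    drop_force_high: float = 15.0,
    noise_sd: float = 0.05,
    force_grid: np.ndarray | None = None,
    seed: int = 0,
    condition: str = "",
) -> list[StretchTrace]:
    """Generate stretching traces with the three unwrapping behaviours.

    ``class_mix`` gives (high_force_drop, gradual_then_drop, low_force_drop)
    proportions and must sum to 1.  Drops are sigmoidal in force; the
    gradual class adds a linear decline before its final drop; per-point
    Gaussian noise is clipped into [0, 1].  The generated class is recorded
    in each trace's ``molecule_id`` ("<class>:<index>").
    """
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != len(TRACE_CLASSES) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix must be 3 non-negative proportions summing to 1")
    if force_grid is None:
        force_grid = np.linspace(FORCE_MIN_PN, FORCE_MAX_PN, 150)
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(TRACE_CLASSES), size=n_traces, p=mix)
    traces = []
    for i, lab in enumerate(labels):
        cls = TRACE_CLASSES[lab]
        centre = drop_force_low if cls == "low_force_drop" else drop_force_high
        drop = 1.0 / (1.0 + np.exp((force_grid - centre) / _SIGMOID_WIDTH_PN))
        fret = _E_LOW + (_E_HIGH - _E_LOW) * drop
        if cls == "gradual_then_drop":
            fret = fret - _GRADUAL_SLOPE * (force_grid - force_grid[0]) * drop
        if noise_sd > 0:
            fret = fret + rng.normal(0.0, noise_sd, force_grid.size)
        traces.append(
            StretchTrace(
                force=force_grid,
                fret=np.clip(fret, 0.0, 1.0),
                molecule_id=f"{cls}:{i}",
                condition=condition,
            )
        )
    return traces


def _windowed_drop(force: np.ndarray, fret: np.ndarray, window_pn: float):
    """Largest mean-FRET decrease across a sliding force boundary.

    For each interior point, compares the mean FRET within ``window_pn``
    before vs after; returns (drop size, force at the maximum).
    """
    best_drop, best_force = -np.inf, None
    for i in range(1, force.size):
        f = force[i]
        pre = fret[(force >= f - window_pn) & (force < f)]
        post = fret[(force >= f) & (force < f + window_pn)]
        if pre.size == 0 or post.size == 0:
            continue
        drop = pre.mean() - post.mean()
        if drop > best_drop:
            best_drop, best_force = drop, f
    return best_drop, best_force


def classify_trace(
    trace: StretchTrace,
    force_boundary: float = 8.0,
    gradual_slope_threshold: float = 0.006,
    window_pn: float = 2.0,
    min_drop: float = 0.15,
) -> str:
    """Assign one of the three unwrapping behaviours to a stretch trace.

    Change-point by maximum windowed FRET decrease; drop force below
    ``force_boundary`` → ``low_force_drop``; otherwise the pre-drop
    segment's fitted slope (E per pN) below ``-gradual_slope_threshold`` →
    ``gradual_then_drop``, else ``high_force_drop``.
    """
    if trace.force.size < 10:
        raise ValueError("need at least 10 points to classify")
    if not (trace.force[0] < force_boundary < trace.force[-1]):
        raise ValueError("force range must span the low/high boundary")
    drop, drop_force = _windowed_drop(trace.force, trace.fret, window_pn)
    if drop_force is None or drop < min_drop:
        raise UnclassifiableTraceError(
            f"no FRET drop above {min_drop} detected (largest {drop:.3f})"
        )
    if drop_force < force_boundary:
        return "low_force_drop"
    pre_mask = trace.force < drop_force - window_pn
    if pre_mask.sum() >= 3:
        fit = linregress(trace.force[pre_mask], trace.fret[pre_mask])
        if fit.slope < -gradual_slope_threshold:
            return "gradual_then_drop"
    return "high_force_drop"


def average_traces(
    traces: list[StretchTrace], force_bins: np.ndarray
) -> pd.DataFrame:
    """Mean FRET vs force with per-bin SE over traces.

    Each trace contributes its own within-bin mean once, so molecules are
    the unit of averaging.  Bins covered by fewer than 2 traces are flagged
    (``flag`` column), never silently dropped.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    force_bins = np.asarray(force_bins, dtype=float)
    n_bins = force_bins.size - 1
    per_trace = np.full((len(traces), n_bins), np.nan)
    for i, tr in enumerate(traces):
        idx = np.digitize(tr.force, force_bins) - 1
        for b in range(n_bins):
            sel = idx == b
            if np.any(sel):
                per_trace[i, b] = tr.fret[sel].mean()
    n_per_bin = np.sum(~np.isnan(per_trace), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_trace, axis=0)
        sd = np.nanstd(per_trace, axis=0, ddof=1)
    se = np.where(n_per_bin > 1, sd / np.sqrt(np.maximum(n_per_bin, 1)), np.nan)
    return pd.DataFrame(
        {
            "force_low": force_bins[:-1],
            "force_high": force_bins[1:],
            "mean_fret": mean,
            "se": se,
            "n_traces": n_per_bin,
            "flag": np.where(n_per_bin < 2, "insufficient_coverage", "ok"),
        }
    )


def class_percentages(counts: dict[str, int], decimals: int = 1) -> dict[str, float]:
    """Percent of traces per class, rounded half-away-from-zero.

    ``decimals=1`` reproduces "21.2% (7 of 33)" styling; ``decimals=0`` the
    "61% (14 of 23)" styling.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    quant = Decimal(1).scaleb(-decimals)
    out = {}
    for cls, c in counts.items():
        pct = Decimal(100 * c) / Decimal(total)
        out[cls] = float(pct.quantize(quant, rounding=ROUND_HALF_UP))
    return out


def write_traces_tsv(path: str | Path, traces: list[StretchTrace]) -> None:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {"molecule_id": tr.molecule_id, "force_pN": tr.force, "fret": tr.fret,
                 "condition": tr.condition}
            )
        )
    with open(path, "w") as fh:
        fh.write("# stretch-segment traces; force in pN, fret is ratiometric efficiency\n")
        pd.concat(rows, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_traces_tsv(path: str | Path) -> list[StretchTrace]:
    df = pd.read_csv(path, sep="\t", comment="#")
    traces = []
    for mol, sub in df.groupby("molecule_id", sort=False):
        cond = str(sub["condition"].iloc[0]) if "condition" in sub else ""
        traces.append(
            StretchTrace(
                force=sub["force_pN"].to_numpy(),
                fret=sub["fret"].to_numpy(),
                molecule_id=str(mol),
                condition=cond,
            )
        )
    return traces
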