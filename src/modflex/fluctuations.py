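"""Per-position fluctuation statistics of rigid base-pair parameters.

Summaries treat each (position, parameter) series as Gaussian — the fit is by
sample moments, which is the maximum-likelihood Gaussian fit and needs no
binning — with standard errors from block averaging: a fixed-length block
(default 20 ns) is treated as one independent measurement, which keeps the
errors honest when the series is autocorrelated.  Differences between
modified and unmodified ensembles are combined with the conventional
quadrature error-propagation rule.  Profiles are reported against the signed
bp distance from the centre of a CpG step and pooled over steps; no
multiplicity correction is applied (the profiles are descriptive, not
hypothesis tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basegeom import STEP_PARAM_NAMES
from .ensemble import ParameterEnsemble, _distance_to_step

__all__ = [
    "GaussianSummary",
    "DeltaProfile",
    "gaussian_summary",
    "propagate_difference_se",
    "delta_profile",
    "window_average_delta_sd",
    "rank_modifications",
    "display_label",
]


@dataclass(frozen=True)
class GaussianSummary:
    """Sample mean and s.d. with block-averaged standard errors."""

    mean: float
    sd: float
    n: int
    se_mean: float
    se_sd: float


@dataclass(frozen=True)
class DeltaProfile:
    """Change in mean and s.d. vs distance from the CpG-step centre.

    Values are averages over the pooled CpG steps; standard errors are
    propagated per position and then combined by the same pooling.
    """

    parameter_name: str
    distances: np.ndarray
    dmean: np.ndarray
    dmean_se: np.ndarray
    dsd: np.ndarray
    dsd_se: np.ndarray
    n_cpg_steps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter_name": self.parameter_name,
                "distance_bp": self.distances,
                "delta_mean": self.dmean,
                "delta_mean_se": self.dmean_se,
                "delta_sd": self.dsd,
                "delta_sd_se": self.dsd_se,
                "n_cpg_steps": self.n_cpg_steps,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# distance_bp measured from the CpG-step centre; bp positions are\n")
            fh.write("# binned to integers by rounding toward zero (both central pairs -> 0)\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def gaussian_summary(
    series: np.ndarray, frame_interval_ps: float, block_length_ns: float = 20.0
) -> GaussianSummary:
    """Moments of one parameter series with block-averaged standard errors.

    ``se_mean`` is the s.d. of per-block means over √M for M complete blocks
    (incomplete trailing block discarded); ``se_sd`` is the analogue over
    per-block s.d.s.  Errors if fewer than 2 complete blocks fit — block
    length is never silently shrunk.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    per_block = int(block_length_ns * 1000.0 / frame_interval_ps)
    if per_block < 1:
        raise ValueError("block length shorter than one frame interval")
    m = n // per_block
    if m < 2:
        raise ValueError(
            f"series of {n} frames holds {m} complete {block_length_ns}-ns blocks; >=2 required"
        )
    mean = float(series.mean())
    sd = float(series.std(ddof=1)) if n > 1 else 0.0
    blocks = series[: m * per_block].reshape(m, per_block)
    block_means = blocks.mean(axis=1)
    block_sds = blocks.std(axis=1, ddof=1)
    se_mean = float(block_means.std(ddof=1) / np.sqrt(m))
    se_sd = float(block_sds.std(ddof=1) / np.sqrt(m))
    return GaussianSummary(mean=mean, sd=sd, n=n, se_mean=se_mean, se_sd=se_sd)


def propagate_difference_se(se_a: float, se_b: float) -> float:
    """Standard error of a difference: √(se_a² + se_b²)."""
    if se_a < 0 or se_b < 0:
        raise ValueError("standard errors must be non-negative")
    return float(np.hypot(se_a, se_b))


def delta_profile(
    modified: ParameterEnsemble,
    unmodified: ParameterEnsemble,
    parameter_name: str,
    cpg_steps: list[int],
    block_length_ns: float = 20.0,
    max_distance: int = 3,
) -> DeltaProfile:
    """Δmean and Δsd of one parameter vs distance from the CpG-step centre.

    For every pooled CpG step and distance bin, the per-position (modified −
    unmodified) difference is formed with quadrature-propagated SEs, then
    averaged over all contributing positions.  Swapping the two ensembles
    negates the profile exactly.
    """
    if modified.frame_interval_ps != unmodified.frame_interval_ps:
        raise ValueError("ensembles have different frame intervals")
    is_step = parameter_name in STEP_PARAM_NAMES
    positions = modified.positions_for(parameter_name)
    if not np.array_equal(positions, unmodified.positions_for(parameter_name)):
        raise ValueError("ensembles cover different positions")
    pos_set = set(int(p) for p in positions)
    distances = np.arange(-max_distance, max_distance + 1)
    # distance bin -> contributing positions over all pooled steps
    bins: dict[int, list[int]] = {int(d): [] for d in distances}
    missing = []
    for step in cpg_steps:
        lo = step - max_distance
        hi = step + max_distance + (0 if is_step else 1)
        for p in range(lo, hi + 1):
            if p not in pos_set:
                missing.append(p)
            else:
                bins[_distance_to_step(p, step, is_step)].append(p)
    if missing:
        raise ValueError(f"positions missing from ensembles: {sorted(set(missing))}")

    summaries_mod = {}
    summaries_un = {}
    needed = sorted({p for ps in bins.values() for p in ps})
    for p in needed:
        summaries_mod[p] = gaussian_summary(
            modified.series(p, parameter_name), modified.frame_interval_ps, block_length_ns
        )
        summaries_un[p] = gaussian_summary(
            unmodified.series(p, parameter_name), unmodified.frame_interval_ps, block_length_ns
        )
    dmean = np.empty(distances.size)
    dmean_se = np.empty(distances.size)
    dsd = np.empty(distances.size)
    dsd_se = np.empty(distances.size)
    for i, d in enumerate(distances):
        ps = bins[int(d)]
        k = len(ps)
        dm = [summaries_mod[p].mean - summaries_un[p].mean for p in ps]
        dm_se = [
            propagate_difference_se(summaries_mod[p].se_mean, summaries_un[p].se_mean)
            for p in ps
        ]
        ds = [summaries_mod[p].sd - summaries_un[p].sd for p in ps]
        ds_se = [
            propagate_difference_se(summaries_mod[p].se_sd, summaries_un[p].se_sd) for p in ps
        ]
        dmean[i] = np.mean(dm)
        dsd[i] = np.mean(ds)
        dmean_se[i] = np.sqrt(np.sum(np.square(dm_se))) / k
        dsd_se[i] = np.sqrt(np.sum(np.square(ds_se))) / k
    return DeltaProfile(
        parameter_name=parameter_name,
        distances=distances,
        dmean=dmean,
        dmean_se=dmean_se,
        dsd=dsd,
        dsd_se=dsd_se,
        n_cpg_steps=len(cpg_steps),
    )


def window_average_delta_sd(profile: DeltaProfile, window_bp: int = 3) -> tuple[float, float]:
    """Δsd averaged over a window of *window_bp* distance bins centred at the
    CpG step, with propagated SE."""
    half = window_bp // 2
    wanted = np.arange(-half, half + 1)
    idx = []
    for d in wanted:
        hits = np.flatnonzero(profile.distances == d)
        if hits.size == 0:
            raise ValueError(f"window distance {d} not covered by profile")
        idx.append(hits[0])
    vals = profile.dsd[idx]
    ses = profile.dsd_se[idx]
    return float(vals.mean()), float(np.sqrt(np.sum(ses**2)) / len(idx))


_DISPLAY = {
    "unmodified": "unmodified C",
    "5mC": "5-mC",
    "5hmC": "5-hmC",
    "5fC": "5-fC",
    "5caC": "5-caC",
}


def display_label(condition: str) -> str:
    return _DISPLAY.get(condition, condition)


def rank_modifications(
    window_averages: dict[str, tuple[float, float]], tie_threshold: float = 1.0
) -> str:
    """Order conditions by their window-averaged Δsd, descending.

    Adjacent conditions whose point estimates differ by less than
    ``tie_threshold`` propagated SEs are joined with "≳" (order within such a
    near-tie is not resolved by the data); clear separations use ">".  The
    result is independent of the order in which conditions are supplied.
    """
    if len(window_averages) < 2:
        raise ValueError("need at least two conditions to rank")
    for cond, (v, se) in window_averages.items():
        if not np.isfinite(v) or not np.isfinite(se):
            raise ValueError(f"non-finite input for condition {cond!r}")
    items = sorted(window_averages.items(), key=lambda kv: (-kv[1][0], kv[0]))
    parts = [display_label(items[0][0])]
    for (_, (va, sa)), (cond_b, (vb, sb)) in zip(items, items[1:]):
        sep = "≳" if (va - vb) < tie_threshold * propagate_difference_se(sa, sb) else ">"
        parts.append(sep)
        parts.append(display_label(cond_b))
    return "".join(parts)
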