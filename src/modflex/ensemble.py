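"""MD-surrogate conformational ensembles of modified DNA.

Generates per-position Gaussian fluctuations of the 12 rigid base-pair
parameters around B-DNA baselines, with modification-dependent shifts of mean
and s.d. localized at annotated CpG steps and decaying linearly over the
neighbouring base pairs, and realizes ensembles as 3-D coordinates (multi-model
PDB) so the extraction pipeline can be exercised end-to-end.

The generator emulates the *statistical* structure of an MD ensemble — Gaussian
instantaneous parameter distributions — not its physics: by default samples are
i.i.d. across frames (an optional AR(1) mode adds a configurable correlation
time so block averaging has something to do), and parameters are independent
across positions and parameter types.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .basegeom import (
    ALL_PARAM_NAMES,
    INTRA_PARAM_NAMES,
    MOD_TYPES,
    STEP_PARAM_NAMES,
    standard_atoms,
)
from .constructs import ModifiedDuplex, apply_modifications, find_cpg_sites
from .geometry import (
    IntraBpParams,
    ReferenceFrame,
    StepParams,
    base_frames_from_pair,
    base_pair_frame,
    fit_base_frame,
    rebuild_frames,
    step_params,
)

__all__ = [
    "DEFAULT_BASELINE",
    "DEFAULT_EFFECT_SCALES",
    "DEFAULT_KERNEL",
    "EnsembleSpec",
    "ParameterEnsemble",
    "generate_parameter_ensemble",
    "realize_coordinates",
    "extract_parameters",
    "condition_suite",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
]

SD_FLOOR = 1e-6

#: Baseline B-DNA (mean, sd) per parameter: twist 36 deg, rise 3.38 Å, other
#: means 0; sds typical of B-DNA simulations (4-5 deg angles, 0.3-0.7 Å
#: translations).  Exposed so calibrations can be swapped wholesale.
DEFAULT_BASELINE: dict[str, tuple[float, float]] = {
    "shift": (0.0, 0.5),
    "slide": (0.0, 0.5),
    "rise": (3.38, 0.3),
    "tilt": (0.0, 4.0),
    "roll": (0.0, 5.0),
    "twist": (36.0, 4.5),
    "shear": (0.0, 0.3),
    "stretch": (0.0, 0.3),
    "stagger": (0.0, 0.4),
    "buckle": (0.0, 5.0),
    "propeller": (0.0, 5.0),
    "opening": (0.0, 4.0),
}

#: Synthetic calibration of modification effects: a single Δsd scale per
#: modification (degrees at the CpG-step centre for angular parameters;
#: translations get 0.06 Å per degree-unit).  The ordering — 5fC largest
#: positive, 5hmC slightly above 5caC slightly above unmodified, 5mC
#: negative — mirrors the qualitative flexibility ranking; the magnitudes are
#: this package's own calibration, not measured values.
DEFAULT_EFFECT_SCALES: dict[str, float] = {
    "5fC": 1.0,
    "5hmC": 0.10,
    "5caC": 0.07,
    "5mC": -0.8,
}
_TRANSLATION_SCALE = 0.06  # Å of Δsd per degree-unit of effect scale
_TRANSLATIONS = ("shift", "slide", "rise", "shear", "stretch", "stagger")

#: Kernel weight vs distance (bp) from the CpG-step centre: linear decay to 0
#: at |d| = 3, so a modification touches up to ~6 neighbouring base pairs.
DEFAULT_KERNEL: dict[int, float] = {d: max(0.0, 1.0 - abs(d) / 3.0) for d in range(-3, 4)}


def default_effects(mod_type: str) -> dict[str, tuple[float, float]]:
    """(Δmean, Δsd) at the CpG centre per parameter for *mod_type*."""
    scale = DEFAULT_EFFECT_SCALES[mod_type]
    out = {}
    for name in ALL_PARAM_NAMES:
        dsd = scale * (_TRANSLATION_SCALE if name in _TRANSLATIONS else 1.0)
        out[name] = (0.0, dsd)
    return out


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic parameter ensemble.

    ``effects`` maps mod_type -> parameter -> (Δmean, Δsd) applied at the
    centre of each annotated CpG step and spread by ``neighbour_kernel``.
    ``ar1_tau_frames`` switches the sampler from i.i.d. to AR(1) with that
    correlation time (in frames).
    """

    duplex: ModifiedDuplex
    n_frames: int
    frame_interval_ps: float = 4.8
    baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {m: default_effects(m) for m in MOD_TYPES}
    )
    neighbour_kernel: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_KERNEL))
    seed: int = 0
    parameters: tuple[str, ...] | None = None  # None = all 12
    ar1_tau_frames: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name, (_, sd) in self.baseline.items():
            if sd < 0:
                raise ValueError(f"negative baseline sd for {name}")
        if self.neighbour_kernel.get(0, None) != 1.0:
            raise ValueError("neighbour kernel must have weight 1 at d=0")
        for d, w in self.neighbour_kernel.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"kernel weight at d={d} outside [0, 1]")
        if self.parameters is not None:
            unknown = set(self.parameters) - set(ALL_PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown parameters: {sorted(unknown)}")

    def param_names(self) -> tuple[str, ...]:
        return tuple(self.parameters) if self.parameters is not None else ALL_PARAM_NAMES

    def spec_hash(self) -> str:
        payload = repr(
            (
                self.duplex.top,
                tuple((a.position, a.strand, a.mod_type) for a in self.duplex.annotations),
                self.n_frames,
                self.frame_interval_ps,
                sorted(self.baseline.items()),
                sorted((m, sorted(e.items())) for m, e in self.effects.items()),
                sorted(self.neighbour_kernel.items()),
                self.seed,
                self.parameters,
                self.ar1_tau_frames,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ParameterEnsemble:
    """Per-position, per-parameter value series over frames.

    ``values[name]`` has shape (n_sites, n_frames); step parameters live on
    step positions 1..L-1 (step s sits between bp s and s+1), intra-bp
    parameters on bp positions 1..L.
    """

    values: dict[str, np.ndarray]
    bp_positions: np.ndarray
    step_positions: np.ndarray
    frame_interval_ps: float
    condition: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        n_frames = {v.shape[1] for v in self.values.values()}
        if len(n_frames) > 1:
            raise ValueError("all parameter arrays must share the frame count")
        for name, arr in self.values.items():
            expected = len(self.step_positions if name in STEP_PARAM_NAMES else self.bp_positions)
            if arr.shape[0] != expected:
                raise ValueError(f"{name}: {arr.shape[0]} sites, expected {expected}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.values.values())).shape[1]

    def positions_for(self, parameter_name: str) -> np.ndarray:
        return self.step_positions if parameter_name in STEP_PARAM_NAMES else self.bp_positions

    def series(self, position: int, parameter_name: str) -> np.ndarray:
        pos = self.positions_for(parameter_name)
        idx = np.flatnonzero(pos == position)
        if idx.size == 0:
            raise KeyError(f"no {parameter_name} series at position {position}")
        return self.values[parameter_name][idx[0]]

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV (frame_index, position, parameter_name, value).

        Positions are 1-based; header comments carry condition, seed and the
        frame interval.
        """
        frames = []
        for name, arr in self.values.items():
            pos = self.positions_for(name)
            n_sites, n_frames = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "frame_index": np.tile(np.arange(n_frames), n_sites),
                        "position": np.repeat(pos, n_frames),
                        "parameter_name": name,
                        "value": arr.ravel(),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        with open(path, "w") as fh:
            fh.write("# positions 1-based; step parameters indexed by their 5' base pair\n")
            fh.write(f"# condition={self.condition} seed={self.seed} "
                     f"frame_interval_ps={self.frame_interval_ps}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParameterEnsemble":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        values: dict[str, np.ndarray] = {}
        bp_pos: np.ndarray | None = None
        step_pos: np.ndarray | None = None
        for name, sub in df.groupby("parameter_name"):
            piv = sub.pivot(index="position", columns="frame_index", values="value")
            arr = piv.to_numpy()
            pos = piv.index.to_numpy()
            values[str(name)] = arr
            if name in STEP_PARAM_NAMES:
                step_pos = pos
            else:
                bp_pos = pos
        if bp_pos is None:
            bp_pos = (np.append(step_pos, step_pos[-1] + 1) if step_pos is not None
                      else np.array([], dtype=int))
        if step_pos is None:
            step_pos = bp_pos[:-1]
        seed = meta.get("seed")
        return cls(
            values=values,
            bp_positions=bp_pos,
            step_positions=step_pos,
            frame_interval_ps=float(meta.get("frame_interval_ps", 4.8)),
            condition=meta.get("condition", ""),
            seed=None if seed in (None, "None") else int(seed),
        )


# ---------------------------------------------------------------------------
# Generation

def _modified_steps(duplex: ModifiedDuplex) -> list[tuple[int, str]]:
    """(top-strand CpG step position, mod_type) for each annotated step."""
    cpg = set(find_cpg_sites(duplex.top))
    return sorted(
        {(a.position, a.mod_type) for a in duplex.annotations
         if a.strand == "top" and a.position in cpg}
    )


def _distance_to_step(site: int, step: int, is_step_param: bool) -> int:
    """Signed bp distance of a site from the centre of the CpG step at *step*.

    The step centre lies between bp ``step`` and ``step + 1``; base-pair
    positions map to integer distances by rounding toward zero, so both
    central pairs land in the d=0 bin.  Step-parameter sites use plain integer
    offsets from the central step.
    """
    if is_step_param:
        return site - step
    return site - step if site <= step else site - step - 1


def _moment_fields(spec: EnsembleSpec) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-site mean and sd arrays for every requested parameter."""
    L = len(spec.duplex)
    mod_steps = _modified_steps(spec.duplex)
    means: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    floored = False
    for name in spec.param_names():
        is_step = name in STEP_PARAM_NAMES
        sites = np.arange(1, L) if is_step else np.arange(1, L + 1)
        base_mean, base_sd = spec.baseline[name]
        mean = np.full(sites.shape, base_mean, dtype=float)
        sd = np.full(sites.shape, base_sd, dtype=float)
        for step, mod in mod_steps:
            dmean, dsd = spec.effects.get(mod, {}).get(name, (0.0, 0.0))
            for i, s in enumerate(sites):
                w = spec.neighbour_kernel.get(_distance_to_step(int(s), step, is_step), 0.0)
                if w:
                    mean[i] += w * dmean
                    sd[i] += w * dsd
        if np.any(sd < 0):
            # only effects can drive sd negative (baseline sds are validated
            # >= 0); zero stays zero so degenerate generators are exact
            floored = True
            sd = np.where(sd < 0, SD_FLOOR, sd)
        means[name] = mean
        sds[name] = sd
    if floored:
        import warnings

        warnings.warn("effect produced sd below floor; floored at 1e-6", stacklevel=3)
    return means, sds


def generate_parameter_ensemble(spec: EnsembleSpec) -> ParameterEnsemble:
    """Sample a Gaussian parameter ensemble per the spec (seeded, reproducible).

    Each (position, parameter) series is Gaussian with mean and s.d. equal to
    the baseline plus kernel-weighted modification effects summed over
    annotated CpG steps.
    """
    rng = np.random.default_rng(spec.seed)
    means, sds = _moment_fields(spec)
    L = len(spec.duplex)
    values: dict[str, np.ndarray] = {}
    phi = np.exp(-1.0 / spec.ar1_tau_frames) if spec.ar1_tau_frames else 0.0
    for name in spec.param_names():
        z = rng.standard_normal((means[name].size, spec.n_frames))
        if phi:
            # stationary AR(1) in the standardized variable
            out = np.empty_like(z)
            out[:, 0] = z[:, 0]
            c = np.sqrt(1.0 - phi * phi)
            for t in range(1, spec.n_frames):
                out[:, t] = phi * out[:, t - 1] + c * z[:, t]
            z = out
        values[name] = means[name][:, None] + sds[name][:, None] * z
    return ParameterEnsemble(
        values=values,
        bp_positions=np.arange(1, L + 1),
        step_positions=np.arange(1, L),
        frame_interval_ps=spec.frame_interval_ps,
        condition=spec.condition or ("unmodified" if not spec.duplex.annotations else "modified"),
        seed=spec.seed,
    )


def condition_suite(
    duplex: ModifiedDuplex,
    conditions: list[str],
    cpg_steps: list[int] | None = None,
    seed: int = 0,
    shared_seed_policy: str = "independent",
    **spec_kwargs,
) -> dict[str, ParameterEnsemble]:
    """One ensemble per condition, identical baselines, differing only in
    modification effects.

    *conditions* entries are mod types or ``"unmodified"``.  ``cpg_steps``
    defaults to every interior CpG step of the duplex (the terminal CG, if
    any, is excluded).  With ``shared_seed_policy="paired"`` all conditions
    share one seed, so ensembles differ only where the kernel has support;
    the default gives each condition its own seed.
    """
    if shared_seed_policy not in ("independent", "paired"):
        raise ValueError("shared_seed_policy must be 'independent' or 'paired'")
    if cpg_steps is None:
        L = len(duplex)
        cpg_steps = [p for p in find_cpg_sites(duplex.top) if p != L - 1]
    out: dict[str, ParameterEnsemble] = {}
    for i, cond in enumerate(conditions):
        if cond == "unmodified":
            dup = ModifiedDuplex(duplex.top)
        elif cond in MOD_TYPES:
            dup = apply_modifications(ModifiedDuplex(duplex.top), cpg_steps, cond)
        else:
            raise ValueError(f"unknown condition: {cond!r}")
        cond_seed = seed if shared_seed_policy == "paired" else seed + i
        spec = EnsembleSpec(duplex=dup, seed=cond_seed, condition=cond, **spec_kwargs)
        out[cond] = generate_parameter_ensemble(spec)
    return out


# ---------------------------------------------------------------------------
# Coordinate realization and extraction

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RESNAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_BASE_OF_RESNAME = {v: k for k, v in _RESNAMES.items()}


def _frame_coords(ensemble: ParameterEnsemble, frame: int) -> list[tuple[ReferenceFrame, ReferenceFrame]]:
    """(top-base frame, bottom-base frame) per bp for one ensemble frame."""
    missing = [n for n in ALL_PARAM_NAMES if n not in ensemble.values]
    if missing:
        raise ValueError(f"ensemble lacks parameters required for realization: {missing}")
    steps = [
        StepParams(*(ensemble.values[name][s, frame] for name in STEP_PARAM_NAMES))
        for s in range(len(ensemble.step_positions))
    ]
    bp_frames = rebuild_frames(ReferenceFrame.identity(), steps)
    pairs = []
    for i in range(len(ensemble.bp_positions)):
        intra = IntraBpParams(
            *(ensemble.values[name][i, frame] for name in INTRA_PARAM_NAMES)
        )
        pairs.append(base_frames_from_pair(bp_frames[i], intra))
    return pairs


def _template(duplex: ModifiedDuplex) -> struc.AtomArray:
    """Atom template: chain A = top strand 5'→3', chain B = bottom 5'→3'.

    Chain A residue i pairs with chain B residue L - i + 1.  Base geometry is
    the unmodified template for all residues (modifications are metadata; the
    ring atoms that define frames are identical either way).
    """
    L = len(duplex)
    records = []
    for i in range(1, L + 1):
        base = duplex.top[i - 1]
        for name in standard_atoms(base):
            records.append(("A", i, _RESNAMES[base], name))
    for b in range(1, L + 1):
        base = duplex.bottom[b - 1]
        for name in standard_atoms(base):
            records.append(("B", b, _RESNAMES[base], name))
    atoms = struc.AtomArray(len(records))
    atoms.chain_id = np.array([r[0] for r in records])
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array([r[2] for r in records])
    atoms.atom_name = np.array([r[3] for r in records])
    atoms.element = np.array([r[3][0] for r in records])
    atoms.hetero = np.zeros(len(records), dtype=bool)
    return atoms


def realize_coordinates(
    ensemble: ParameterEnsemble, duplex: ModifiedDuplex, return_coords: bool = False
):
    """Build 3-D coordinates for every frame of a full 12-parameter ensemble.

    Per frame, base-pair frames are chained from the step parameters, split
    into the two base frames via the intra-bp parameters, and standard base
    atoms are placed through each frame.  Returns an
    :class:`biotite.structure.AtomArrayStack` (float32 coordinates, ready for
    PDB output); with ``return_coords`` the full-precision float64 coordinate
    array (n_frames, n_atoms, 3) is returned as well, and feeding it back to
    :func:`extract_parameters` reproduces the ensemble values to ~1e-9.
    """
    L = len(duplex)
    if len(ensemble.bp_positions) != L:
        raise ValueError("ensemble does not cover all base pairs of the duplex")
    template = _template(duplex)
    stack = struc.AtomArrayStack(ensemble.n_frames, template.array_length())
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    full = np.empty((ensemble.n_frames, template.array_length(), 3), dtype=float)
    for f in range(ensemble.n_frames):
        pairs = _frame_coords(ensemble, f)
        coords = []
        for i in range(1, L + 1):
            fw, _ = pairs[i - 1]
            for xyz in standard_atoms(duplex.top[i - 1]).values():
                coords.append(fw.axes @ xyz + fw.origin)
        for b in range(1, L + 1):
            _, fc = pairs[L - b]
            for xyz in standard_atoms(duplex.bottom[b - 1]).values():
                coords.append(fc.axes @ xyz + fc.origin)
        full[f] = np.asarray(coords)
    stack.coord[:] = full
    if return_coords:
        return stack, full
    return stack


def extract_parameters(
    stack: struc.AtomArrayStack,
    frame_interval_ps: float = 4.8,
    condition: str = "",
    top_chain: str = "A",
    bottom_chain: str = "B",
    coords: np.ndarray | None = None,
) -> ParameterEnsemble:
    """Rigid base-pair parameters from a multi-model coordinate ensemble.

    Residue ``i`` of the top chain is paired with residue ``L - i + 1`` of the
    bottom chain (both chains numbered 1..L along their own 5'→3' direction).
    ``coords`` optionally supplies full-precision coordinates with the same
    atom layout as the stack (whose own coordinates are float32).
    """
    top_mask = stack.chain_id == top_chain
    bottom_mask = stack.chain_id == bottom_chain
    top_ids = np.unique(stack.res_id[top_mask])
    L = top_ids.size
    all_coords = stack.coord if coords is None else np.asarray(coords, dtype=float)
    n_frames = all_coords.shape[0]
    values = {name: np.empty((L if name in INTRA_PARAM_NAMES else L - 1, n_frames))
              for name in ALL_PARAM_NAMES}
    # pre-index atoms per residue
    res_atoms: dict[tuple[str, int], np.ndarray] = {}
    res_base: dict[tuple[str, int], str] = {}
    for chain, mask in ((top_chain, top_mask), (bottom_chain, bottom_mask)):
        for rid in np.unique(stack.res_id[mask]):
            sel = np.flatnonzero(mask & (stack.res_id == rid))
            res_atoms[(chain, int(rid))] = sel
            res_base[(chain, int(rid))] = _BASE_OF_RESNAME[stack.res_name[sel[0]]]
    for f in range(n_frames):
        coord = all_coords[f]
        bp_frames = []
        for i in range(1, L + 1):
            sel_w = res_atoms[(top_chain, i)]
            sel_c = res_atoms[(bottom_chain, L - i + 1)]
            obs_w = {stack.atom_name[k]: coord[k] for k in sel_w}
            obs_c = {stack.atom_name[k]: coord[k] for k in sel_c}
            fw = fit_base_frame(obs_w, res_base[(top_chain, i)])
            fc = fit_base_frame(obs_c, res_base[(bottom_chain, L - i + 1)])
            bp, intra = base_pair_frame(fw, fc)
            bp_frames.append(bp)
            for name, val in zip(INTRA_PARAM_NAMES, intra.as_array()[[0, 1, 2, 3, 4, 5]]):
                values[name][i - 1, f] = val
        for s in range(L - 1):
            sp = step_params(bp_frames[s], bp_frames[s + 1])
            for name, val in zip(STEP_PARAM_NAMES, sp.as_array()):
                values[name][s, f] = val
    return ParameterEnsemble(
        values=values,
        bp_positions=np.arange(1, L + 1),
        step_positions=np.arange(1, L),
        frame_interval_ps=frame_interval_ps,
        condition=condition,
    )


def write_multimodel_pdb(
    path: str | Path, stack: struc.AtomArrayStack, seed: int | None = None,
    spec_hash: str | None = None,
) -> None:
    """Write MODEL/ENDMDL-delimited PDB; seed and spec hash go into REMARKs."""
    f = pdb.PDBFile()
    f.set_structure(stack)
    buf = io.StringIO()
    f.write(buf)
    with open(path, "w") as fh:
        fh.write("REMARK 250 synthetic parameter-ensemble realization\n")
        if seed is not None:
            fh.write(f"REMARK 250 seed={seed}\n")
        if spec_hash is not None:
            fh.write(f"REMARK 250 spec_hash={spec_hash}\n")
        fh.write(buf.getvalue())


def read_multimodel_pdb(path: str | Path) -> struc.AtomArrayStack:
    f = pdb.PDBFile.read(str(path))
    return f.get_structure(model=None)
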