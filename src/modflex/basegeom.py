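"""Standard reference-frame geometry for the nucleic-acid bases.

Atom coordinates (Å) are expressed in the standard base reference frame
convention used throughout nucleic-acid structural analysis: the frame origin
sits in the base plane near the pairing edge, the x-axis points away from the
major groove along the pseudo-dyad, the y-axis points toward the sugar of the
parent strand, and the base plane is (nearly) the xy-plane.  Version: v1,
frozen with this package; the round-trip design of the geometry module means
downstream statistics depend only on these constants being a rigid,
non-collinear template, not on agreement with any external table to the last
digit.

Only ring atoms are used for frame fitting (``RING_ATOMS``); exocyclic
substituents are placed for coordinate realization but never enter the fit,
so modified and unmodified cytosines yield directly comparable frames.
"""

from __future__ import annotations

import numpy as np

# Canonical parameter names, shared across the package.
STEP_PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
INTRA_PARAM_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
ALL_PARAM_NAMES = STEP_PARAM_NAMES + INTRA_PARAM_NAMES

MOD_TYPES = ("5mC", "5hmC", "5fC", "5caC")

#: atom name -> (x, y, z) in the standard base frame, Å
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}

# Modified cytosines reuse the cytosine ring template; the C5 substituent is
# represented by a single placeholder heavy atom so realized coordinates are
# visibly distinct, but it is excluded from fitting like every exocyclic atom.
for _mod, _sub in (("5mC", "CM5"), ("5hmC", "CM5"), ("5fC", "CM5"), ("5caC", "CM5")):
    _atoms = dict(BASE_ATOMS["C"])
    _atoms[_sub] = (2.290, 5.065, 0.001)
    BASE_ATOMS[_mod] = _atoms

RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": _PURINE_RING,
    "G": _PURINE_RING,
    "C": _PYRIMIDINE_RING,
    "T": _PYRIMIDINE_RING,
    "5mC": _PYRIMIDINE_RING,
    "5hmC": _PYRIMIDINE_RING,
    "5fC": _PYRIMIDINE_RING,
    "5caC": _PYRIMIDINE_RING,
}


def standard_atoms(base_type: str) -> dict[str, np.ndarray]:
    """All standard-frame atoms for *base_type* as name -> 3-vector."""
    if base_type not in BASE_ATOMS:
        raise KeyError(f"unknown base type: {base_type!r}")
    return {name: np.asarray(xyz, dtype=float) for name, xyz in BASE_ATOMS[base_type].items()}


def ring_atom_coords(base_type: str) -> tuple[list[str], np.ndarray]:
    """Ring-atom names and their standard coordinates (n_atoms, 3)."""
    atoms = standard_atoms(base_type)
    names = [n for n in RING_ATOMS[base_type]]
    return names, np.stack([atoms[n] for n in names])
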