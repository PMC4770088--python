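"""DNA constructs: sequences, CpG sites, modification placement, loop geometry.

Coordinates are 1-based and inclusive throughout.  Bottom-strand positions are
indexed along the bottom strand 5'→3', so bottom position ``b`` faces top
position ``L - b + 1`` of an ``L``-bp duplex.  Modification annotations are
metadata carried alongside a plain A/C/G/T sequence — sequence strings never
use alternate alphabet letters, which keeps FASTA round trips
standard-compliant; modified positions travel in a sidecar TSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .basegeom import MOD_TYPES

__all__ = [
    "CENTRAL_70BP",
    "ModificationAnnotation",
    "ModifiedDuplex",
    "CyclizationConstruct",
    "reverse_complement",
    "find_cpg_sites",
    "apply_modifications",
    "loop_circumference",
    "modification_density",
    "read_fasta",
    "write_fasta",
    "read_modifications_tsv",
    "write_modifications_tsv",
]

#: Central 70-bp region of the cyclization construct whose four interior CpG
#: steps carry the cytosine modifications (5'→3', top strand).
CENTRAL_70BP = (
    "TACCTCAATATAGACTCCCTCCGGTGCCGAGGCCGCTCAATTGGTCGTAGGACTATCCTCACCTCCACCG"
)

_ALPHABET = set("ACGT")
_STRANDS = ("top", "bottom")


def _validate_sequence(bases: str) -> str:
    if not bases:
        raise ValueError("sequence must be nonempty")
    bad = set(bases) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return bases


def reverse_complement(bases: str) -> str:
    """Reverse complement of a top-strand string (5'→3' on the other strand)."""
    return str(Seq(_validate_sequence(bases)).reverse_complement())


@dataclass(frozen=True)
class ModificationAnnotation:
    """One modified cytosine: 1-based position along its own strand 5'→3'."""

    position: int
    strand: str
    mod_type: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"mod_type must be one of {MOD_TYPES}, got {self.mod_type!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class ModifiedDuplex:
    """A blunt double-stranded DNA with cytosine-modification annotations.

    The bottom strand is derived (exact reverse complement of ``top``).  Every
    annotation must sit on a C of its strand; duplicate (position, strand)
    entries are rejected.
    """

    top: str
    annotations: tuple[ModificationAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _validate_sequence(self.top)
        object.__setattr__(self, "annotations", tuple(self.annotations))
        seen = set()
        for ann in self.annotations:
            key = (ann.position, ann.strand)
            if key in seen:
                raise ValueError(f"duplicate annotation at {key}")
            seen.add(key)
            strand_seq = self.top if ann.strand == "top" else self.bottom
            if ann.position > len(strand_seq):
                raise ValueError(f"annotation position {ann.position} beyond duplex length")
            base = strand_seq[ann.position - 1]
            if base != "C":
                raise ValueError(
                    f"annotation at {ann.strand} position {ann.position} targets "
                    f"{base!r}, not C"
                )

    @property
    def bottom(self) -> str:
        return reverse_complement(self.top)

    def __len__(self) -> int:
        return len(self.top)

    def base_at(self, position: int, strand: str = "top") -> str:
        seq = self.top if strand == "top" else self.bottom
        return seq[position - 1]


@dataclass(frozen=True)
class CyclizationConstruct:
    """Looping construct: a duplex with two complementary 5' overhangs.

    The two overhangs anneal to each other, so the closed-loop circumference
    is ``duplex_length + overhang_length`` (the overhang length counts once).
    """

    duplex_length: int
    overhang_length: int
    label_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.duplex_length <= 0:
            raise ValueError("duplex_length must be positive")
        if self.overhang_length < 0:
            raise ValueError("overhang_length must be >= 0")


def find_cpg_sites(bases: str) -> list[int]:
    """1-based start positions of every CG dinucleotide on the top strand."""
    _validate_sequence(bases)
    return [i + 1 for i in range(len(bases) - 1) if bases[i : i + 2] == "CG"]


def apply_modifications(
    duplex: ModifiedDuplex,
    cpg_steps: list[int],
    mod_type: str,
    both_strands: bool = True,
) -> ModifiedDuplex:
    """Annotate the cytosines of the given CpG steps with *mod_type*.

    Each step position must be the C of a top-strand CG dinucleotide.  With
    ``both_strands`` the symmetric bottom-strand cytosine (facing the step's
    G) is annotated too, so each step contributes two modified cytosines.
    The base letters themselves are never changed.
    """
    L = len(duplex)
    new = list(duplex.annotations)
    for p in cpg_steps:
        if p < 1 or p + 1 > L or duplex.top[p - 1 : p + 1] != "CG":
            raise ValueError(f"position {p} is not a CpG step on the top strand")
        new.append(ModificationAnnotation(p, "top", mod_type))
        if both_strands:
            # bottom-strand C pairing with the top-strand G at p+1
            new.append(ModificationAnnotation(L - p, "bottom", mod_type))
    return replace(duplex, annotations=tuple(new))


def loop_circumference(construct: CyclizationConstruct) -> int:
    """Closed-loop circumference in bp: duplex length plus one overhang."""
    return construct.duplex_length + construct.overhang_length


def modification_density(duplex_length: int, n_modified: int) -> float:
    """Percent of all nucleotides (both strands) carrying a modification."""
    if duplex_length <= 0:
        raise ValueError("duplex_length must be positive")
    if n_modified < 0 or n_modified > 2 * duplex_length:
        raise ValueError("n_modified must be in [0, 2 * duplex_length]")
    return 100.0 * n_modified / (2 * duplex_length)


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a single- or multi-record FASTA as id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(_validate_sequence(s)), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_modifications_tsv(path: str | Path, duplex: ModifiedDuplex) -> None:
    """Sidecar TSV of annotations (columns: position, strand, mod_type; 1-based)."""
    df = pd.DataFrame(
        [(a.position, a.strand, a.mod_type) for a in duplex.annotations],
        columns=["position", "strand", "mod_type"],
    )
    with open(path, "w") as fh:
        fh.write("# modification annotations; positions 1-based along each strand 5'->3'\n")
        df.to_csv(fh, sep="\t", index=False)


def read_modifications_tsv(path: str | Path) -> list[ModificationAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "strand", "mod_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"modification TSV must have columns {sorted(required)}")
    return [
        ModificationAnnotation(int(r.position), str(r.strand), str(r.mod_type))
        for r in df.itertuples()
    ]
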