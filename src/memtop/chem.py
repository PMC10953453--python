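"""Mass arithmetic for intact proteoforms.

Residue masses, chain and proteoform masses (monoisotopic or average),
disulfide corrections, m/z <-> neutral-mass conversion under
protonation-only charging, and disulfide-count inference from a measured
intact mass.

Conventions
-----------
* Chain mass = sum of residue (monomer-minus-water) masses + one water
  (free N-terminal H, free C-terminal OH). No PTMs are modelled; construct
  offsets (tags, Met processing) go into ``Proteoform.fixed_mass_shift``.
* Each disulfide bridge removes two hydrogens.
* Charging is by protonation only: m/z = (M + z * m_p) / z with
  m_p = 1.007276 Da, matching positive-mode native spectra.
* Average masses are computed from pyteomics elemental compositions with
  IUPAC average atomic weights; monoisotopic masses come straight from the
  pyteomics residue table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from pyteomics import mass as _pmass

from .errors import (
    InconsistentMassError,
    InvalidChargeError,
    InvalidInputError,
    InvalidResidueError,
)

__all__ = [
    "AMINO_ACIDS",
    "PROTON_MASS",
    "MassMode",
    "Proteoform",
    "residue_mass",
    "chain_mass",
    "proteoform_mass",
    "mz_from_mass",
    "mass_from_mz",
    "infer_disulfide_count",
    "water_mass",
    "hydrogen_mass",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Proton mass in Da; all charging is protonation in positive mode.
PROTON_MASS = 1.007276

# IUPAC average atomic weights (2005 revision); these reproduce the
# standard average residue table (G = 57.0513, water = 18.0153).
_AVG_ATOMIC_WEIGHT = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.065,
}


class MassMode(str, Enum):
    """Which isotope convention to use for masses."""

    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"


def _average_mass(composition) -> float:
    return sum(_AVG_ATOMIC_WEIGHT[el] * n for el, n in composition.items())


_MONO_RESIDUE = {aa: _pmass.std_aa_mass[aa] for aa in AMINO_ACIDS}
_AVG_RESIDUE = {aa: _average_mass(_pmass.std_aa_comp[aa]) for aa in AMINO_ACIDS}

_WATER = {
    MassMode.MONOISOTOPIC: _pmass.calculate_mass(formula="H2O"),
    MassMode.AVERAGE: _average_mass({"H": 2, "O": 1}),
}
_HYDROGEN = {
    MassMode.MONOISOTOPIC: _pmass.calculate_mass(formula="H"),
    MassMode.AVERAGE: _AVG_ATOMIC_WEIGHT["H"],
}


def water_mass(mode: MassMode = MassMode.MONOISOTOPIC) -> float:
    """Mass of one water molecule (Da) in the given mode."""
    return _WATER[MassMode(mode)]


def hydrogen_mass(mode: MassMode = MassMode.MONOISOTOPIC) -> float:
    """Mass of one hydrogen atom (Da) in the given mode."""
    return _HYDROGEN[MassMode(mode)]


def residue_mass(aa: str, mode: MassMode = MassMode.MONOISOTOPIC) -> float:
    """Standard residue (monomer-minus-water) mass for one amino acid.

    Parameters
    ----------
    aa
        One of the 20 standard one-letter codes.
    mode
        Monoisotopic or average.

    Raises
    ------
    InvalidResidueError
        If ``aa`` is not a standard amino-acid letter.
    """
    mode = MassMode(mode)
    table = _MONO_RESIDUE if mode is MassMode.MONOISOTOPIC else _AVG_RESIDUE
    try:
        return table[aa]
    except KeyError:
        raise InvalidResidueError(f"unknown amino-acid letter {aa!r}") from None


@dataclass
class Proteoform:
    """A protein chain with oligomeric state, disulfides, and mass offset.

    Parameters
    ----------
    name
        Identifier (e.g. the FASTA record id).
    sequence
        One-letter amino-acid sequence of the monomer chain.
    n_copies
        Oligomeric state; 1 for a monomer, 3 for a homotrimer.
    disulfides
        Unordered 1-based residue-index pairs; both must be cysteines, and
        no cysteine may appear in two bridges.
    fixed_mass_shift
        Constant mass offset (Da) for unmodelled modifications.
    """

    name: str
    sequence: str
    n_copies: int = 1
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    fixed_mass_shift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must have length >= 1")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise InvalidResidueError(
                f"non-standard letters in sequence: {sorted(bad)}"
            )
        if self.n_copies < 1:
            raise ValueError("n_copies must be a positive integer")
        L = len(self.sequence)
        seen: set[int] = set()
        norm = []
        for pair in self.disulfides:
            i, j = sorted(pair)
            if i == j:
                raise ValueError(f"disulfide pair {pair} links a residue to itself")
            for idx in (i, j):
                if not 1 <= idx <= L:
                    raise ValueError(f"disulfide index {idx} outside 1..{L}")
                if self.sequence[idx - 1] != "C":
                    raise ValueError(
                        f"disulfide index {idx} is {self.sequence[idx - 1]}, not C"
                    )
                if idx in seen:
                    raise ValueError(f"residue {idx} appears in two disulfides")
                seen.add(idx)
            norm.append((i, j))
        self.disulfides = sorted(norm)

    @property
    def length(self) -> int:
        return len(self.sequence)


def chain_mass(sequence: str, mode: MassMode = MassMode.AVERAGE) -> float:
    """Neutral mass (Da) of a single linear chain with no disulfides."""
    mode = MassMode(mode)
    return sum(residue_mass(aa, mode) for aa in sequence) + _WATER[mode]


def proteoform_mass(p: Proteoform, mode: MassMode = MassMode.AVERAGE) -> float:
    """Neutral mass (Da) of a proteoform.

    M = n_copies * (chain mass - 2 * H * n_disulfides) + fixed_mass_shift;
    every disulfide bridge removes two hydrogens from every copy.
    """
    mode = MassMode(mode)
    per_chain = chain_mass(p.sequence, mode) - 2.0 * _HYDROGEN[mode] * len(p.disulfides)
    return p.n_copies * per_chain + p.fixed_mass_shift


def mz_from_mass(mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion of a neutral mass (Da)."""
    if z < 1:
        raise InvalidChargeError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass (Da) implied by an m/z at charge z (protonation only)."""
    if z < 1:
        raise InvalidChargeError(f"charge must be >= 1, got {z}")
    if mz <= PROTON_MASS:
        raise InvalidInputError(f"m/z {mz} at or below the proton mass")
    return z * (mz - PROTON_MASS)


def infer_disulfide_count(
    measured_mass: float, chain_mass_da: float, tolerance: float = 5.0
) -> tuple[int, float]:
    """Infer the number of disulfide bridges from a mass deficit.

    The measured intact mass of a disulfide-bonded protein falls short of
    its sequence (chain) mass by 2 x 1.00794 Da per bridge. Returns
    ``(count, residual)`` where residual is the part of the deficit not
    explained by ``count`` integer bridges.

    Raises
    ------
    InconsistentMassError
        If the measured mass exceeds the chain mass by more than
        ``tolerance`` Da.
    """
    deficit = chain_mass_da - measured_mass
    if deficit < -tolerance:
        raise InconsistentMassError(
            f"measured mass exceeds chain mass by {-deficit:.2f} Da"
        )
    step = 2.0 * _HYDROGEN[MassMode.AVERAGE]
    count = max(0, round(deficit / step))
    residual = deficit - count * step
    return count, residual


def read_fasta(path: str | Path, n_copies: int = 1) -> list[Proteoform]:
    """Read a single- or multi-record FASTA into Proteoforms.

    The record id becomes ``Proteoform.name``; disulfides and mass shifts
    are attached separately (topology table or config).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    return [
        Proteoform(name=rec.id, sequence=str(rec.seq).upper(), n_copies=n_copies)
        for rec in records
    ]
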