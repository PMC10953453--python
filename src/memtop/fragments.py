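"""Theoretical b/y fragment ledger for a proteoform.

Single backbone cleavage of one chain gives, at each site s (the bond
between residues s and s+1, 1-based), a b ion covering residues 1..s and
a y ion covering s+1..L. Disulfide bridges constrain this: a cleavage
inside a bridged loop cannot release either fragment (the straddle rule),
while a bridge fully contained in a fragment stays intact and lowers its
mass by two hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MassMode, Proteoform, hydrogen_mass, residue_mass, water_mass

__all__ = ["TheoreticalFragment", "generate_by_ions", "infeasible_sites", "write_theory_tsv"]


@dataclass(frozen=True)
class TheoreticalFragment:
    """One theoretical b or y ion at one cleavage site."""

    ion_type: str  # 'b' or 'y'
    site: int  # cleavage between residues site and site+1 (1-based)
    neutral_mass: float
    contains_disulfides: int
    feasible: bool


def generate_by_ions(
    p: Proteoform,
    mode: MassMode = MassMode.MONOISOTOPIC,
    allow_contained_disulfides: bool = True,
) -> list[TheoreticalFragment]:
    """Enumerate all 2(L-1) b/y fragments of the monomer chain.

    Feasibility: a fragment is infeasible when any disulfide (c1 < c2)
    straddles its cleavage site (c1 <= s < c2). A bridge fully inside a
    fragment subtracts 2 x H and increments ``contains_disulfides``; set
    ``allow_contained_disulfides=False`` to mark such loop-retaining
    fragments infeasible as well.

    For oligomers the ledger is generated from the monomer sequence: one
    backbone cleavage of one chain.
    """
    mode = MassMode(mode)
    seq = p.sequence
    L = len(seq)
    water = water_mass(mode)
    hyd = hydrogen_mass(mode)
    res = np.array([residue_mass(aa, mode) for aa in seq])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    total = prefix[-1]

    out: list[TheoreticalFragment] = []
    for s in range(1, L):
        straddle = any(c1 <= s < c2 for c1, c2 in p.disulfides)
        nb = sum(1 for c1, c2 in p.disulfides if c2 <= s)
        ny = sum(1 for c1, c2 in p.disulfides if c1 > s)
        feas_b = not straddle and (allow_contained_disulfides or nb == 0)
        feas_y = not straddle and (allow_contained_disulfides or ny == 0)
        out.append(
            TheoreticalFragment("b", s, float(prefix[s]) - 2 * hyd * nb, nb, feas_b)
        )
        out.append(
            TheoreticalFragment(
                "y", s, float(total - prefix[s]) + water - 2 * hyd * ny, ny, feas_y
            )
        )
    return out


def infeasible_sites(p: Proteoform) -> set[int]:
    """Cleavage sites masked by the disulfide straddle rule."""
    L = len(p.sequence)
    return {s for s in range(1, L) if any(c1 <= s < c2 for c1, c2 in p.disulfides)}


def write_theory_tsv(theory: list[TheoreticalFragment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ion_type": [f.ion_type for f in theory],
            "site": [f.site for f in theory],
            "neutral_mass": [f.neutral_mass for f in theory],
            "feasible": [f.feasible for f in theory],
            "contains_disulfides": [f.contains_disulfides for f in theory],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
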