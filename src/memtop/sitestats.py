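"""Charge-normalized per-site fragmentation statistics.

Image-current detectors respond in proportion to ion charge, so raw
fragment intensities are divided by z before aggregation. Per cleavage
site the pipeline reports summed normalized intensity, the
intensity-weighted average charge, and unique-fragment counts; across the
sequence it reports coverage (fraction of cleavable bonds observed) and a
20x20 amino-acid-pair propensity matrix for the cleaved bond X|Y,
rescaled so the hottest cell reads 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import AMINO_ACIDS
from .errors import AssignmentError, InvalidChargeError
from .matching import Assignment

__all__ = [
    "SiteProfile",
    "FragmentSummary",
    "normalize_intensity",
    "site_profile",
    "sequence_coverage",
    "pair_heatmap",
    "fragment_summary",
    "write_site_profile_tsv",
    "write_pair_matrix_tsv",
]


def normalize_intensity(raw: float, z: int, mode: str = "charge") -> float:
    """Correct detector response: raw/z for charge-proportional detectors.

    ``mode='none'`` returns the raw intensity unchanged (for detectors
    without charge-proportional response).
    """
    if z < 1:
        raise InvalidChargeError(f"charge must be >= 1, got {z}")
    if raw < 0:
        raise ValueError("intensity must be non-negative")
    if mode == "none":
        return raw
    if mode != "charge":
        raise ValueError(f"unknown normalization mode {mode!r}")
    return raw / z


@dataclass
class SiteProfile:
    """Per-cleavage-site aggregates over all assignments.

    Arrays are indexed by site 1..L-1 (position 0 of each array is site 1).
    ``weighted_avg_charge`` is NaN at sites with no intensity.
    """

    sequence_length: int
    total_norm_intensity: np.ndarray
    weighted_avg_charge: np.ndarray
    n_unique_fragments: np.ndarray
    ion_types_present: list[frozenset]

    @property
    def covered_sites(self) -> np.ndarray:
        """1-based sites with at least one assignment."""
        return np.nonzero(self.n_unique_fragments > 0)[0] + 1


@dataclass
class FragmentSummary:
    """Unweighted means over unique (ion_type, site, z) fragments."""

    mean_mass: float
    mean_charge: float
    n_unique: int


def _unique_assignments(assignments: list[Assignment]) -> list[Assignment]:
    # unique fragment = distinct (ion_type, site, z); duplicates keep the
    # more intense observation
    best: dict[tuple[str, int, int], Assignment] = {}
    for a in assignments:
        key = (a.ion_type, a.site, a.z)
        if key not in best or a.observed_intensity > best[key].observed_intensity:
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.site, a.ion_type, a.z))


def site_profile(
    assignments: list[Assignment],
    sequence_length: int,
    norm: str = "charge",
) -> SiteProfile:
    """Aggregate normalized intensity and weighted charge per site."""
    n_sites = sequence_length - 1
    total = np.zeros(n_sites)
    zw = np.zeros(n_sites)
    nuniq = np.zeros(n_sites, dtype=int)
    ions: list[set] = [set() for _ in range(n_sites)]
    for a in _unique_assignments(assignments):
        if not 1 <= a.site <= n_sites:
            raise AssignmentError(
                f"site {a.site} outside 1..{n_sites} for L={sequence_length}"
            )
        w = normalize_intensity(a.observed_intensity, a.z, norm)
        total[a.site - 1] += w
        zw[a.site - 1] += w * a.z
        nuniq[a.site - 1] += 1
        ions[a.site - 1].add(a.ion_type)
    with np.errstate(invalid="ignore", divide="ignore"):
        wavg = np.where(total > 0, zw / np.where(total > 0, total, 1.0), np.nan)
    return SiteProfile(
        sequence_length,
        total,
        wavg,
        nuniq,
        [frozenset(s) for s in ions],
    )


def sequence_coverage(assignments: list[Assignment], sequence_length: int) -> float:
    """Percent of the L-1 cleavable bonds observed with either ion type."""
    sites = {a.site for a in assignments}
    if sequence_length < 2:
        return 0.0
    return 100.0 * len(sites) / (sequence_length - 1)


def pair_heatmap(
    assignments: list[Assignment],
    sequence: str,
    norm: str = "charge",
) -> pd.DataFrame:
    """20x20 amino-acid-pair propensity matrix of the cleaved bond X|Y.

    Rows are the N-terminal residue X (position s), columns the
    C-terminal residue Y (position s+1); cells sum normalized intensities
    of unique fragments and are rescaled so the maximum cell equals 100
    (ties share 100).
    """
    mat = pd.DataFrame(
        0.0, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
    )
    for a in _unique_assignments(assignments):
        if a.site >= len(sequence):
            raise AssignmentError(
                f"site {a.site} inconsistent with sequence of length {len(sequence)}"
            )
        x, y = sequence[a.site - 1], sequence[a.site]
        mat.loc[x, y] += normalize_intensity(a.observed_intensity, a.z, norm)
    top = mat.to_numpy().max()
    if top > 0:
        mat = mat * (100.0 / top)
    return mat


def fragment_summary(assignments: list[Assignment]) -> FragmentSummary:
    """Mean neutral fragment mass and mean charge over unique fragments.

    An empty input yields the empty-summary marker (n_unique=0, NaN means).
    """
    uniq = _unique_assignments(assignments)
    if not uniq:
        return FragmentSummary(float("nan"), float("nan"), 0)
    masses = np.array([a.neutral_mass for a in uniq])
    charges = np.array([a.z for a in uniq], dtype=float)
    return FragmentSummary(float(masses.mean()), float(charges.mean()), len(uniq))


def write_site_profile_tsv(profile: SiteProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "site": np.arange(1, profile.sequence_length),
            "total_norm_intensity": profile.total_norm_intensity,
            "weighted_avg_charge": profile.weighted_avg_charge,
            "n_unique": profile.n_unique_fragments,
            "ion_types": ["".join(sorted(s)) for s in profile.ion_types_present],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_pair_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.4f")
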