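"""Match observed MS2 peaks to theoretical b/y fragments across charges.

Fragment charge is not annotated on centroided native top-down peaks, so
each peak is tried at every charge 1..z_max; the implied neutral mass is
compared against the feasible theoretical ledger and the peak receives
the single assignment with the smallest |ppm error| within tolerance.
The same theoretical fragment may be hit at several charges — these are
the repeat fragments grouped by :func:`group_repeats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import mass_from_mz, mz_from_mass
from .errors import ConfigError
from .fragments import TheoreticalFragment
from .peaks import PeakList

__all__ = [
    "Assignment",
    "RepeatGroup",
    "match_peaks",
    "group_repeats",
    "write_assignments_tsv",
    "read_assignments_tsv",
]

_ION_ORDER = {"b": 0, "y": 1}


@dataclass(frozen=True)
class Assignment:
    """One observed peak matched to one theoretical fragment at one charge."""

    ion_type: str
    site: int
    z: int
    observed_mz: float
    observed_intensity: float
    theoretical_mz: float
    neutral_mass: float
    error_ppm: float


@dataclass
class RepeatGroup:
    """All assignments sharing (ion_type, site), one per distinct charge."""

    ion_type: str
    site: int
    assignments: list[Assignment]

    @property
    def n_charge_states(self) -> int:
        return len({a.z for a in self.assignments})


def match_peaks(
    theory: list[TheoreticalFragment],
    pl: PeakList,
    tol_ppm: float = 10.0,
    z_max: int = 10,
) -> list[Assignment]:
    """Assign each MS2 peak to its best-matching feasible fragment.

    For every peak and every charge z in 1..z_max the candidate neutral
    mass ``mass_from_mz(mz, z)`` is scored against the ledger by |ppm
    error|; the peak takes the minimum-error candidate within ``tol_ppm``.
    Ties break deterministically: lower z, then b before y, then lower
    site. If the peak list carries a precursor charge, z is capped there.
    """
    if tol_ppm <= 0:
        raise ConfigError(f"tol_ppm must be positive, got {tol_ppm}")
    feasible = [f for f in theory if f.feasible]
    if not feasible or len(pl) == 0:
        return []
    if pl.precursor_z is not None:
        z_max = min(z_max, pl.precursor_z)

    frags = sorted(feasible, key=lambda f: f.neutral_mass)
    masses = np.array([f.neutral_mass for f in frags])

    out: list[Assignment] = []
    for i in range(len(pl)):
        mz_obs = pl.mz[i]
        best = None
        for z in range(1, z_max + 1):
            m = mass_from_mz(mz_obs, z)
            j = int(np.searchsorted(masses, m))
            for k in (j - 1, j):
                if not 0 <= k < len(frags):
                    continue
                f = frags[k]
                ppm = (m - f.neutral_mass) / f.neutral_mass * 1e6
                if abs(ppm) > tol_ppm:
                    continue
                key = (abs(ppm), z, _ION_ORDER[f.ion_type], f.site)
                if best is None or key < best[0]:
                    best = (key, f, z, ppm)
        if best is not None:
            _, f, z, ppm = best
            out.append(
                Assignment(
                    ion_type=f.ion_type,
                    site=f.site,
                    z=z,
                    observed_mz=float(mz_obs),
                    observed_intensity=float(pl.intensity[i]),
                    theoretical_mz=mz_from_mass(f.neutral_mass, z),
                    neutral_mass=f.neutral_mass,
                    error_ppm=float(ppm),
                )
            )
    return out


def group_repeats(assignments: list[Assignment]) -> list[RepeatGroup]:
    """Group assignments by (ion_type, site); repeats span several charges.

    Duplicate (ion_type, site, z) entries collapse to the most intense.
    Groups are sorted by n_charge_states descending, then by site.
    """
    best: dict[tuple[str, int, int], Assignment] = {}
    for a in assignments:
        key = (a.ion_type, a.site, a.z)
        if key not in best or a.observed_intensity > best[key].observed_intensity:
            best[key] = a
    groups: dict[tuple[str, int], list[Assignment]] = {}
    for a in best.values():
        groups.setdefault((a.ion_type, a.site), []).append(a)
    out = [
        RepeatGroup(ion, site, sorted(members, key=lambda a: a.z))
        for (ion, site), members in groups.items()
    ]
    out.sort(key=lambda g: (-g.n_charge_states, g.site, _ION_ORDER[g.ion_type]))
    return out


_COLUMNS = [
    "ion_type",
    "site",
    "z",
    "observed_mz",
    "theoretical_mz",
    "error_ppm",
    "intensity",
    "neutral_mass",
]


def write_assignments_tsv(assignments: list[Assignment], path: str | Path) -> None:
    pd.DataFrame(
        {
            "ion_type": [a.ion_type for a in assignments],
            "site": [a.site for a in assignments],
            "z": [a.z for a in assignments],
            "observed_mz": [a.observed_mz for a in assignments],
            "theoretical_mz": [a.theoretical_mz for a in assignments],
            "error_ppm": [a.error_ppm for a in assignments],
            "intensity": [a.observed_intensity for a in assignments],
            "neutral_mass": [a.neutral_mass for a in assignments],
        },
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_assignments_tsv(path: str | Path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        Assignment(
            ion_type=str(r.ion_type),
            site=int(r.site),
            z=int(r.z),
            observed_mz=float(r.observed_mz),
            observed_intensity=float(r.intensity),
            theoretical_mz=float(r.theoretical_mz),
            neutral_mass=float(r.neutral_mass),
            error_ppm=float(r.error_ppm),
        )
        for r in df.itertuples(index=False)
    ]
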