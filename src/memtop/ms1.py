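"""Native MS1 analysis: charge-series detection, neutral-mass estimation,
and satellite adduct-ladder detection on the deconvolved mass axis.

A high-mass native spectrum shows each species as a run of peaks at
consecutive protonation states. Series detection hypothesises a neutral
mass from every (peak, charge) pair, predicts the m/z positions of the
neighbouring charge states, and keeps maximal consecutive runs whose
implied masses agree. Adducts (bound phospholipids at ~700-730 Da steps,
residual detergent monomers) appear as ladders of nearly equal mass
increments above the base species and are detected after deconvolution,
on the zero-charge mass axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import mass_from_mz, mz_from_mass
from .errors import ConfigError, InsufficientMembersError, MemtopError
from .peaks import PeakList

__all__ = ["ChargeSeries", "AdductLadder", "detect_series", "series_mass", "detect_adducts"]


@dataclass
class ChargeSeries:
    """Peaks assigned consecutive charges and the neutral mass they imply.

    ``members`` holds (peak index, assigned charge) with charge strictly
    decreasing as m/z increases.
    """

    members: list[tuple[int, int]]
    mass_estimate: float
    mass_sd: float
    mean_intensity: float
    total_intensity: float

    @property
    def charges(self) -> list[int]:
        return sorted(z for _, z in self.members)


@dataclass
class AdductLadder:
    """A run of nearly equal mass increments above a base species."""

    base_mass: float
    step_mass: float
    n_steps: int
    step_intensities: list[float]


def _member_masses(members, pl: PeakList) -> np.ndarray:
    return np.array([mass_from_mz(pl.mz[i], z) for i, z in members])


def _weighted_stats(members, pl: PeakList) -> tuple[float, float, float, float]:
    masses = _member_masses(members, pl)
    w = pl.intensity[[i for i, _ in members]]
    if w.sum() <= 0:
        w = np.ones_like(w)
    mean = float(np.average(masses, weights=w))
    sd = float(np.sqrt(np.average((masses - mean) ** 2, weights=w)))
    inten = pl.intensity[[i for i, _ in members]]
    return mean, sd, float(inten.mean()), float(inten.sum())


def _run_for_hypothesis(
    pl: PeakList, mass: float, z_anchor: int, z_min: int, z_max: int, mz_tol: float
) -> list[tuple[int, int]]:
    """Best peak per charge for one mass hypothesis, trimmed to the maximal
    consecutive charge run containing ``z_anchor``."""
    matched: dict[int, int] = {}
    for z in range(z_min, z_max + 1):
        target = mz_from_mass(mass, z)
        j = int(np.searchsorted(pl.mz, target))
        best, best_err = -1, mz_tol
        for k in (j - 1, j):
            if 0 <= k < len(pl):
                err = abs(pl.mz[k] - target)
                if err <= best_err:
                    best, best_err = k, err
        if best >= 0:
            matched[z] = best
    if z_anchor not in matched:
        return []
    lo = z_anchor
    while lo - 1 in matched:
        lo -= 1
    hi = z_anchor
    while hi + 1 in matched:
        hi += 1
    return [(matched[z], z) for z in range(lo, hi + 1)]


def detect_series(
    pl: PeakList,
    z_min: int = 5,
    z_max: int = 30,
    mz_tol: float = 0.5,
    min_members: int = 3,
) -> list[ChargeSeries]:
    """Find charge-state series in a native MS1 peak list.

    Every (peak, z) pair seeds a neutral-mass hypothesis which is extended
    to neighbouring charges within ``mz_tol``; maximal runs of at least
    ``min_members`` consecutive charges are kept. Contested peaks go to
    the series with the smaller relative mass error (ties: the more
    intense series). Series are returned ranked by summed intensity.
    """
    if z_max < z_min:
        raise ConfigError(f"z_max {z_max} < z_min {z_min}")
    if z_min < 1:
        raise ConfigError("z_min must be >= 1")
    if min_members < 2:
        raise ConfigError("min_members must be >= 2")
    if len(pl) == 0:
        return []
    if pl.ms_level != 1:
        raise MemtopError("detect_series expects an MS1 peak list")

    candidates: dict[frozenset, list[tuple[int, int]]] = {}
    for i in range(len(pl)):
        for z in range(z_min, z_max + 1):
            mass = mass_from_mz(pl.mz[i], z)
            members = _run_for_hypothesis(pl, mass, z, z_min, z_max, mz_tol)
            if len(members) >= min_members:
                candidates.setdefault(frozenset(members), members)

    series = []
    for members in candidates.values():
        mean, sd, mi, ti = _weighted_stats(members, pl)
        series.append(ChargeSeries(sorted(members), mean, sd, mi, ti))
    series.sort(key=lambda s: (-s.total_intensity, s.mass_estimate))
    return resolve_contested_peaks(series, pl, min_members)


def _claim_key(s: ChargeSeries, z: int, i: int, pl: PeakList):
    # Relative mass error quantized at 1e-8 so float noise cannot decide a
    # tie (harmonic series fit exact data to machine precision); genuine
    # error differences are orders of magnitude larger. Ties fall through
    # to the higher-intensity series, then to mass for determinism.
    rel = abs(mass_from_mz(pl.mz[i], z) - s.mass_estimate) / s.mass_estimate
    return (round(rel * 1e8), -s.total_intensity, s.mass_estimate, tuple(s.members))


def resolve_contested_peaks(
    series: list[ChargeSeries], pl: PeakList, min_members: int
) -> list[ChargeSeries]:
    """Make candidate series disjoint.

    Each contested peak goes to the series with the smaller (quantized)
    relative mass error, ties to the higher-intensity series; losers keep
    their longest surviving consecutive-charge run if it still has
    ``min_members``. The surviving series are returned ranked by summed
    intensity.
    """
    claims: dict[int, tuple] = {}
    owner: dict[int, tuple] = {}
    for s in series:
        for i, z in s.members:
            key = _claim_key(s, z, i, pl)
            if i not in claims or key < claims[i]:
                claims[i] = key
                owner[i] = (id(s), s)

    rebuilt: list[ChargeSeries] = []
    for s in series:
        kept = sorted(
            ((i, z) for i, z in s.members if owner[i][0] == id(s)),
            key=lambda m: m[1],
        )
        runs: list[list[tuple[int, int]]] = []
        cur: list[tuple[int, int]] = []
        for m in kept:
            if cur and m[1] != cur[-1][1] + 1:
                runs.append(cur)
                cur = []
            cur.append(m)
        if cur:
            runs.append(cur)
        best = max(runs, key=len, default=[])
        if len(best) >= min_members:
            mean, sd, mi, ti = _weighted_stats(best, pl)
            rebuilt.append(ChargeSeries(sorted(best), mean, sd, mi, ti))

    # Dedupe identical member sets and drop leftovers overlapping an
    # already-accepted, higher-ranked series.
    accepted: list[ChargeSeries] = []
    used: set[int] = set()
    for s in sorted(rebuilt, key=lambda s: (-s.total_intensity, s.mass_estimate)):
        idxs = {i for i, _ in s.members}
        if idxs & used:
            continue
        accepted.append(s)
        used |= idxs
    return accepted


def series_mass(s: ChargeSeries, pl: PeakList) -> tuple[float, float]:
    """Intensity-weighted neutral mass and weighted SD of a series."""
    if len(s.members) < 2:
        raise InsufficientMembersError("series mass needs >= 2 members")
    mean, sd, _, _ = _weighted_stats(s.members, pl)
    return mean, sd


def detect_adducts(
    masses: list[tuple[float, float]],
    base_mass: float,
    step_window: tuple[float, float] = (700.0, 730.0),
    max_steps: int = 10,
    base_tol: float = 2.0,
) -> AdductLadder:
    """Detect a ladder of adduct mass increments above a base species.

    ``masses`` is a deconvolved (mass, intensity) list. Starting from the
    entry nearest ``base_mass`` (within ``base_tol`` Da), the ladder is
    extended greedily by increments inside ``step_window``; when several
    candidates fall in the window the most intense is taken. Phospholipid
    ladders use the ~700-730 Da window; detergent monomers (e.g. DDM at
    510.6 Da) need a window around their monomer mass.
    """
    lo, hi = step_window
    if hi < lo:
        raise ConfigError("step_window must be (lo, hi) with lo <= hi")
    arr = sorted(masses)
    if not arr:
        raise MemtopError("empty mass list")
    base_candidates = [m for m in arr if abs(m[0] - base_mass) <= base_tol]
    if not base_candidates:
        raise MemtopError(f"base mass {base_mass} not found within {base_tol} Da")
    base = min(base_candidates, key=lambda m: abs(m[0] - base_mass))

    current = base[0]
    increments: list[float] = []
    intensities: list[float] = []
    while len(increments) < max_steps:
        window = [m for m in arr if lo <= m[0] - current <= hi]
        if not window:
            break
        nxt = max(window, key=lambda m: (m[1], -m[0]))
        increments.append(nxt[0] - current)
        intensities.append(nxt[1])
        current = nxt[0]
    step = float(np.mean(increments)) if increments else 0.0
    return AdductLadder(base[0], step, len(increments), intensities)
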