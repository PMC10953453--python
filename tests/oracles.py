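"""Independent brute-force oracles used only by the test suite.

These deliberately take the slow, exhaustive route — enumerating charge
assignments and candidate combinations — so they share no search logic
with the package implementations they check.
"""

from __future__ import annotations

import numpy as np

from memtop.chem import mass_from_mz, mz_from_mass


def oracle_detect_series(pl, z_min, z_max, mz_tol, min_members):
    """Exhaustive charge-series search on a small peak list.

    Every (peak, charge) pair seeds a mass hypothesis; for each charge in
    range the *nearest* peak within tolerance of the predicted m/z (the
    series membership rule) is found by a full linear scan, and the
    maximal consecutive-charge window around the seed is kept. Valid
    maximal series are then made disjoint by the same ranking contract as
    the implementation (quantized relative mass error, then summed
    intensity).

    Returns a list of frozensets of (peak index, charge) members.
    """
    n = len(pl)
    candidates = {}
    for i in range(n):
        for z in range(z_min, z_max + 1):
            m0 = mass_from_mz(pl.mz[i], z)
            per_charge = {}
            for zp in range(z_min, z_max + 1):
                target = mz_from_mass(m0, zp)
                hits = sorted(
                    (j for j in range(n) if abs(pl.mz[j] - target) <= mz_tol),
                    key=lambda j: abs(pl.mz[j] - target),
                )
                if hits:
                    per_charge[zp] = hits[0]
            if z not in per_charge:
                continue
            lo = z
            while lo - 1 in per_charge:
                lo -= 1
            hi = z
            while hi + 1 in per_charge:
                hi += 1
            window = list(range(lo, hi + 1))
            if len(window) < min_members:
                continue
            members = tuple((per_charge[zp], zp) for zp in window)
            key = frozenset(members)
            if key not in candidates:
                w = pl.intensity[[j for j, _ in members]]
                masses = np.array([mass_from_mz(pl.mz[j], zp) for j, zp in members])
                if w.sum() <= 0:
                    w = np.ones_like(w)
                mass = float(np.average(masses, weights=w))
                candidates[key] = (mass, float(pl.intensity[[j for j, _ in members]].sum()))

    # Disjointness contract (same as the library, applied to this
    # exhaustively generated candidate set): contested peaks go to the
    # series with the smaller quantized relative mass error, ties to the
    # higher-intensity series; losers keep their longest surviving
    # consecutive run if it still satisfies min_members.
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1][1], kv[1][0]))
    claims = {}
    owner = {}
    for members, (mass, total) in ranked:
        for j, zp in members:
            rel = abs(mass_from_mz(pl.mz[j], zp) - mass) / mass
            key = (round(rel * 1e8), -total, mass, tuple(sorted(members)))
            if j not in claims or key < claims[j]:
                claims[j] = key
                owner[j] = frozenset(members)

    survivors = []
    for members, (mass, total) in ranked:
        kept = sorted(
            (m for m in members if owner[m[0]] == frozenset(members)),
            key=lambda m: m[1],
        )
        runs, cur = [], []
        for m in kept:
            if cur and m[1] != cur[-1][1] + 1:
                runs.append(cur)
                cur = []
            cur.append(m)
        if cur:
            runs.append(cur)
        best_run = max(runs, key=len, default=[])
        if len(best_run) >= min_members:
            w = pl.intensity[[j for j, _ in best_run]]
            masses = np.array([mass_from_mz(pl.mz[j], zp) for j, zp in best_run])
            if w.sum() <= 0:
                w = np.ones_like(w)
            survivors.append(
                (frozenset(best_run),
                 float(np.average(masses, weights=w)),
                 float(pl.intensity[[j for j, _ in best_run]].sum()))
            )

    accepted = []
    used = set()
    for members, mass, total in sorted(survivors, key=lambda s: (-s[2], s[1])):
        idxs = {j for j, _ in members}
        if idxs & used:
            continue
        accepted.append(members)
        used |= idxs
    return accepted


def oracle_match_peaks(theory, pl, tol_ppm, z_max):
    """Exhaustive (peak x fragment x charge) scoring.

    Full triple loop with no search-space pruning; per peak the candidate
    with the smallest |ppm| wins, ties broken by lower z, then b before y,
    then lower site — the same contract the implementation promises.
    Returns a list of (ion_type, site, z, peak index) tuples.
    """
    ion_order = {"b": 0, "y": 1}
    feasible = [f for f in theory if f.feasible]
    z_cap = z_max if pl.precursor_z is None else min(z_max, pl.precursor_z)
    out = []
    for i in range(len(pl)):
        best = None
        for f in feasible:
            for z in range(1, z_cap + 1):
                m = mass_from_mz(pl.mz[i], z)
                ppm = (m - f.neutral_mass) / f.neutral_mass * 1e6
                if abs(ppm) > tol_ppm:
                    continue
                key = (abs(ppm), z, ion_order[f.ion_type], f.site)
                if best is None or key < best[0]:
                    best = (key, f, z)
        if best is not None:
            _, f, z = best
            out.append((f.ion_type, f.site, z, i))
    return out
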