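"""Seeded synthetic data with known ground truth.

Generates membrane-protein-like proteoforms (alternating transmembrane
helices and loops, loop-placed disulfides), native MS1 spectra of the
intact species with phospholipid adduct ladders and residual detergent,
and MS2 b/y fragmentation spectra whose per-site cleavage propensities
follow the empirical rules of native top-down spectra: enhanced cleavage
N-terminal to proline (X|P) and glycine (A|G, F|G, V|G, I|G), C-terminal
to aspartate and glutamate (D|X, E|X), a transmembrane-helix enhancement
producing sequence tags, and disulfide-masked spans with no fragments.

The detector model is charge-proportional: an emitted fragment of true
abundance a observed at charge z has raw intensity a * z, so dividing by
z (the pipeline's normalization) recovers a exactly when jitter is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import MassMode, Proteoform, mz_from_mass, proteoform_mass
from .errors import ConfigError
from .fragments import TheoreticalFragment, generate_by_ions
from .peaks import PeakList
from .topology import Domain, Topology

__all__ = [
    "SimConfig",
    "SimMS1Result",
    "SimMS2Result",
    "simulate_proteoform",
    "simulate_ms1",
    "simulate_ms2",
    "bond_class_multiplier",
]

# Residue frequencies: helices hydrophobic-rich (with G and P so the
# glycine/proline bond classes occur inside the membrane), loops polar and
# acidic. Cys is only introduced explicitly for disulfides.
_HELIX_COMP = {
    "A": 0.12, "L": 0.14, "I": 0.10, "V": 0.10, "F": 0.08, "G": 0.12,
    "M": 0.03, "S": 0.05, "T": 0.06, "W": 0.02, "Y": 0.03, "P": 0.05,
    "N": 0.02, "Q": 0.02, "E": 0.02, "D": 0.02, "K": 0.01, "R": 0.005,
    "H": 0.005,
}
_LOOP_COMP = {
    "G": 0.10, "S": 0.10, "T": 0.08, "D": 0.10, "E": 0.10, "N": 0.06,
    "Q": 0.06, "K": 0.08, "R": 0.08, "P": 0.08, "H": 0.03, "A": 0.06,
    "L": 0.04, "V": 0.02, "I": 0.01, "F": 0.01, "Y": 0.01, "M": 0.01,
    "W": 0.005,
}

#: Average masses of common adducts (Da).
DDM_MONOMER_MASS = 510.6
PHOSPHOLIPID_STEP = 720.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate a GPCR-like receptor: ~300 residues, seven
    transmembrane helices with alternating extracellular/cytosolic loops,
    two loop disulfides, a native charge envelope centred at 17+, up to
    five phospholipid adducts at ~720 Da, and the bond-class propensity
    multipliers observed for vibrationally activated membrane proteins.
    """

    seed: int = 0
    sequence_length: int = 300
    n_tm_helices: int = 7
    helix_length: int = 21
    n_disulfides: int = 2
    disulfide_pairs: list[tuple[int, int]] | None = None

    # MS1 model
    envelope_center_z: float = 17.0
    envelope_width_z: float = 1.5
    adduct_step_mass: float = PHOSPHOLIPID_STEP
    adduct_max_steps: int = 5
    adduct_decay: float = 0.5
    detergent_level: float = 0.0  # mean residual detergent adducts per species
    detergent_mass: float = DDM_MONOMER_MASS
    ms1_jitter_sigma: float = 0.05  # m/z
    ms1_noise_peaks: int = 20
    ms1_noise_intensity: tuple[float, float] = (1.0, 5.0)

    # MS2 propensity model (multiplicative on a base rate of 1)
    base_rate: float = 1.0
    mult_xp: float = 5.0  # X|P
    mult_dx: float = 3.0  # D|X
    mult_ex: float = 3.0  # E|X
    mult_ag: float = 5.0  # A|G
    mult_fg: float = 3.0  # F|G
    mult_vg: float = 3.0  # V|G
    mult_ig: float = 3.0  # I|G
    mult_lx: float = 1.5  # L|X
    tm_factor: float = 3.0
    #: optional per-helix extra factors keyed by domain label (e.g. "H4"),
    #: on top of the global tm_factor
    helix_factors: dict[str, float] = field(default_factory=dict)

    # MS2 emission model
    n_fragment_sites: int = 60
    p_both_ions: float = 0.3
    charge_per_residue: float = 0.05
    charge_dispersion: float = 1.0
    max_fragment_charge: int = 10
    ms2_jitter_ppm: float = 2.0  # relative m/z jitter, 1 sigma in ppm
    ms2_noise_peaks: int = 50
    ms2_noise_intensity: tuple[float, float] = (0.1, 0.9)
    noise_avoid_theory: bool = True
    noise_guard_ppm: float = 30.0

    def validate(self) -> None:
        if self.sequence_length < 30:
            raise ConfigError("sequence_length must be >= 30")
        if self.n_tm_helices < 0:
            raise ConfigError("n_tm_helices must be >= 0")
        for name in (
            "base_rate", "mult_xp", "mult_dx", "mult_ex", "mult_ag",
            "mult_fg", "mult_vg", "mult_ig", "mult_lx", "tm_factor",
            "detergent_level",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SimMS1Result:
    peaks: PeakList
    true_mass: float
    adduct_step: float
    n_adduct_steps: int


@dataclass
class SimMS2Result:
    peaks: PeakList
    fragments: pd.DataFrame  # ion_type, site, z, abundance, mz, neutral_mass
    site_abundance: np.ndarray  # propensity model value per site (1..L-1)


def _draw(rng: np.random.Generator, comp: dict[str, float], n: int) -> list[str]:
    letters = list(comp)
    p = np.array([comp[a] for a in letters])
    p = p / p.sum()
    return list(rng.choice(letters, size=n, p=p))


def simulate_proteoform(cfg: SimConfig) -> tuple[Proteoform, Topology]:
    """Random membrane-protein-like proteoform plus its topology.

    Helices alternate with loops (extracellular first, GPCR-style);
    termini flank the bundle. Disulfides are placed as cysteine pairs in
    consecutive extracellular loops unless explicit pairs are given.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    L, nh = cfg.sequence_length, cfg.n_tm_helices

    if nh == 0:
        seq = "".join(_draw(rng, _LOOP_COMP, L))
        topo = Topology([Domain("chain", 1, L, "terminus")])
        p = Proteoform("sim_soluble", seq, disulfides=[])
        return p, topo

    helix_lens = [int(x) for x in rng.integers(cfg.helix_length - 2,
                                               cfg.helix_length + 3, size=nh)]
    n_loops = nh - 1
    soluble = L - sum(helix_lens)
    if soluble < (n_loops + 2) * 3:
        raise ConfigError("sequence too short for the requested helix count")
    # two termini plus inter-helix loops share the soluble residues
    n_segments = n_loops + 2
    base = soluble // n_segments
    loop_lens = [base] * n_segments
    loop_lens[-1] += soluble - base * n_segments

    domains: list[Domain] = []
    seq_parts: list[str] = []
    pos = 1
    # N-terminus (extracellular side)
    domains.append(Domain("n_term", pos, pos + loop_lens[0] - 1, "terminus"))
    seq_parts += _draw(rng, _LOOP_COMP, loop_lens[0])
    pos += loop_lens[0]
    for h in range(nh):
        domains.append(Domain(f"H{h + 1}", pos, pos + helix_lens[h] - 1, "tm_helix"))
        seq_parts += _draw(rng, _HELIX_COMP, helix_lens[h])
        pos += helix_lens[h]
        if h < nh - 1:
            # loop after helix h+1: odd loops cytosolic, even extracellular
            kind = "loop_cytosolic" if h % 2 == 0 else "loop_extracellular"
            ln = loop_lens[h + 1]
            domains.append(Domain(f"loop{h + 1}", pos, pos + ln - 1, kind))
            seq_parts += _draw(rng, _LOOP_COMP, ln)
            pos += ln
    domains.append(Domain("c_term", pos, pos + loop_lens[-1] - 1, "terminus"))
    seq_parts += _draw(rng, _LOOP_COMP, loop_lens[-1])

    seq = list("".join(seq_parts))
    topo = Topology(domains)

    if cfg.disulfide_pairs is not None:
        pairs = [tuple(sorted(p)) for p in cfg.disulfide_pairs]
        for i, j in pairs:
            seq[i - 1] = "C"
            seq[j - 1] = "C"
    else:
        ext_loops = [d for d in topo.domains if d.kind == "loop_extracellular"]
        if cfg.n_disulfides > 0 and len(ext_loops) < 2:
            raise ConfigError(
                "not enough extracellular loops to place the requested disulfides"
            )
        pairs = []
        used: set[int] = set()
        for k in range(cfg.n_disulfides):
            d1 = ext_loops[k % len(ext_loops)]
            d2 = ext_loops[(k + 1) % len(ext_loops)]
            if d1 is d2:
                raise ConfigError(
                    "disulfide request exceeds available distinct loops"
                )
            pos1 = _free_loop_position(rng, d1, used)
            pos2 = _free_loop_position(rng, d2, used)
            seq[pos1 - 1] = "C"
            seq[pos2 - 1] = "C"
            pairs.append(tuple(sorted((pos1, pos2))))
    p = Proteoform("sim_membrane", "".join(seq), disulfides=pairs)
    return p, topo


def _free_loop_position(rng, domain: Domain, used: set[int]) -> int:
    candidates = [i for i in range(domain.start, domain.end + 1) if i not in used]
    if not candidates:
        raise ConfigError(f"no free cysteine position left in {domain.label}")
    pos = int(rng.choice(candidates))
    used.add(pos)
    return pos


def simulate_ms1(p: Proteoform, cfg: SimConfig) -> SimMS1Result:
    """Native MS1 spectrum of the intact species with adducts and noise.

    Peaks appear at every charge of a Gaussian envelope, for every lipid
    ladder rung (geometric intensity decay) and a Poisson-drawn number of
    residual detergent monomers per species (mean ``detergent_level``,
    the knob standing in for sub-threshold activation).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    M = proteoform_mass(p, MassMode.AVERAGE)
    c, w = cfg.envelope_center_z, cfg.envelope_width_z
    z_lo = max(1, int(round(c - 3 * w)))
    z_hi = int(round(c + 3 * w))

    mzs, intens = [], []
    for z in range(z_lo, z_hi + 1):
        zw = float(np.exp(-((z - c) ** 2) / (2 * w * w)))
        for k in range(cfg.adduct_max_steps + 1):
            inten = 100.0 * zw * cfg.adduct_decay**k
            k_det = int(rng.poisson(cfg.detergent_level))
            mass = M + k * cfg.adduct_step_mass + k_det * cfg.detergent_mass
            mz = mz_from_mass(mass, z)
            if cfg.ms1_jitter_sigma > 0:
                mz += rng.normal(0.0, cfg.ms1_jitter_sigma)
            mzs.append(mz)
            intens.append(inten)

    lo_mz, hi_mz = min(mzs) * 0.9, max(mzs) * 1.1
    for _ in range(cfg.ms1_noise_peaks):
        mzs.append(rng.uniform(lo_mz, hi_mz))
        intens.append(rng.uniform(*cfg.ms1_noise_intensity))

    pl = PeakList(np.array(mzs), np.array(intens), ms_level=1, label="sim_ms1")
    return SimMS1Result(pl, M, cfg.adduct_step_mass, cfg.adduct_max_steps)


def bond_class_multiplier(x: str, y: str, cfg: SimConfig) -> float:
    """Propensity multiplier for cleaving the bond X|Y.

    The strongest applicable class wins (e.g. D|P takes max(X|P, D|X)).
    """
    mults = [1.0]
    if y == "P":
        mults.append(cfg.mult_xp)
    if x == "D":
        mults.append(cfg.mult_dx)
    if x == "E":
        mults.append(cfg.mult_ex)
    if y == "G":
        if x == "A":
            mults.append(cfg.mult_ag)
        elif x == "F":
            mults.append(cfg.mult_fg)
        elif x == "V":
            mults.append(cfg.mult_vg)
        elif x == "I":
            mults.append(cfg.mult_ig)
    if x == "L":
        mults.append(cfg.mult_lx)
    return max(mults)


def site_propensities(
    p: Proteoform, topo: Topology, cfg: SimConfig
) -> np.ndarray:
    """Cleavage abundance per site: base x bond class x helix x feasibility."""
    seq = p.sequence
    L = len(seq)
    straddled = {
        s for s in range(1, L) for c1, c2 in p.disulfides if c1 <= s < c2
    }
    out = np.zeros(L - 1)
    for s in range(1, L):
        if s in straddled:
            continue
        a = cfg.base_rate * bond_class_multiplier(seq[s - 1], seq[s], cfg)
        dom = topo.domain_of(s)
        if dom.kind == "tm_helix":
            a *= cfg.tm_factor * cfg.helix_factors.get(dom.label, 1.0)
        out[s - 1] = a
    return out


def simulate_ms2(
    p: Proteoform, topo: Topology, cfg: SimConfig
) -> SimMS2Result:
    """MS2 spectrum of multiply charged b/y fragments with ground truth.

    Sites are sampled without replacement with probability proportional
    to their propensity; each sampled site emits b, y or both, each at
    1-5 distinct charges drawn around a length-proportional mean. Raw
    peak intensity is abundance x z (charge-proportional detector), so
    charge normalization recovers the true abundances.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 3])
    theory = generate_by_ions(p, MassMode.MONOISOTOPIC)
    frag_by_key: dict[tuple[str, int], TheoreticalFragment] = {
        (f.ion_type, f.site): f for f in theory
    }
    L = len(p.sequence)
    abundance = site_propensities(p, topo, cfg)
    feasible_sites = np.nonzero(abundance > 0)[0] + 1
    if feasible_sites.size == 0:
        raise ConfigError("no feasible cleavage sites under this configuration")
    n_sel = min(cfg.n_fragment_sites, feasible_sites.size)
    probs = abundance[feasible_sites - 1]
    probs = probs / probs.sum()
    chosen = rng.choice(feasible_sites, size=n_sel, replace=False, p=probs)

    rows = []
    mzs, intens = [], []
    for s in sorted(int(s) for s in chosen):
        a = float(abundance[s - 1])
        u = rng.random()
        if u < cfg.p_both_ions:
            ions = ["b", "y"]
        else:
            ions = ["b"] if rng.random() < 0.5 else ["y"]
        for ion in ions:
            frag = frag_by_key[(ion, s)]
            if not frag.feasible:
                continue
            length = s if ion == "b" else L - s
            z_mean = max(1.2, length * cfg.charge_per_residue)
            n_z = int(rng.integers(1, 6))
            raw_z = rng.normal(z_mean, cfg.charge_dispersion, size=n_z)
            charges = sorted(
                {int(np.clip(round(z), 1, cfg.max_fragment_charge)) for z in raw_z}
            )
            for z in charges:
                mz = mz_from_mass(frag.neutral_mass, z)
                obs = mz * (1.0 + (rng.normal(0, cfg.ms2_jitter_ppm) * 1e-6
                                   if cfg.ms2_jitter_ppm > 0 else 0.0))
                mzs.append(obs)
                intens.append(a * z)
                rows.append(
                    {
                        "ion_type": ion,
                        "site": s,
                        "z": z,
                        "abundance": a,
                        "mz": mz,
                        "neutral_mass": frag.neutral_mass,
                    }
                )

    # Noise peaks; optionally kept clear of every theoretical fragment m/z
    # so false matches indicate matcher defects, not decoy coincidences.
    if mzs:
        lo_mz, hi_mz = min(mzs) * 0.8, max(mzs) * 1.1
    else:
        lo_mz, hi_mz = 500.0, 6000.0
    guard = _theory_mz_grid(theory, cfg.max_fragment_charge)
    for _ in range(cfg.ms2_noise_peaks):
        for _attempt in range(100):
            mz = rng.uniform(lo_mz, hi_mz)
            if not cfg.noise_avoid_theory or not _near_theory(
                mz, guard, cfg.noise_guard_ppm
            ):
                break
        mzs.append(mz)
        intens.append(rng.uniform(*cfg.ms2_noise_intensity))

    pl = PeakList(
        np.array(mzs), np.array(intens), ms_level=2, label="sim_ms2",
        precursor_z=max(cfg.max_fragment_charge, int(round(cfg.envelope_center_z))),
    )
    gt = pd.DataFrame(
        rows, columns=["ion_type", "site", "z", "abundance", "mz", "neutral_mass"]
    )
    return SimMS2Result(pl, gt, abundance)


def _theory_mz_grid(theory: list[TheoreticalFragment], z_max: int) -> np.ndarray:
    vals = [
        mz_from_mass(f.neutral_mass, z)
        for f in theory
        if f.feasible
        for z in range(1, z_max + 1)
    ]
    return np.sort(np.array(vals))


def _near_theory(mz: float, grid: np.ndarray, guard_ppm: float) -> bool:
    j = int(np.searchsorted(grid, mz))
    for k in (j - 1, j):
        if 0 <= k < grid.size and abs(mz - grid[k]) / grid[k] * 1e6 <= guard_ppm:
            return True
    return False
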