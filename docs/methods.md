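# Methods

This note documents the models, conventions and numerical choices behind
`memtop`, and what the synthetic-data tests do and do not demonstrate.

## Mass conventions

Chain mass is the sum of residue (monomer-minus-water) masses plus one
water: free N-terminal H, free C-terminal OH. No PTMs are modelled; any
construct offset (tags, N-terminal Met processing) is the user's
`fixed_mass_shift`. Monoisotopic residue masses come from the pyteomics
residue table; average masses are computed from pyteomics elemental
compositions with IUPAC average atomic weights (C 12.0107, H 1.00794,
N 14.0067, O 15.9994, S 32.065), reproducing the standard average table
(Gly 57.0513, water 18.0153). Average mode is the default for intact
proteins (>40 kDa species are reported as average masses); monoisotopic
is the default for fragment work.

Charging is protonation-only, positive mode: m/z = (M + z·1.007276)/z.
Each disulfide bridge removes two hydrogens from every chain copy.
Disulfide-count inference rounds the chain-minus-measured deficit to the
nearest multiple of 2 × 1.00794 Da and reports the residual; a measured
mass exceeding the chain mass by more than 5 Da (default tolerance) is
an error rather than "zero bridges".

## MS1 charge-series detection

Every (peak, charge) pair in the configured z range seeds a neutral-mass
hypothesis. The hypothesis predicts the m/z of each neighbouring charge
state; the nearest peak within `mz_tol` (default 0.5 m/z — native
high-mass peaks are broad) joins the series, and the maximal run of
consecutive charges containing the seed is kept when it has at least
`min_members` (default 3) members. The series mass is the
intensity-weighted mean of the member-implied neutral masses; its
uncertainty is the weighted standard deviation.

Candidate series are then made disjoint. A contested peak goes to the
series with the smaller relative mass error; errors are quantized at
1e-8 relative before comparison because exact data admit harmonic
aliases (every second peak of a series at halved charge fits a
half-mass hypothesis to machine precision) that must not win on float
noise. Quantized ties fall to the higher-intensity series, then to mass
for determinism. Losers keep their longest surviving consecutive run if
it still satisfies `min_members`. Series are ranked by summed intensity.

Adduct ladders are detected on the deconvolved (zero-charge) mass axis:
starting from the base species, the ladder greedily extends by
increments inside a window — (700, 730) Da for phospholipids, a window
around 510.6 Da for DDM monomers — taking the most intense candidate at
each rung. Output is the rung count, mean step mass and rung
intensities.

## Fragment theory and the disulfide straddle rule

Single backbone cleavage of one chain, b and y ions only — no internal
fragments, no a/x/c/z, no neutral losses. At each site s (bond between
residues s and s+1) the ledger holds one b (residues 1..s) and one y
(s+1..L) fragment; the intact-chain "b_L/y_L" is not emitted. A
disulfide (c1 < c2) straddling the cleavage (c1 ≤ s < c2) makes both
ions infeasible: vibrational activation does not cleave S–S bonds, so a
cut inside a bridged loop releases nothing. A bridge fully contained in
a fragment stays intact, subtracting 2H and incrementing a counter;
whether such loop-retaining fragments count as feasible is configurable
(`allow_contained_disulfides`, default true). For oligomers the ledger
is generated from the monomer sequence; the complex-level precursor
mass belongs to the MS1 stage.

## Peak-to-fragment matching

Observed centroids carry no charge annotation (isotope spacing is out of
scope), so each peak is tried at every charge 1..z_max (default 10,
capped at the precursor charge when known). The implied neutral mass is
scored against the feasible ledger by |ppm error|; the peak takes the
single best candidate within `tol_ppm` (default 10 ppm, a typical
high-resolution top-down tolerance). Ties break deterministically:
lower charge, then b before y, then lower site. Matching is therefore
an injection from peaks to (fragment, charge) pairs; one fragment
matched at several charges forms a repeat group. Duplicate
(ion, site, z) observations collapse to the most intense.

## Site statistics

Raw intensities are divided by charge before aggregation: image-current
detectors respond in proportion to z, and dividing restores abundance
(`norm="none"` is available for other detector models). A "unique
fragment" is a distinct (ion type, site, charge) triple. Per site the
profile reports summed normalized intensity, intensity-weighted average
charge and unique-fragment count. Coverage counts cleavable bonds:
100 × covered sites / (L−1), either ion type sufficing. The pair
heatmap sums normalized intensity into the 20×20 grid of the cleaved
bond (N-terminal residue, C-terminal residue) and rescales so the
maximum cell reads 100, ties sharing 100. Whether repeat fragments are
summed before or after normalization does not matter for the charge
model used here (a·z/z = a either way); summation happens after.

## Topology mapping

A topology is an ordered, gap-free, non-overlapping partition of
residues 1..L into tm_helix, loop (periplasmic / cytosolic /
extracellular) and terminus domains, 1-based inclusive. Cleavage site s
belongs to the domain containing residue s, so boundary bonds go to the
N-terminal domain — consistent with indexing fragments by the residue
number N-terminal to the bond. Domain summaries report intensity
fractions, covered-site counts and the longest run of consecutive
covered sites per domain; sequence tags are maximal runs of at least
`min_len` (default 2) consecutive covered sites, attributed to the
domain holding the majority of their sites (ties to the N-terminal-most
domain). Disulfide-infeasible sites are reported per domain alongside
the observed zeros, so absence caused by bridging is distinguishable
from absence despite feasibility. Mapping onto 3D structures is out of
scope.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every draw taken from `numpy.random.default_rng([seed, stream])`
so identical configs give byte-identical output.

**Proteoform.** Alternating helix/loop architecture: helices of
21 ± 2 residues drawn from a hydrophobic-rich composition (A/L/I/V/F/G
heavy, with enough G and P that the glycine and proline bond classes
occur inside the membrane), loops and termini from a polar composition
rich in D/E/G/S/P. The default is GPCR-like: 300 residues, 7 helices,
extracellular N-terminus, loops alternating cytosolic/extracellular,
and two disulfides placed as cysteine pairs in consecutive
extracellular loops (each bridge spans about two helices). Explicit
`disulfide_pairs` override the placement. Since the pair positions
cannot precede the random sequence, the config takes a bridge count and
the generator chooses loop positions.

**MS1.** Peaks at every charge of a Gaussian envelope (default centred
at 17+, width 1.5) for every rung of the lipid ladder (default 720 Da,
5 rungs, geometric decay 0.5) plus a Poisson-drawn number of residual
detergent monomers per species (`detergent_level`, default 0; DDM
monomer 510.6 Da). `detergent_level` is the knob standing in for
sub-threshold activation: raising it degrades charge-state resolution
the way insufficient micelle removal does. Gaussian m/z jitter (default
0.05) and uniform noise peaks complete the spectrum. No isotope
envelopes and no profile-mode traces are modelled.

**MS2.** Per-site cleavage abundance = base rate × bond-class
multiplier × helix factor × disulfide feasibility. Default multipliers:
X|P 5, A|G 5, D|X 3, E|X 3, F|G 3, V|G 3, I|G 3, L|X 1.5 (the
strongest applicable class wins), transmembrane factor 3, with optional
per-helix extras for enhancement-recovery studies. Sixty sites are
sampled without replacement with probability proportional to abundance;
each emits b, y or both (both with probability 0.3), at 1–5 distinct
charges drawn around a length-proportional mean (0.05 charges/residue,
dispersion 1). Raw intensity is abundance × z — the
charge-proportional detector response the pipeline's normalization
inverts, which makes the normalization decision itself testable:
at zero jitter the recovered per-fragment abundances equal the
generating ones exactly. m/z jitter is relative (default 2 ppm) so it
lives on the same scale as the matching tolerance. Noise peaks are
uniform in m/z and, by default, redrawn if they land within 30 ppm of
any theoretical fragment m/z: the generator guarantees "no
mass-coincident decoys", turning the matcher's precision into a
falsifiable property rather than a seed lottery (`noise_avoid_theory`
switches this off).

**What passing does not show.** The generator has no isotope structure,
no peak-shape effects, no intensity noise, no co-isolation, and its
propensity model is exactly the multiplicative family the statistics
assume. Recovery results therefore validate the pipeline's
bookkeeping, search and aggregation — not the biological claim that
real membrane proteins fragment this way, and not robustness to
model-misspecified intensities.

## Problem sizes and test design

Synthetic studies use L = 300 (7 helices) or L = 400 (11 helices,
ammonia-channel-like) with ~60 sampled sites and 50 noise peaks —
enough for stable rank statistics while keeping the whole suite and the
acceptance script in the seconds range. Oracle-equivalence checks run
the production search against brute-force enumeration (full-scan
nearest-peak series building; exhaustive peak × fragment × charge
scoring) on 100+ random instances of ≤ 30 peaks. Property-based tests
(hypothesis, 200 cases each) cover the m/z round trip, intensity
conservation across aggregation, and coverage/tolerance monotonicity.

## Known limitations

No isotope-envelope deconvolution or averagine fitting; no FDR
estimation against decoy sequences (future work); no internal
fragments or neutral losses; no mzML reader (TSV and MGF only); no
3D-structure overlay. The laser-power physics of micelle removal is
deliberately reduced to the `detergent_level` adduct knob — the
photochemistry is out of scope.
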