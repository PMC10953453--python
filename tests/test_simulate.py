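"""Synthetic-data generator: determinism, architecture, round trips."""

import numpy as np
import pandas as pd
import pytest

from memtop import (
    SimConfig,
    detect_adducts,
    detect_series,
    match_peaks,
    series_mass,
    simulate_ms1,
    simulate_ms2,
    simulate_proteoform,
    site_profile,
)
from memtop.errors import ConfigError
from memtop.fragments import generate_by_ions, infeasible_sites


class TestSimulateProteoform:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=1, sequence_length=200, n_tm_helices=7)
        p1, t1 = simulate_proteoform(cfg)
        p2, t2 = simulate_proteoform(cfg)
        assert p1.sequence == p2.sequence
        assert p1.disulfides == p2.disulfides
        assert t1.domains == t2.domains

    def test_soluble_control(self):
        p, topo = simulate_proteoform(SimConfig(seed=2, n_tm_helices=0))
        assert topo.tm_labels() == []
        assert len(topo.domains) == 1

    def test_gpcr_like_architecture(self):
        cfg = SimConfig(seed=3, n_tm_helices=7, n_disulfides=2)
        p, topo = simulate_proteoform(cfg)
        assert len(topo.tm_labels()) == 7
        assert len(p.disulfides) == 2
        # every bridge cysteine sits in a loop, never in a helix
        for c1, c2 in p.disulfides:
            for c in (c1, c2):
                assert p.sequence[c - 1] == "C"
                assert topo.domain_of(c).kind != "tm_helix"
        assert topo.length == p.length

    def test_helices_are_hydrophobic_rich(self):
        p, topo = simulate_proteoform(SimConfig(seed=4))
        hydro = set("AILVFMW")
        helix_res = [
            p.sequence[i - 1]
            for d in topo.domains if d.kind == "tm_helix"
            for i in range(d.start, d.end + 1)
        ]
        loop_res = [
            p.sequence[i - 1]
            for d in topo.domains if d.kind != "tm_helix"
            for i in range(d.start, d.end + 1)
        ]
        f_helix = sum(r in hydro for r in helix_res) / len(helix_res)
        f_loop = sum(r in hydro for r in loop_res) / len(loop_res)
        assert f_helix > 2 * f_loop

    def test_impossible_disulfide_request_rejected(self):
        with pytest.raises(ConfigError):
            simulate_proteoform(SimConfig(seed=5, n_tm_helices=2, n_disulfides=2))


class TestSimulateMS1:
    def test_noiseless_round_trip_recovers_mass(self):
        cfg = SimConfig(seed=6, detergent_level=0.0, ms1_jitter_sigma=0.0,
                        ms1_noise_peaks=0, adduct_max_steps=0)
        p, _ = simulate_proteoform(cfg)
        res = simulate_ms1(p, cfg)
        series = detect_series(res.peaks, z_min=10, z_max=25, mz_tol=0.5)
        mass, sd = series_mass(series[0], res.peaks)
        assert mass == pytest.approx(res.true_mass, abs=1e-6)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_adduct_ladder_round_trip(self):
        cfg = SimConfig(seed=7, ms1_jitter_sigma=0.0, ms1_noise_peaks=0,
                        adduct_max_steps=5, adduct_step_mass=720.0)
        p, _ = simulate_proteoform(cfg)
        res = simulate_ms1(p, cfg)
        series = detect_series(res.peaks, z_min=10, z_max=25, mz_tol=0.5)
        masses = [(series_mass(s, res.peaks)[0], s.total_intensity) for s in series]
        ladder = detect_adducts(masses, res.true_mass, (700, 730), 10)
        assert ladder.n_steps == 5
        assert ladder.step_mass == pytest.approx(720.0, abs=0.1)

    def test_detergent_adducts_degrade_deconvolution(self):
        base = dict(seed=8, ms1_jitter_sigma=0.02, ms1_noise_peaks=10,
                    adduct_max_steps=2)
        cfg_clean = SimConfig(**base, detergent_level=0.0)
        cfg_messy = SimConfig(**base, detergent_level=3.0)
        p, _ = simulate_proteoform(cfg_clean)
        clean = simulate_ms1(p, cfg_clean)
        messy = simulate_ms1(p, cfg_messy)

        def mass_error_and_unassigned(res):
            series = detect_series(res.peaks, z_min=10, z_max=25, mz_tol=0.5)
            assigned = {i for s in series for i, _ in s.members}
            unassigned = 1 - len(assigned) / len(res.peaks)
            if not series:
                return np.inf, unassigned
            best = min(abs(s.mass_estimate - res.true_mass) for s in series)
            return best, unassigned

        err_clean, un_clean = mass_error_and_unassigned(clean)
        err_messy, un_messy = mass_error_and_unassigned(messy)
        assert err_messy > err_clean
        assert un_messy > un_clean

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9, detergent_level=1.0)
        p, _ = simulate_proteoform(cfg)
        a, b = simulate_ms1(p, cfg), simulate_ms1(p, cfg)
        np.testing.assert_array_equal(a.peaks.mz, b.peaks.mz)
        np.testing.assert_array_equal(a.peaks.intensity, b.peaks.intensity)


class TestSimulateMS2:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=10)
        p, topo = simulate_proteoform(cfg)
        a, b = simulate_ms2(p, topo, cfg), simulate_ms2(p, topo, cfg)
        np.testing.assert_array_equal(a.peaks.mz, b.peaks.mz)
        pd.testing.assert_frame_equal(a.fragments, b.fragments)

    def test_detector_round_trip_exact_at_zero_jitter(self):
        """normalize_intensity inverts the charge-proportional response."""
        cfg = SimConfig(seed=11, ms2_jitter_ppm=0.0, ms2_noise_peaks=0)
        p, topo = simulate_proteoform(cfg)
        res = simulate_ms2(p, topo, cfg)
        theory = generate_by_ions(p)
        assignments = match_peaks(theory, res.peaks, tol_ppm=1, z_max=10)
        recovered = {
            (x.ion_type, x.site, x.z): x.observed_intensity / x.z
            for x in assignments
        }
        for row in res.fragments.itertuples(index=False):
            assert recovered[(row.ion_type, row.site, row.z)] == pytest.approx(
                row.abundance, rel=1e-12
            )

    def test_uniform_null_is_flat_per_fragment(self):
        """With all multipliers at 1 the per-fragment normalized intensity
        is identical at every site: no intrinsic site preference."""
        cfg = SimConfig(seed=12, tm_factor=1.0, mult_xp=1, mult_dx=1,
                        mult_ex=1, mult_ag=1, mult_fg=1, mult_vg=1,
                        mult_ig=1, mult_lx=1, n_disulfides=0,
                        ms2_jitter_ppm=0.0, ms2_noise_peaks=0)
        p, topo = simulate_proteoform(cfg)
        res = simulate_ms2(p, topo, cfg)
        assert res.fragments["abundance"].nunique() == 1
        a = match_peaks(generate_by_ions(p), res.peaks, tol_ppm=1, z_max=10)
        prof = site_profile(a, p.length)
        hit = prof.n_unique_fragments > 0
        per_frag = prof.total_norm_intensity[hit] / prof.n_unique_fragments[hit]
        np.testing.assert_allclose(per_frag, per_frag[0], rtol=1e-9)

    def test_disulfide_masked_span_yields_no_fragments(self):
        """Bridged helices produce zero assignments, as in receptor spectra
        where disulfide-linked spans go dark."""
        cfg = SimConfig(seed=13)
        p, topo = simulate_proteoform(cfg)
        assert p.disulfides  # default config places two bridges
        res = simulate_ms2(p, topo, cfg)
        masked = infeasible_sites(p)
        assert masked
        a = match_peaks(generate_by_ions(p), res.peaks, tol_ppm=10, z_max=10)
        assert not ({x.site for x in a} & masked)

    def test_enhanced_bond_class_recovered_in_heatmap(self):
        from memtop import pair_heatmap

        cfg = SimConfig(seed=14, tm_factor=1.0)
        p, topo = simulate_proteoform(cfg)
        res = simulate_ms2(p, topo, cfg)
        a = match_peaks(generate_by_ions(p), res.peaks, tol_ppm=10, z_max=10)
        mat = pair_heatmap(a, p.sequence)
        (x, y) = mat.stack().idxmax()
        assert y in "PG" or x in "DE"

    def test_recall_against_ground_truth(self):
        """End-to-end recall >= 0.95 at a tolerance of 3x the jitter."""
        cfg = SimConfig(seed=15, ms2_jitter_ppm=2.0)
        p, topo = simulate_proteoform(cfg)
        res = simulate_ms2(p, topo, cfg)
        a = match_peaks(generate_by_ions(p), res.peaks, tol_ppm=6.0, z_max=10)
        truth = {
            (r.ion_type, r.site, r.z) for r in res.fragments.itertuples(index=False)
        }
        got = {(x.ion_type, x.site, x.z) for x in a}
        assert len(truth & got) / len(truth) >= 0.95
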