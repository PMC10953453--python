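"""Charge normalization, site profiles, coverage, pair heatmaps, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtop.errors import AssignmentError, InvalidChargeError
from memtop.sitestats import (
    fragment_summary,
    normalize_intensity,
    pair_heatmap,
    sequence_coverage,
    site_profile,
)
from test_matching import make_assignment


class TestNormalizeIntensity:
    def test_division_by_charge(self):
        assert normalize_intensity(100.0, 4) == 25.0
        assert normalize_intensity(0.0, 7) == 0.0

    def test_equal_abundance_across_charges(self):
        # same true abundance seen at z=2 (raw 200) and z=5 (raw 500)
        assert normalize_intensity(200.0, 2) == normalize_intensity(500.0, 5)

    def test_identity_mode_and_bad_charge(self):
        assert normalize_intensity(42.0, 5, mode="none") == 42.0
        with pytest.raises(InvalidChargeError):
            normalize_intensity(1.0, 0)


class TestSiteProfile:
    def test_hand_arithmetic(self):
        a = [
            make_assignment("b", 10, 3, intensity=90.0),  # norm 30
            make_assignment("y", 10, 5, intensity=50.0),  # norm 10
        ]
        prof = site_profile(a, sequence_length=20)
        assert prof.total_norm_intensity[9] == pytest.approx(40.0)
        assert prof.weighted_avg_charge[9] == pytest.approx(3.5)
        assert prof.n_unique_fragments[9] == 2
        assert prof.ion_types_present[9] == frozenset("by")

    def test_empty_profile(self):
        prof = site_profile([], sequence_length=50)
        assert prof.total_norm_intensity.sum() == 0
        assert np.isnan(prof.weighted_avg_charge).all()

    def test_out_of_range_site_rejected(self):
        with pytest.raises(AssignmentError):
            site_profile([make_assignment("b", 30, 1)], sequence_length=20)

    def test_intensity_conservation(self, rng):
        a = [
            make_assignment("b", int(s), int(z), intensity=float(i))
            for s, z, i in zip(
                rng.integers(1, 99, 60), rng.integers(1, 8, 60),
                rng.uniform(1, 100, 60),
            )
        ]
        # deduplicate to unique fragments as the profile does
        uniq = {}
        for x in a:
            key = (x.ion_type, x.site, x.z)
            if key not in uniq or x.observed_intensity > uniq[key].observed_intensity:
                uniq[key] = x
        prof = site_profile(a, sequence_length=100)
        expected = sum(x.observed_intensity / x.z for x in uniq.values())
        assert prof.total_norm_intensity.sum() == pytest.approx(expected)

    def test_weighted_charge_bounded_by_member_charges(self, rng):
        a = [
            make_assignment("b", 5, int(z), intensity=float(i))
            for z, i in zip(rng.integers(1, 9, 10), rng.uniform(1, 50, 10))
        ]
        prof = site_profile(a, sequence_length=10)
        zs = {x.z for x in a}
        assert min(zs) <= prof.weighted_avg_charge[4] <= max(zs)


class TestSequenceCoverage:
    def test_boundary_cases(self):
        assert sequence_coverage([], 101) == 0.0
        full = [make_assignment("b", s, 1) for s in range(1, 101)]
        assert sequence_coverage(full, 101) == 100.0

    def test_26_sites_of_100_bonds(self):
        a = [make_assignment("b", s, 1) for s in range(1, 27)]
        assert sequence_coverage(a, 101) == pytest.approx(26.0)

    def test_either_ion_type_counts_once(self):
        a = [make_assignment("b", 5, 1), make_assignment("y", 5, 2)]
        assert sequence_coverage(a, 11) == pytest.approx(10.0)

    @settings(max_examples=200, deadline=None)
    @given(
        sites=st.lists(st.integers(1, 99), max_size=30),
        extra=st.lists(st.integers(1, 99), max_size=10),
    )
    def test_monotone_in_assignments(self, sites, extra):
        base = [make_assignment("b", s, 1) for s in sites]
        more = base + [make_assignment("y", s, 2) for s in extra]
        assert sequence_coverage(more, 100) >= sequence_coverage(base, 100)


class TestPairHeatmap:
    SEQ = "AGTPIPAG" + "L" * 12

    def test_single_bond_scores_100(self):
        a = [make_assignment("b", 1, 2, intensity=8.0)]  # A|G bond
        mat = pair_heatmap(a, self.SEQ)
        assert mat.loc["A", "G"] == 100.0
        assert mat.to_numpy().sum() == 100.0

    def test_ties_share_the_maximum(self):
        a = [
            make_assignment("b", 3, 2, intensity=10.0),  # T|P
            make_assignment("b", 5, 2, intensity=10.0),  # I|P
        ]
        mat = pair_heatmap(a, self.SEQ)
        assert mat.loc["T", "P"] == 100.0
        assert mat.loc["I", "P"] == 100.0

    def test_rescaling_invariance(self, rng):
        a = [
            make_assignment("b", int(s), int(z), intensity=float(i))
            for s, z, i in zip(
                rng.integers(1, len(self.SEQ) - 1, 25),
                rng.integers(1, 6, 25), rng.uniform(1, 30, 25),
            )
        ]
        scaled = [
            make_assignment(x.ion_type, x.site, x.z,
                            intensity=x.observed_intensity * 7.5)
            for x in a
        ]
        m1, m2 = pair_heatmap(a, self.SEQ), pair_heatmap(scaled, self.SEQ)
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), rtol=1e-12)

    def test_all_cells_within_0_100(self, rng):
        a = [
            make_assignment("y", int(s), int(z), intensity=float(i))
            for s, z, i in zip(
                rng.integers(1, len(self.SEQ) - 1, 40),
                rng.integers(1, 6, 40), rng.uniform(0, 100, 40),
            )
        ]
        vals = pair_heatmap(a, self.SEQ).to_numpy()
        assert vals.min() >= 0 and vals.max() == 100.0


class TestFragmentSummary:
    def test_two_fragments(self):
        a = [
            make_assignment("b", 10, 4, mass=8000.0),
            make_assignment("y", 20, 5, mass=9000.0),
        ]
        s = fragment_summary(a)
        assert (s.mean_mass, s.mean_charge, s.n_unique) == (8500.0, 4.5, 2)

    def test_single_and_empty(self):
        (one,) = [make_assignment("b", 3, 2, mass=1234.5)]
        s = fragment_summary([one])
        assert (s.mean_mass, s.mean_charge, s.n_unique) == (1234.5, 2.0, 1)
        empty = fragment_summary([])
        assert empty.n_unique == 0 and math.isnan(empty.mean_mass)

    def test_longer_fragments_give_heavier_higher_charged_summary(self):
        short = [make_assignment("b", s, 2, mass=3000.0 + s) for s in range(1, 6)]
        long_ = [make_assignment("b", s, 5, mass=9000.0 + s) for s in range(1, 6)]
        s_short, s_long = fragment_summary(short), fragment_summary(long_)
        assert s_long.mean_mass > s_short.mean_mass
        assert s_long.mean_charge > s_short.mean_charge
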