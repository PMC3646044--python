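"""Ubiquity curves, two-parameter and minor-core election, regions, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from conftest import profile_from_columns, random_profile
from ubicore import (
    CohortProfile,
    CoreCutoff,
    TaxonCountTable,
    ValidationError,
    bootstrap_core_counts,
    elect_core,
    elect_minor_core,
    elect_region_core,
    normalize,
    region_ubiquity_and,
    region_ubiquity_mean,
    ubiquity,
    ubiquity_curve,
)


class TestUbiquity:
    def test_strict_inequality(self, toy_profile):
        # abundances of A: 0.6, 0.5, 0.9, 0.2 -> only 0.6 and 0.9 exceed 0.5
        assert ubiquity(toy_profile, "A", 0.5) == 0.5

    def test_all_positive_at_zero(self, toy_profile):
        assert ubiquity(toy_profile, "A", 0.0) == 1.0

    def test_absent_taxon_zero(self):
        prof = profile_from_columns(t=np.zeros(4))
        assert ubiquity(prof, "t", 0.0) == 0.0
        assert ubiquity(prof, "t", 0.5) == 0.0

    def test_unknown_taxon_key_error(self, toy_profile):
        with pytest.raises(KeyError):
            ubiquity(toy_profile, "nope", 0.1)

    def test_negative_cutoff_rejected(self, toy_profile):
        with pytest.raises(ValidationError):
            ubiquity(toy_profile, "A", -0.1)


class TestUbiquityCurve:
    def test_enumerated_breakpoints(self):
        prof = profile_from_columns(t=np.array([0.2, 0.2, 0.8]))
        curve = ubiquity_curve(prof, "t")
        assert curve.breakpoints.tolist() == [0.2, 0.8]
        assert curve.ubiquities.tolist() == pytest.approx([1 / 3, 0.0])

    def test_single_donor_full_abundance(self):
        prof = CohortProfile(pd.DataFrame({"t": [1.0]}, index=["d0"]))
        curve = ubiquity_curve(prof, "t")
        assert curve(0.0) == 1.0
        assert curve(0.999) == 1.0
        assert curve(1.0) == 0.0

    def test_matches_pointwise_definition(self, toy_profile):
        for taxon in toy_profile.taxon_labels:
            curve = ubiquity_curve(toy_profile, taxon)
            for a in np.concatenate([[0.0], curve.breakpoints, [0.33, 0.77]]):
                assert curve(a) == ubiquity(toy_profile, taxon, a)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_non_increasing(self, seed):
        prof = random_profile(np.random.default_rng(seed))
        for taxon in prof.taxon_labels:
            curve = ubiquity_curve(prof, taxon)
            grid = np.linspace(0, 1, 101)
            vals = curve(grid)
            assert (np.diff(vals) <= 1e-12).all()
            assert curve(curve.breakpoints.max()) == 0.0

    def test_mean_abundance_recovered(self, toy_profile):
        curve = ubiquity_curve(toy_profile, "A")
        assert curve.mean_abundance() == pytest.approx(np.mean([0.6, 0.5, 0.9, 0.2]))


class TestElectCore:
    def test_toy_strictness(self, toy_profile):
        # B's ubiquity at 0.1 is exactly 0.75 -> excluded by strict cutoff
        assert elect_core(toy_profile, CoreCutoff(0.1, 0.75)) == {"A"}

    def test_tiny_cutoffs_elect_all_present(self, toy_profile):
        assert elect_core(toy_profile, CoreCutoff(1e-9, 1e-9)) == {"A", "B", "C"}

    def test_absent_taxon_never_elected(self):
        prof = profile_from_columns(t=np.zeros(4))
        assert elect_core(prof, CoreCutoff(1e-9, 1e-9)) == {"_rest"}

    @pytest.mark.parametrize("seed", range(5))
    def test_antitone_in_both_cutoffs(self, seed):
        prof = random_profile(np.random.default_rng(seed))
        base = elect_core(prof, CoreCutoff(0.05, 0.5))
        assert elect_core(prof, CoreCutoff(0.10, 0.5)) <= base
        assert elect_core(prof, CoreCutoff(0.05, 0.7)) <= base

    def test_cutoff_validation(self):
        with pytest.raises(ValidationError):
            CoreCutoff(0.0, 0.8)
        with pytest.raises(ValidationError):
            CoreCutoff(0.01, 1.5)


class TestMinorCore:
    def test_elected_with_max_ubiquity(self):
        prof = profile_from_columns(t=np.array([5e-4, 8e-4, 3e-4, 0.0]))
        recs = elect_minor_core(prof)
        rec = {r.taxon: r for r in recs}["t"]
        assert rec.max_ubiquity == 0.75
        assert rec.max_abundance == pytest.approx(8e-4)

    def test_rejected_above_ceiling(self):
        prof = profile_from_columns(t=np.array([5e-4, 0.02, 3e-4, 4e-4]))
        assert "t" not in {r.taxon for r in elect_minor_core(prof)}

    def test_rejected_minority(self):
        prof = profile_from_columns(t=np.array([5e-4, 0.0, 0.0, 0.0]))
        assert "t" not in {r.taxon for r in elect_minor_core(prof)}

    def test_majority_tie_excluded(self):
        # exactly 50% presence is not a majority (> floor is strict)
        prof = profile_from_columns(t=np.array([5e-4, 5e-4, 0.0, 0.0]))
        assert "t" not in {r.taxon for r in elect_minor_core(prof)}

    def test_ceiling_tolerance(self):
        prof = profile_from_columns(t=np.array([5e-4, 0.02, 3e-4, 4e-4]))
        got = {r.taxon for r in elect_minor_core(prof, ceiling_tolerance=0.25)}
        assert "t" in got

    def test_parameter_ordering_error(self, toy_profile):
        with pytest.raises(ValidationError):
            elect_minor_core(toy_profile, detection_floor=0.05, abundance_ceiling=0.01)

    @pytest.mark.parametrize("seed", range(10))
    def test_disjoint_from_major_core(self, seed):
        # a minor-core taxon never exceeds 1% anywhere, so it cannot clear
        # a 1% abundance cutoff at 80% ubiquity
        prof = random_profile(np.random.default_rng(seed), n_donors=6, n_taxa=5)
        core = elect_core(prof, CoreCutoff(0.01, 0.80))
        minor = {r.taxon for r in elect_minor_core(prof)}
        assert core.isdisjoint(minor)


class TestRegions:
    def test_mean_and_product(self):
        p1 = profile_from_columns(t=np.array([0.5] * 9 + [0.1]))
        p2 = profile_from_columns(t=np.array([0.5] * 7 + [0.1] * 3))
        # ubiquity at a=0.2: p1 -> 0.9, p2 -> 0.7
        assert region_ubiquity_mean([p1, p2], "t", 0.2) == pytest.approx(0.8)
        assert region_ubiquity_and([p1, p2], "t", 0.2) == pytest.approx(0.63)

    def test_single_habitat_identity(self, toy_profile):
        u = ubiquity(toy_profile, "A", 0.1)
        assert region_ubiquity_mean([toy_profile], "A", 0.1) == u
        assert region_ubiquity_and([toy_profile], "A", 0.1) == u

    def test_absent_taxon_annihilates_and(self, toy_profile):
        other = profile_from_columns(z=np.array([0.3, 0.3]))
        assert region_ubiquity_and([toy_profile, other], "A", 0.1) == 0.0
        assert region_ubiquity_mean([toy_profile, other], "A", 0.1) == pytest.approx(0.5)

    def test_empty_region_error(self):
        with pytest.raises(ValidationError):
            region_ubiquity_mean([], "t", 0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_and_below_mean_below_max(self, seed):
        rng = np.random.default_rng(seed)
        profs = [random_profile(rng) for _ in range(3)]
        taxa = {t for p in profs for t in p.taxon_labels}
        for a in [0.0, 0.01, 0.2]:
            for t in taxa:
                ubs = [ubiquity(p, t, a) if t in p else 0.0 for p in profs]
                anded = region_ubiquity_and(profs, t, a)
                meaned = region_ubiquity_mean(profs, t, a)
                assert anded <= meaned + 1e-12
                assert meaned <= max(ubs) + 1e-12

    def test_region_election_modes(self, toy_profile):
        profs = [toy_profile, toy_profile]
        anded = elect_region_core(profs, CoreCutoff(0.1, 0.75), mode="and")
        meaned = elect_region_core(profs, CoreCutoff(0.1, 0.75), mode="mean")
        assert anded <= meaned  # product can only lose members


class TestBootstrapCoreCounts:
    def test_degenerate_single_taxon(self):
        df = pd.DataFrame({"only": [100, 100, 100]}, index=["d1", "d2", "d3"])
        table = TaxonCountTable(df)
        (rep,) = bootstrap_core_counts(table, [CoreCutoff(0.5, 0.5)], b=20, seed=0)
        assert rep.observed == rep.median == rep.lower == rep.upper == 1

    def test_observed_matches_election(self, toy_table):
        cutoff = CoreCutoff(0.2, 0.4)
        (rep,) = bootstrap_core_counts(toy_table, [cutoff], b=10, seed=1)
        assert rep.observed == len(elect_core(normalize(toy_table), cutoff))
        assert rep.taxa == frozenset(elect_core(normalize(toy_table), cutoff))

    def test_seed_reproducible(self, toy_table):
        cutoffs = [CoreCutoff(0.2, 0.4), CoreCutoff(0.5, 0.5)]
        a = bootstrap_core_counts(toy_table, cutoffs, b=40, seed=42)
        b = bootstrap_core_counts(toy_table, cutoffs, b=40, seed=42)
        assert a == b

    def test_bounds_bracket_median(self, toy_table):
        (rep,) = bootstrap_core_counts(toy_table, [CoreCutoff(0.2, 0.4)], b=160, seed=3)
        assert rep.lower <= rep.median <= rep.upper

    def test_b_too_small(self, toy_table):
        with pytest.raises(ValidationError):
            bootstrap_core_counts(toy_table, [CoreCutoff(0.2, 0.4)], b=1)
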