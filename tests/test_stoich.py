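"""Relative and integer stoichiometry, occupancy, time courses, clustering."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextomics.model import (
    ComplexDefinition,
    InsufficientDataError,
    ValidationError,
)
from contextomics.stoich import (
    RecruitmentProfile,
    cluster_profiles,
    complex_bound_fraction,
    enumerate_candidates,
    fit_integer_stoichiometry,
    normalize_timecourse,
    occupancy_fraction,
    relative_stoichiometry,
)

LUBAC = ComplexDefinition("lubac", (("HOIP", 1), ("HOIL1", 2), ("SHARPIN", 2)))
TRIPLE = ComplexDefinition("abc", (("A", 1), ("B", 1), ("C", 1)))


def brute_force_best(observed, max_copies=4, allow_excess=True):
    """Independent oracle: re-enumerate the candidate set with plain loops
    and return the minimal achievable RMS log2 error."""
    members = list(observed)
    obs = np.array([observed[m] for m in members])
    obs_log = np.log2(obs / obs.max())
    best = math.inf
    bases = [
        v
        for v in itertools.product(range(1, max_copies + 1), repeat=len(members))
        if math.gcd(*v) == 1
    ]
    excesses = [None]
    if allow_excess:
        excesses += [
            v
            for v in itertools.product(range(0, max_copies + 1), repeat=len(members))
            if any(v)
        ]
    for base in bases:
        for excess in excesses:
            comp = np.array(base, float)
            if excess is not None:
                comp = comp + np.array(excess, float)
            err = float(
                np.sqrt(np.mean((np.log2(comp / comp.max()) - obs_log) ** 2))
            )
            best = min(best, err)
    return best


class TestRelativeStoichiometry:
    def test_most_abundant_reference_with_tie_broken_by_member_order(self):
        est = relative_stoichiometry(TRIPLE, {"A": 100.0, "B": 50.0, "C": 100.0})
        assert est.reference_member == "A"
        assert est.ratios == {"A": 1.0, "B": 0.5, "C": 1.0}

    def test_substoichiometric_partner_ratio(self):
        cdef = ComplexDefinition("pair", (("TRAF2", 1), ("BIRC2", 1)))
        est = relative_stoichiometry(cdef, {"TRAF2": 100.0, "BIRC2": 22.0})
        assert est.ratios["BIRC2"] == pytest.approx(0.22)

    def test_all_zero_amounts_raise(self):
        cdef = ComplexDefinition("xy", (("X", 1), ("Y", 1)))
        with pytest.raises(InsufficientDataError):
            relative_stoichiometry(cdef, {"X": 0.0, "Y": 0.0})

    def test_fixed_reference_policy(self):
        est = relative_stoichiometry(
            TRIPLE, {"A": 100.0, "B": 50.0, "C": 200.0}, policy="fixed:A"
        )
        assert est.reference_member == "A"
        assert est.ratios["C"] == pytest.approx(2.0)

    def test_missing_member_reported_absent(self):
        est = relative_stoichiometry(TRIPLE, {"A": 100.0, "B": 50.0})
        assert est.missing_members == ("C",)
        assert "C" not in est.ratios

    @given(scale=st.floats(1e-6, 1e6))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, scale):
        amounts = {"A": 30.0, "B": 70.0, "C": 50.0}
        scaled = {k: v * scale for k, v in amounts.items()}
        a = relative_stoichiometry(TRIPLE, amounts)
        b = relative_stoichiometry(TRIPLE, scaled)
        for pid in amounts:
            assert b.ratios[pid] == pytest.approx(a.ratios[pid], rel=1e-9)


class TestIntegerStoichiometry:
    def test_excess_subunit_pattern_top_ranked(self):
        # 0.5 : 1 : 1 is a core 1:1:1 with one extra copy of each of two subunits
        top = fit_integer_stoichiometry({"HOIP": 0.5, "HOIL1": 1.0, "SHARPIN": 1.0})[0]
        assert top.base == (1, 1, 1)
        assert top.excess == (0, 1, 1)
        assert top.fit_error == 0.0

    def test_equimolar_pair_needs_no_excess(self):
        top = fit_integer_stoichiometry({"A": 1.0, "B": 1.0})[0]
        assert top.base == (1, 1)
        assert top.excess is None
        assert top.fit_error == 0.0

    def test_one_to_three_ratios_fit_exactly(self):
        top = fit_integer_stoichiometry({"A": 1 / 3, "B": 1.0, "C": 1.0})[0]
        assert top.fit_error == 0.0
        assert np.allclose(top.predicted_ratios, [1 / 3, 1.0, 1.0])

    def test_agrees_with_brute_force_oracle_on_noisy_ratios(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            observed = {
                m: float(r)
                for m, r in zip("ABC", np.sort(rng.uniform(0.2, 1.0, 3))[::-1])
            }
            top = fit_integer_stoichiometry(observed)[0]
            assert top.fit_error == pytest.approx(brute_force_best(observed), abs=1e-12)

    def test_roundtrip_of_predicted_ratios(self):
        """Feeding any model's predicted ratios back returns a top model
        with the same ratios at zero error."""
        for base, excess in enumerate_candidates(2, 3, True)[:50]:
            comp = np.array(base, float)
            if excess is not None:
                comp = comp + np.array(excess, float)
            ratios = dict(zip("AB", comp / comp.max()))
            top = fit_integer_stoichiometry(ratios, max_copies=3)[0]
            assert top.fit_error == pytest.approx(0.0, abs=1e-12)
            assert np.allclose(top.predicted_ratios, comp / comp.max())

    def test_ranking_is_deterministic(self):
        observed = {"A": 0.52, "B": 1.0, "C": 0.97}
        a = fit_integer_stoichiometry(observed, top=5)
        b = fit_integer_stoichiometry(observed, top=5)
        assert [(m.base, m.excess) for m in a] == [(m.base, m.excess) for m in b]

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValidationError):
            fit_integer_stoichiometry({"A": 0.0, "B": 1.0})

    def test_max_copies_below_one_rejected(self):
        with pytest.raises(ValueError):
            fit_integer_stoichiometry({"A": 0.5, "B": 1.0}, max_copies=0)


class TestOccupancyAndBoundFraction:
    @pytest.mark.parametrize(
        "bait,interactor,mult,expected",
        [(100, 5, 1, 0.05), (100, 250, 1, 2.5), (100, 0, 1, 0.0), (100, 30, 2, 0.15)],
    )
    def test_occupancy(self, bait, interactor, mult, expected):
        assert occupancy_fraction(bait, interactor, mult) == pytest.approx(expected)

    def test_occupancy_requires_positive_bait(self):
        with pytest.raises(ValidationError):
            occupancy_fraction(0, 10)

    @pytest.mark.parametrize(
        "carrier,cargo,fraction,over",
        [(100, 22, 0.22, False), (100, 100, 1.0, False), (100, 130, 1.3, True)],
    )
    def test_bound_fraction_and_over_unity_flag(self, carrier, cargo, fraction, over):
        res = complex_bound_fraction(carrier, cargo)
        assert res.fraction == pytest.approx(fraction)
        assert res.over_unity is over

    def test_bound_fraction_requires_positive_carrier(self):
        with pytest.raises(ValidationError):
            complex_bound_fraction(0, 10)


class TestTimecourse:
    T = (0.0, 5.0, 10.0, 15.0)

    def test_receptor_then_max_normalization(self):
        prof = normalize_timecourse("P", self.T, (10, 40, 80, 60), (10, 20, 40, 60))
        assert prof.values == pytest.approx((0.5, 1.0, 1.0, 0.5))

    def test_analyte_proportional_to_receptor_is_flat_one(self):
        prof = normalize_timecourse("P", self.T, (5, 10, 20, 30), (10, 20, 40, 60))
        assert prof.values == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_all_zero_analyte_gives_flat_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            prof = normalize_timecourse("P", self.T, (0, 0, 0, 0), (10, 20, 40, 60))
        assert prof.values == (0.0,) * 4
        assert any("zero" in r.message for r in caplog.records)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_to_receptor_rescaling(self, scale):
        receptor = (10.0, 20.0, 40.0, 60.0)
        scaled = tuple(r * scale for r in receptor)
        a = normalize_timecourse("P", self.T, (10, 40, 80, 60), receptor)
        b = normalize_timecourse("P", self.T, (10, 40, 80, 60), scaled)
        assert b.values == pytest.approx(a.values, rel=1e-9)


class TestClustering:
    T = (0.0, 5.0, 10.0, 15.0)

    def _profiles_from_templates(self, templates, per_template, noise, seed):
        rng = np.random.default_rng(seed)
        profiles = []
        for g, template in enumerate(templates):
            for i in range(per_template):
                values = np.array(template) + rng.normal(0, noise, len(template))
                values = np.clip(values, 0.01, None)
                values = values / values.max()
                profiles.append(
                    RecruitmentProfile(f"g{g}_p{i}", self.T, tuple(values))
                )
        return profiles

    def test_three_template_groups_recovered_exactly(self):
        templates = [
            (0.0, 1.0, 0.6, 0.3),   # early peak
            (0.0, 0.3, 1.0, 0.8),   # mid peak
            (0.0, 0.1, 0.4, 1.0),   # late rise
        ]
        profiles = self._profiles_from_templates(templates, 5, 0.03, seed=3)
        labels = cluster_profiles(profiles, k=3)
        # all members of a template share one label; labels differ across templates
        groups = [
            {labels[f"g{g}_p{i}"] for i in range(5)} for g in range(3)
        ]
        assert all(len(g) == 1 for g in groups)
        assert len({next(iter(g)) for g in groups}) == 3

    def test_k_equal_n_gives_singletons(self):
        templates = [(0.0, 1.0, 0.5, 0.2), (0.0, 0.2, 1.0, 0.5), (0.1, 0.3, 0.6, 1.0)]
        profiles = self._profiles_from_templates(templates, 1, 0.0, seed=1)
        labels = cluster_profiles(profiles, k=3)
        assert len(set(labels.values())) == 3

    def test_duplicate_profiles_share_a_label(self):
        base = RecruitmentProfile("a", self.T, (0.0, 0.5, 1.0, 0.7))
        dup = RecruitmentProfile("b", self.T, (0.0, 0.5, 1.0, 0.7))
        other = RecruitmentProfile("c", self.T, (1.0, 0.6, 0.3, 0.1))
        labels = cluster_profiles([base, dup, other], k=2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_zero_variance_profile_gets_singleton_with_warning(self, caplog):
        flat = RecruitmentProfile("flat", self.T, (1.0, 1.0, 1.0, 1.0))
        profiles = self._profiles_from_templates(
            [(0.0, 1.0, 0.5, 0.2), (0.0, 0.2, 1.0, 0.5)], 2, 0.02, seed=2
        ) + [flat]
        with caplog.at_level("WARNING"):
            labels = cluster_profiles(profiles, k=2)
        flat_label = labels["flat"]
        assert all(lab != flat_label for pid, lab in labels.items() if pid != "flat")
        assert any("zero variance" in r.message for r in caplog.records)

    def test_mismatched_grids_rejected(self):
        a = RecruitmentProfile("a", self.T, (0.0, 0.5, 1.0, 0.7))
        b = RecruitmentProfile("b", (0.0, 5.0, 10.0), (0.0, 0.5, 1.0))
        with pytest.raises(ValidationError):
            cluster_profiles([a, b, a], k=2)
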