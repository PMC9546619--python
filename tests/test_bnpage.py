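"""Gel-profile normalization, minimum detection, shift test, periodicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contextomics.bnpage import (
    BNPAGEProfile,
    NoMinimumError,
    comigration_matrix,
    detect_peaks_and_periodicity,
    early_late_shift,
    find_first_relative_minimum,
    normalize_profile_max,
    normalize_profile_to_fraction,
)
from contextomics.model import InsufficientDataError, ValidationError


def _profile(values, pid="P", cond="minusDUB", pad_to=10):
    values = list(values)
    if len(values) < pad_to:
        values = values + [0.0] * (pad_to - len(values))
    return BNPAGEProfile(pid, cond, tuple(float(v) for v in values))


def gaussian_profile(centers, n=70, sigma=1.0, heights=None):
    x = np.arange(1, n + 1, dtype=float)
    heights = heights or [1.0] * len(centers)
    y = np.zeros(n)
    for c, h in zip(centers, heights):
        y += h * np.exp(-((x - c) ** 2) / (2 * sigma**2))
    return _profile(y)


class TestNormalization:
    def test_max_normalization(self):
        prof = normalize_profile_max(_profile([2, 4, 8]))
        assert prof.intensities[:3] == (0.25, 0.5, 1.0)

    def test_idempotence(self):
        once = normalize_profile_max(_profile([2, 4, 8]))
        twice = normalize_profile_max(once)
        assert once.intensities == twice.intensities

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profile_max(_profile([0] * 10))

    def test_fraction_anchor(self):
        prof = normalize_profile_to_fraction(_profile([9, 6, 3, 6, 9]), 3)
        assert prof.intensities[:5] == (3.0, 2.0, 1.0, 2.0, 3.0)

    def test_anchor_at_max_equals_max_normalization(self):
        raw = _profile([1, 5, 10, 4, 2])
        assert normalize_profile_to_fraction(raw, 3).intensities == \
            normalize_profile_max(raw).intensities

    def test_zero_anchor_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profile_to_fraction(_profile([1, 0, 3]), 2)

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, scale):
        values = [1, 5, 10, 4, 2, 8, 3, 1, 1, 1]
        a = normalize_profile_max(_profile(values))
        b = normalize_profile_max(_profile([v * scale for v in values]))
        assert b.intensities == pytest.approx(a.intensities, rel=1e-9)


class TestFirstRelativeMinimum:
    def test_direct_definition_without_smoothing(self):
        prof = _profile([10, 7, 4, 6, 9, 3, 8])
        assert find_first_relative_minimum(prof, smoothing_window=1) == 3

    def test_monotone_profile_has_no_minimum(self):
        with pytest.raises(NoMinimumError):
            find_first_relative_minimum(
                _profile(range(1, 11)), smoothing_window=1
            )

    def test_plateau_resolves_to_earliest_index(self):
        prof = _profile([5, 2, 2, 6, 1, 7])
        assert find_first_relative_minimum(prof, smoothing_window=1) == 2

    def test_smoothing_suppresses_single_fraction_dip(self):
        # a one-fraction dip at index 3 disappears under a 3-wide window;
        # the deep valley at index 6 survives
        prof = _profile([10, 9.6, 3.0, 9.4, 9.0, 1.0, 1.2, 9.0, 9.5, 9.8])
        assert find_first_relative_minimum(prof, smoothing_window=3) == 6


class TestEarlyLateShift:
    def _pairs(self, n=20, seed=0):
        """Matched profiles: minus well-trapped, plus spread over the gel."""
        rng = np.random.default_rng(seed)
        minus, plus = {}, {}
        for i in range(n):
            pid = f"p{i}"
            m = np.zeros(12)
            m[:2] = rng.uniform(5, 10, 2)
            p = rng.uniform(0.5, 1.5, 12)
            minus[pid] = _profile(m, pid=pid, pad_to=12)
            plus[pid] = _profile(p, pid=pid, cond="plusDUB", pad_to=12)
        return minus, plus

    def test_shares_well_trapped_vs_uniform(self):
        minus = {"p": _profile([5, 5, 0, 0, 0, 0, 0, 0, 0, 0])}
        plus = {"p": _profile([1] * 10, cond="plusDUB")}
        res = early_late_shift(minus, plus, early_cutoff=5, min_proteins=1)
        assert res.shares_minus["p"] == 1.0
        assert res.shares_plus["p"] == 0.5

    def test_identical_profiles_give_p_one(self):
        prof = {f"p{i}": _profile([1, 2, 3, 4, 5, 4, 3, 2, 1, 1], pid=f"p{i}")
                for i in range(6)}
        res = early_late_shift(prof, prof)
        assert all(d == 0 for d in res.differences.values())
        assert res.p_value == 1.0

    def test_uniform_positive_differences_give_exact_signed_rank_p(self):
        minus, plus = self._pairs(n=20)
        res = early_late_shift(minus, plus)
        assert all(d > 0 for d in res.differences.values())
        # exact one-sided null for n=20 all-positive differences: 2^-20
        assert res.p_value == pytest.approx(2.0**-20)
        assert res.p_value < 0.01

    def test_too_few_matched_proteins_skips_test(self, caplog):
        minus, plus = self._pairs(n=3)
        with caplog.at_level("WARNING"):
            res = early_late_shift(minus, plus)
        assert res.p_value is None
        assert len(res.shares_minus) == 3

    def test_no_overlap_rejected(self):
        with pytest.raises(InsufficientDataError):
            early_late_shift({"a": _profile([1] * 10)}, {"b": _profile([1] * 10)})

    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=20, derandomize=True)
    def test_shares_invariant_to_profile_rescaling(self, scale):
        values = [5, 3, 1, 1, 0, 2, 0, 1, 0, 0]
        a = early_late_shift(
            {"p": _profile(values)}, {"p": _profile(values)}, min_proteins=1
        )
        b = early_late_shift(
            {"p": _profile([v * scale for v in values])},
            {"p": _profile(values)},
            min_proteins=1,
        )
        assert b.shares_minus["p"] == pytest.approx(a.shares_minus["p"], rel=1e-9)


class TestPeaksAndPeriodicity:
    def test_noiseless_triplet_recovered_exactly(self):
        prof = normalize_profile_max(gaussian_profile([10, 20, 30]))
        peaks = detect_peaks_and_periodicity(prof)
        assert peaks.peak_indices == (10, 20, 30)
        assert peaks.spacing_mean == 10.0
        assert peaks.spacing_cv == 0.0

    def test_flat_profile_has_no_peaks(self):
        peaks = detect_peaks_and_periodicity(_profile([1] * 20))
        assert peaks.peak_indices == ()
        assert peaks.spacing_mean is None

    def test_single_peak_has_undefined_spacing(self):
        prof = normalize_profile_max(gaussian_profile([15]))
        peaks = detect_peaks_and_periodicity(prof)
        assert peaks.peak_indices == (15,)
        assert peaks.spacings == ()
        assert peaks.spacing_cv is None

    def test_well_region_exclusion(self):
        prof = normalize_profile_max(gaussian_profile([2, 20, 30], heights=[5, 1, 1]))
        peaks = detect_peaks_and_periodicity(prof, exclude_well=3)
        assert peaks.peak_indices == (20, 30)

    def test_constant_height_ratio_of_decaying_ladder(self):
        prof = normalize_profile_max(
            gaussian_profile([10, 20, 30], heights=[1.0, 0.75, 0.75**2])
        )
        peaks = detect_peaks_and_periodicity(prof)
        assert peaks.peak_intensity_ratios == pytest.approx((0.75, 0.75), rel=1e-6)


class TestComigration:
    def test_identical_profiles_correlate_perfectly(self):
        a = _profile([1, 5, 2, 8, 3, 1, 0, 2, 1, 0], pid="a")
        b = _profile([1, 5, 2, 8, 3, 1, 0, 2, 1, 0], pid="b")
        corr = comigration_matrix([a, b])
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_reflection_about_mean_anticorrelates(self):
        values = np.array([1, 5, 2, 8, 3, 1, 0, 2, 1, 0], dtype=float)
        reflected = 2 * values.mean() - values
        reflected -= reflected.min()  # keep intensities non-negative; r unchanged
        corr = comigration_matrix(
            [_profile(values, pid="a"), _profile(reflected, pid="b")]
        )
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_template_pair_has_largest_off_diagonal(self):
        rng = np.random.default_rng(7)
        template = np.abs(np.sin(np.linspace(0, 3 * np.pi, 20))) + 0.1
        a = _profile(template + rng.normal(0, 0.02, 20), pid="a", pad_to=20)
        b = _profile(template + rng.normal(0, 0.02, 20), pid="b", pad_to=20)
        c = _profile(rng.uniform(0, 1, 20), pid="c", pad_to=20)
        corr = comigration_matrix([a, b, c])
        off = {("a", "b"): corr.loc["a", "b"], ("a", "c"): corr.loc["a", "c"],
               ("b", "c"): corr.loc["b", "c"]}
        assert max(off, key=off.get) == ("a", "b")

    def test_zero_variance_profile_reported_absent(self, caplog):
        a = _profile([1, 5, 2, 8, 3, 1, 0, 2, 1, 0], pid="a")
        flat = _profile([2] * 10, pid="flat")
        with caplog.at_level("WARNING"):
            corr = comigration_matrix([a, flat])
        assert np.isnan(corr.loc["a", "flat"])
        assert any("zero variance" in r.message for r in caplog.records)
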