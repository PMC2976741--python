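"""Feature extraction: derivations, statistics vs direct formulas, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypowatch.features import (
    FEATURE_NAMES,
    PAIR_ORDER,
    SERIES_ORDER,
    clinical_features,
    cross_correlation_features,
    derive_series,
    extract_features,
    statistical_features,
    wavelet_features,
)
from hypowatch.records import MedicationEvent
from hypowatch.windows import WindowSpec, compile_multiple

from conftest import make_flat_record


def obs_slices(n=30, hr=85.0, sbp=120.0, dbp=80.0, map_=95.0):
    return {
        "hr": np.full(n, hr),
        "sbp": np.full(n, sbp),
        "dbp": np.full(n, dbp),
        "map": np.full(n, map_),
    }


class TestDeriveSeries:
    def test_pp_and_co_formulas(self):
        six = derive_series(obs_slices(hr=60.0, sbp=120.0, dbp=80.0))
        assert six["pp"][0] == 40.0
        assert six["co"][0] == 2400.0

    def test_missing_input_propagates(self):
        s = obs_slices()
        s["dbp"][7] = np.nan
        six = derive_series(s)
        assert np.isnan(six["pp"][7]) and np.isnan(six["co"][7])
        assert not np.isnan(six["pp"][6])

    def test_six_series_same_length(self):
        six = derive_series(obs_slices(60))
        assert {len(v) for v in six.values()} == {60}


def naive_stats(values):
    """Direct-formula oracle for the eight statistics (no scipy/numpy helpers)."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = var**0.5
    srt = sorted(values)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(pos), min(int(pos) + 1, n - 1)
        return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

    med = quantile(0.5)
    iqr = quantile(0.75) - quantile(0.25)
    skew = (sum((v - mean) ** 3 for v in values) / n) / sd**3 if sd else 0.0
    kurt = (sum((v - mean) ** 4 for v in values) / n) / sd**4 if sd else 0.0
    sx = sum(range(n))
    sxx = sum(i * i for i in range(n))
    sxy = sum(i * v for i, v in enumerate(values))
    slope = (n * sxy - sx * sum(values)) / (n * sxx - sx * sx)
    return np.array([mean, med, sd, var, iqr, skew, kurt, slope])


class TestStatisticalFeatures:
    def test_constant_series_degenerate_conventions(self):
        out = statistical_features(np.full(30, 42.0))
        np.testing.assert_allclose(out, [42, 42, 0, 0, 0, 0, 0, 0], atol=1e-12)

    def test_linear_series_has_unit_slope(self):
        out = statistical_features(np.arange(30.0))
        assert out[7] == pytest.approx(1.0, abs=1e-10)

    def test_hand_computed_small_case(self):
        out = statistical_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out[0] == 2.5  # mean
        assert out[3] == 1.25  # population variance
        assert out[4] == 1.5  # IQR with linear-interpolation quantiles
        assert out[6] == pytest.approx(1.64)  # non-excess kurtosis

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_direct_formula_oracle(self, seed):
        values = np.random.default_rng(seed).normal(80, 10, 30)
        np.testing.assert_allclose(
            statistical_features(values), naive_stats(list(values)), rtol=1e-10
        )

    def test_missing_values_dropped_slope_uses_minute_index(self):
        series = np.arange(30.0) * 2.0
        series[5] = np.nan
        out = statistical_features(series)
        assert out[7] == pytest.approx(2.0, abs=1e-9)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            statistical_features(np.full(30, np.nan))


class TestCrossCorrelation:
    def test_all_ones_pair_is_one(self):
        six = {name: np.ones(4) for name in SERIES_ORDER}
        np.testing.assert_allclose(cross_correlation_features(six), np.ones(15))

    def test_two_point_arithmetic(self):
        six = {name: np.array([1.0, 2.0]) for name in SERIES_ORDER}
        six["sbp"] = np.array([2.0, 1.0])
        out = cross_correlation_features(six)
        idx = PAIR_ORDER.index(("hr", "sbp"))
        assert out[idx] == 2.0  # (1*2 + 2*1)/2

    def test_scaling_linearity(self):
        rng = np.random.default_rng(0)
        six = {name: rng.normal(size=30) for name in SERIES_ORDER}
        base = cross_correlation_features(six)
        six_scaled = dict(six, hr=3.0 * six["hr"])
        scaled = cross_correlation_features(six_scaled)
        hr_pairs = [i for i, p in enumerate(PAIR_ORDER) if "hr" in p]
        np.testing.assert_allclose(scaled[hr_pairs], 3.0 * base[hr_pairs], rtol=1e-12)
        rest = [i for i in range(15) if i not in hr_pairs]
        np.testing.assert_allclose(scaled[rest], base[rest])

    def test_jointly_present_minutes_only(self):
        six = {name: np.ones(4) for name in SERIES_ORDER}
        six["hr"] = np.array([np.nan, 2.0, 2.0, np.nan])
        out = cross_correlation_features(six)
        idx = PAIR_ORDER.index(("hr", "sbp"))
        assert out[idx] == 2.0  # mean of 2*1 over the two joint minutes


class TestWaveletFeatures:
    def test_normalization_with_interior_gap(self):
        series = np.sin(np.arange(30) / 3.0) + 80.0
        series[10:12] = np.nan
        rel = wavelet_features(series)
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)
        assert (rel >= 0).all()

    def test_edge_gap_nearest_extension(self):
        series = np.full(30, 80.0)
        series[0] = np.nan  # nearest-value extension keeps it constant
        rel = wavelet_features(series)
        assert rel[0] == pytest.approx(1.0, abs=1e-6)


class TestClinicalFeatures:
    def _example(self, record, spec=WindowSpec(30, 60)):
        return compile_multiple(record, spec)[0]  # obs window [0, 30)

    def test_no_events_zero_doses(self, flat_record):
        out = clinical_features(flat_record, self._example(flat_record))
        np.testing.assert_allclose(out, [60.0, 0.0, 0.0])

    def test_dose_inside_window_counted_by_group(self):
        meds = [
            MedicationEvent(minute_index=5, drug_name="dopamine", dose=5.0),
            MedicationEvent(minute_index=20, drug_name="lasix", dose=2.0),
            MedicationEvent(minute_index=20, drug_name="epinephrine", dose=1.5),
        ]
        record = make_flat_record(medications=meds)
        out = clinical_features(record, self._example(record))
        np.testing.assert_allclose(out, [60.0, 6.5, 2.0])

    def test_half_open_window_membership(self):
        meds = [
            MedicationEvent(minute_index=30, drug_name="lasix", dose=2.0),  # == obs_end
            MedicationEvent(minute_index=29, drug_name="lasix", dose=1.0),  # last minute
        ]
        record = make_flat_record(medications=meds)
        out = clinical_features(record, self._example(record))
        assert out[2] == 1.0


class TestExtractFeatures:
    def test_vector_length_and_names(self, small_cohort, default_spec):
        assert len(FEATURE_NAMES) == 102
        record = small_cohort.records[0]
        example = compile_multiple(record, default_spec)[0]
        assert extract_features(example, record).shape == (102,)

    def test_group_sizes_sum_to_102(self):
        stats = sum(1 for n in FEATURE_NAMES if n.split("_", 1)[-1] in
                    ("mean", "median", "sd", "var", "iqr", "skew", "kurt", "slope"))
        xcorr = sum(1 for n in FEATURE_NAMES if n.startswith("xcorr_"))
        wavelet = sum(1 for n in FEATURE_NAMES if "_Er_" in n)
        clinical = sum(1 for n in FEATURE_NAMES if n in ("age", "dose_raising", "dose_lowering"))
        assert (stats, xcorr, wavelet, clinical) == (48, 15, 36, 3)

    def test_determinism(self, small_cohort, default_spec):
        record = small_cohort.records[1]
        example = compile_multiple(record, default_spec)[0]
        np.testing.assert_array_equal(
            extract_features(example, record), extract_features(example, record)
        )

    def test_wavelet_energy_partition_inside_vector(self, small_cohort, default_spec):
        record = small_cohort.records[2]
        example = compile_multiple(record, default_spec)[0]
        vec = dict(zip(FEATURE_NAMES, extract_features(example, record)))
        for series in SERIES_ORDER:
            total = sum(vec[f"{series}_Er_{b}"] for b in ("a5", "d1", "d2", "d3", "d4", "d5"))
            assert total == pytest.approx(1.0, abs=1e-9)
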