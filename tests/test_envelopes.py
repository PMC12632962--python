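"""Centroid and uptake math against brute-force and closed-form oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hxms.envelopes import (
    CentroidSeries,
    MissingZeroError,
    centroid,
    compute_uptake,
    normalize_envelope,
    zero_reference,
)
from hxms.model import Envelope, HXMSError
from hxms.synthetic import binomial_pmf

TABLE_ENVELOPE = [0.527, 0.298, 0.116, 0.036, 0.000, 0.023, 0.000]


class TestNormalize:
    def test_simple_ratio(self):
        assert list(normalize_envelope([2, 1, 1])) == [0.5, 0.25, 0.25]

    def test_unit_sum_input_unchanged(self):
        out = list(normalize_envelope(TABLE_ENVELOPE))
        assert out == pytest.approx(TABLE_ENVELOPE, abs=1e-12)
        assert sum(out) == pytest.approx(1.0, abs=1e-9)

    def test_single_peak(self):
        assert list(normalize_envelope([5])) == [1.0]

    @pytest.mark.parametrize("bad", [[], [0.0, 0.0], [1.0, -0.1]])
    def test_degenerate_inputs_rejected(self, bad):
        with pytest.raises(HXMSError):
            normalize_envelope(bad)


class TestCentroid:
    def test_single_peak_is_origin(self):
        assert centroid(Envelope([1.0])) == 0.0

    def test_all_mass_on_second_peak(self):
        assert centroid(Envelope([0.0, 1.0])) == 1.0

    def test_worked_example_against_brute_force(self):
        # independent oracle: accumulate peak-by-peak without the library
        acc = 0.0
        for i in range(len(TABLE_ENVELOPE)):
            acc = acc + i * TABLE_ENVELOPE[i]
        assert acc == pytest.approx(0.753, abs=1e-12)
        assert centroid(Envelope(TABLE_ENVELOPE)) == pytest.approx(acc, abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20)
           .filter(lambda v: sum(v) > 1e-6), st.integers(1, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_translation_covariance(self, raw, k):
        base = normalize_envelope(raw)
        shifted = Envelope([0.0] * k + list(base))
        assert centroid(shifted) == pytest.approx(centroid(base) + k, abs=1e-9)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20)
           .filter(lambda v: sum(v) > 1e-6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_centroid_within_peak_range(self, raw):
        env = normalize_envelope(raw)
        assert -1e-12 <= centroid(env) <= len(env) - 1 + 1e-12

    @pytest.mark.parametrize("n", [1, 5, 12, 30])
    @pytest.mark.parametrize("p", [0.0, 0.3, 0.5, 0.9, 1.0])
    def test_binomial_envelope_recovers_mean(self, n, p):
        env = normalize_envelope(binomial_pmf(n, p))
        assert centroid(env) == pytest.approx(n * p, abs=1e-9)


class TestUptake:
    def test_subtracts_zero_centroid(self):
        series = CentroidSeries(key=(1, 10, "A", 0, "0000"),
                                points=[(0.0, 0.75), (60.0, 2.10)])
        out = compute_uptake(series)
        assert out[0] == (0.0, 0.0)
        assert out[1][1] == pytest.approx(1.35, abs=1e-12)

    def test_zero_timepoint_uptake_is_exactly_zero(self):
        series = CentroidSeries(key=(1, 10, "A", 0, "0000"),
                                points=[(0.0, 0.7531234)])
        assert compute_uptake(series) == [(0.0, 0.0)]

    def test_missing_zero_without_reference_raises(self):
        series = CentroidSeries(key=(1, 10, "A", 2, "0000"),
                                points=[(60.0, 2.10)])
        with pytest.raises(MissingZeroError, match=r"\(1, 10, 'A', 2, '0000'\)"):
            compute_uptake(series)

    def test_supplied_reference_used_when_no_zero(self):
        series = CentroidSeries(key=(1, 10, "A", 2, "0000"),
                                points=[(60.0, 2.10)])
        assert compute_uptake(series, zero_reference=0.75) == \
            [(60.0, pytest.approx(1.35, abs=1e-12))]


class TestZeroReference:
    @staticmethod
    def _series(rep, points):
        return CentroidSeries(key=(1, 10, "A", rep, "0000"), points=points)

    def test_replicate_missing_zero_gets_mean_of_others(self):
        group = [
            self._series(0, [(0.0, 0.70), (60.0, 2.0)]),
            self._series(1, [(0.0, 0.80), (60.0, 2.1)]),
            self._series(2, [(60.0, 2.2)]),
        ]
        refs = zero_reference(group)
        assert refs == {0: 0.70, 1: 0.80, 2: pytest.approx(0.75, abs=1e-12)}

    def test_single_replicate_uses_itself(self):
        refs = zero_reference([self._series(0, [(0.0, 0.7)])])
        assert refs == {0: 0.7}

    def test_no_zero_anywhere_raises(self):
        group = [self._series(0, [(60.0, 2.0)]), self._series(1, [(60.0, 2.1)])]
        with pytest.raises(MissingZeroError):
            zero_reference(group)


def test_zero_uptake_across_fixture_corpus(corpus):
    for file in corpus:
        zero_records = [r for r in file.records if r.time_sec == 0.0]
        assert zero_records
        assert all(r.uptake == 0.0 for r in zero_records)
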