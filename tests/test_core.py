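"""Unit and property tests for the damage estimator and conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lordq as lq
from lordq.core import MAX_EFFICIENCY


def ct(x):
    return lq.CtValue(cycles=x)


CENSORED = lq.CtValue(censored=True)


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "wells, expected",
        [
            ([ct(20.0), ct(20.0), ct(20.0)], (20.0, 0.0, 3)),
            ([ct(19.8), ct(20.0), ct(20.2)], (20.0, 0.2, 3)),
            ([ct(19.8), ct(20.2), CENSORED], (20.0, math.sqrt(0.08), 2)),
            ([ct(21.5)], (21.5, 0.0, 1)),
        ],
    )
    def test_mean_sd_n(self, wells, expected):
        mean, sd, n = lq.aggregate_replicates(wells)
        assert mean == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1])
        assert n == expected[2]

    def test_all_censored_raises_distinct_error(self):
        with pytest.raises(lq.UnquantifiableSampleError):
            lq.aggregate_replicates([CENSORED, CENSORED, CENSORED])

    def test_outlier_rejection_optional_and_off_by_default(self):
        wells = [ct(20.0), ct(20.1), ct(23.0)]
        mean_default, _, n_default = lq.aggregate_replicates(wells)
        assert n_default == 3 and mean_default == pytest.approx(21.033333, abs=1e-6)
        mean_qc, _, n_qc = lq.aggregate_replicates(wells, drop_outliers=True)
        assert n_qc == 2 and mean_qc == pytest.approx(20.05)


def direct_lesion_rate(sample, controls, eff, a):
    """Naive evaluation of the printed geometric-mean product form."""
    num = eff.e_long ** sample.ct_long_mean * eff.e_short ** (-sample.ct_short_mean)
    prod = 1.0
    for c in controls.controls:
        prod *= eff.e_long ** c.ct_long_mean * eff.e_short ** (-c.ct_short_mean)
    denom = prod ** (1.0 / controls.n)
    return 1e4 * ((num / denom) ** (1.0 / a) - 1.0)


class TestLesionRate:
    def test_sample_equal_to_single_control_is_exactly_zero(
        self, single_control, default_eff
    ):
        sample = lq.SampleCtSummary("s", "uv", 20.0, 15.0)
        res = lq.lesion_rate(sample, single_control, default_eff)
        assert res.lesions_per_10kb == 0.0

    @pytest.mark.parametrize(
        "ct_long, ct_short, expected",
        [
            (21.0, 15.0, 1.7140),   # one extra long cycle: 1e4*(1.82^(1/3494)-1)
            (21.0, 16.0, -0.2411),  # 1e4*((1.82/1.98)^(1/3494)-1), signed
        ],
    )
    def test_worked_cases_match_independent_arithmetic(
        self, single_control, default_eff, ct_long, ct_short, expected
    ):
        sample = lq.SampleCtSummary("s", "uv", ct_long, ct_short)
        res = lq.lesion_rate(sample, single_control, default_eff)
        assert res.lesions_per_10kb == pytest.approx(expected, abs=1e-4)

    def test_two_controls_halve_the_delta(self, default_eff):
        controls = lq.ControlSet([
            lq.SampleCtSummary("c1", "control", 20.0, 15.0),
            lq.SampleCtSummary("c2", "control", 21.0, 15.0),
        ])
        sample = lq.SampleCtSummary("s", "uv", 21.0, 15.0)
        res = lq.lesion_rate(sample, controls, default_eff)
        # exponent 0.5/3494 instead of 1/3494
        assert res.lesions_per_10kb == pytest.approx(0.8570, abs=5e-5)

    def test_control_order_invariance(self, default_eff, rng):
        controls = [
            lq.SampleCtSummary(f"c{i}", "control", 20 + rng.uniform(-1, 1),
                               15 + rng.uniform(-1, 1))
            for i in range(5)
        ]
        sample = lq.SampleCtSummary("s", "uv", 22.0, 15.3)
        a = lq.lesion_rate(sample, lq.ControlSet(controls), default_eff)
        b = lq.lesion_rate(sample, lq.ControlSet(controls[::-1]), default_eff)
        assert a.lesions_per_10kb == pytest.approx(b.lesions_per_10kb, rel=1e-14)

    def test_replicated_control_collapse(self, default_eff):
        c = lq.SampleCtSummary("c", "control", 20.4, 15.1)
        sample = lq.SampleCtSummary("s", "uv", 22.0, 15.0)
        one = lq.lesion_rate(sample, lq.ControlSet([c]), default_eff)
        four = lq.lesion_rate(sample, lq.ControlSet([c] * 4), default_eff)
        assert one.lesions_per_10kb == pytest.approx(four.lesions_per_10kb, rel=1e-12)

    @given(
        d_long=st.floats(0.01, 5.0),
        d_short=st.floats(0.01, 5.0),
        base_long=st.floats(15.0, 30.0),
        base_short=st.floats(10.0, 25.0),
    )
    def test_monotone_in_sample_cts(self, d_long, d_short, base_long, base_short):
        """More long-Ct means more damage; more short-Ct means less."""
        eff = lq.EfficiencyPair(1.82, 1.98)
        controls = lq.ControlSet(
            [lq.SampleCtSummary("c", "control", base_long, base_short)]
        )
        ref = lq.lesion_rate(
            lq.SampleCtSummary("s", "g", base_long, base_short), controls, eff
        ).lesions_per_10kb
        up_long = lq.lesion_rate(
            lq.SampleCtSummary("s", "g", base_long + d_long, base_short),
            controls, eff,
        ).lesions_per_10kb
        up_short = lq.lesion_rate(
            lq.SampleCtSummary("s", "g", base_long, base_short + d_short),
            controls, eff,
        ).lesions_per_10kb
        assert up_long > ref > up_short

    @given(
        n_controls=st.integers(1, 5),
        data=st.data(),
    )
    def test_log_space_matches_direct_product_form(self, n_controls, data):
        cts = st.floats(5.0, 40.0)
        eff = lq.EfficiencyPair(
            data.draw(st.floats(1.5, 2.0), label="e_long"),
            data.draw(st.floats(1.5, 2.0), label="e_short"),
        )
        controls = lq.ControlSet([
            lq.SampleCtSummary(f"c{i}", "control", data.draw(cts), data.draw(cts))
            for i in range(n_controls)
        ])
        sample = lq.SampleCtSummary("s", "g", data.draw(cts), data.draw(cts))
        ours = lq.lesion_rate(sample, controls, eff).lesions_per_10kb
        naive = direct_lesion_rate(sample, controls, eff, 3494)
        assert ours == pytest.approx(naive, rel=1e-10, abs=1e-10)

    def test_snapshot_reproduces_the_estimate(self, single_control, default_eff):
        sample = lq.SampleCtSummary("s", "uv", 23.1, 15.4)
        res = lq.lesion_rate(sample, single_control, default_eff)
        snap = res.inputs_snapshot
        rebuilt = 1e4 * math.expm1(
            (math.log(snap["e_long"]) * (snap["ct_long_mean"] - snap["control_mean_ct_long"])
             - math.log(snap["e_short"]) * (snap["ct_short_mean"] - snap["control_mean_ct_short"]))
            / snap["long_length_bp"]
        )
        assert rebuilt == pytest.approx(res.lesions_per_10kb, rel=1e-14)

    def test_contract_errors(self, single_control, default_eff):
        nan_sample = lq.SampleCtSummary("s", "g", float("nan"), 15.0)
        with pytest.raises(ValueError):
            lq.lesion_rate(nan_sample, single_control, default_eff)
        with pytest.raises(ValueError):
            lq.ControlSet([])
        with pytest.raises(ValueError):
            lq.EfficiencyPair(e_long=1.0, e_short=1.98)
        with pytest.raises(ValueError):
            lq.EfficiencyPair(e_long=1.82, e_short=MAX_EFFICIENCY + 0.01)

    def test_efficiency_above_two_warns_but_is_accepted(self):
        with pytest.warns(lq.EfficiencyWarning):
            eff = lq.EfficiencyPair(e_long=1.82, e_short=2.05)
        assert eff.e_short == 2.05


class TestFragmentConversion:
    @pytest.mark.parametrize(
        "length, expected_2dp",
        [(3301, 3.03), (10000, 1.00), (2438, 4.10)],
    )
    def test_breaks_from_length(self, length, expected_2dp):
        breaks = lq.fragment_length_to_breaks(
            lq.FragmentProfile("f", length)
        )
        assert round(breaks, 2) == expected_2dp

    @pytest.mark.parametrize(
        "breaks, expected_bp",
        [(1.0, 10000.0), (10000.0 / 3301, 3301.0), (5.0, 2000.0)],
    )
    def test_length_from_breaks(self, breaks, expected_bp):
        assert lq.breaks_to_fragment_length(breaks) == pytest.approx(expected_bp)

    @given(st.floats(1.0, 1e7))
    def test_round_trip(self, length):
        back = lq.breaks_to_fragment_length(lq.fragment_length_to_breaks(length))
        assert back == pytest.approx(length, rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lq.fragment_length_to_breaks(0.0)
        with pytest.raises(ValueError):
            lq.breaks_to_fragment_length(-1.0)
        with pytest.raises(ValueError):
            lq.FragmentProfile("f", -5.0)


class TestDomainTypes:
    def test_amplicon_geometry_validated(self):
        with pytest.raises(ValueError):
            lq.AmpliconPair(long_length_bp=66, short_length_bp=66)
        pair = lq.AmpliconPair()
        assert (pair.long_length_bp, pair.short_length_bp) == (3494, 66)

    def test_ct_value_bounds(self):
        with pytest.raises(ValueError):
            lq.CtValue(cycles=41.0)  # beyond the 40-cycle programme
        with pytest.raises(ValueError):
            lq.CtValue(cycles=float("nan"))
        assert lq.CtValue(censored=True).censored

    def test_summary_needs_replicates(self):
        with pytest.raises(ValueError):
            lq.SampleCtSummary("s", "g", 20.0, 15.0, n_long=0)
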