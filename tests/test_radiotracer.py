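"""Radiotracer turnover rates, pool inventories and detection limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotbio import radiotracer as rt


def make_vial(**overrides) -> rt.IncubationVial:
    base = dict(
        sample_id="V1",
        assay=rt.Assay.SR,
        depth=500.0,
        activity_product=50.0,
        activity_substrate=50.0,
        pool_total=1e-6,
        bulk_density=2.0,
        incubation_time=10.0,
        sediment_mass=5.0,
        fractionation_factor=1.0,
    )
    base.update(overrides)
    return rt.IncubationVial(**base)


class TestTurnoverRate:
    def test_no_product_formed_gives_zero_rate(self):
        res = rt.turnover_rate(make_vial(activity_product=0.0, activity_substrate=100.0))
        assert res.rate == 0.0
        assert res.turnover_fraction == 0.0

    def test_direct_arithmetic(self):
        # fraction 0.5, pool 1e-6 mol, alpha 1, rho 2, t 10 d, m 5 g
        # -> 0.5e-6 * 2 / 50 = 2e-8 mol cm-3 d-1 = 2e4 pmol cm-3 d-1
        res = rt.turnover_rate(make_vial())
        assert res.turnover_fraction == pytest.approx(0.5)
        assert res.rate == pytest.approx(2e4)

    def test_isotope_fractionation_correction_scales_rate(self):
        plain = rt.turnover_rate(make_vial(fractionation_factor=1.0))
        corrected = rt.turnover_rate(make_vial(fractionation_factor=1.06))
        assert corrected.rate / plain.rate == pytest.approx(1.06)

    def test_assay_defaults_for_alpha(self):
        assert make_vial(fractionation_factor=None).alpha == 1.06
        assert make_vial(assay=rt.Assay.MG, fractionation_factor=None).alpha == 1.08

    @pytest.mark.parametrize(
        "field,factor",
        [("pool_total", 3.0), ("bulk_density", 3.0)],
    )
    def test_rate_linear_in_pool_and_density(self, field, factor):
        base = rt.turnover_rate(make_vial())
        scaled = rt.turnover_rate(make_vial(**{field: getattr(make_vial(), field) * factor}))
        assert scaled.rate / base.rate == pytest.approx(factor)

    @pytest.mark.parametrize(
        "field,factor",
        [("incubation_time", 4.0), ("sediment_mass", 4.0)],
    )
    def test_rate_inverse_linear_in_time_and_mass(self, field, factor):
        base = rt.turnover_rate(make_vial())
        scaled = rt.turnover_rate(make_vial(**{field: getattr(make_vial(), field) * factor}))
        assert base.rate / scaled.rate == pytest.approx(factor)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_turnover_fraction_invariant_under_activity_rescaling(self, scale):
        a = rt.turnover_rate(make_vial(activity_product=30.0, activity_substrate=70.0))
        b = rt.turnover_rate(
            make_vial(activity_product=30.0 * scale, activity_substrate=70.0 * scale)
        )
        assert b.turnover_fraction == pytest.approx(a.turnover_fraction, rel=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(incubation_time=0.0),
            dict(sediment_mass=-1.0),
            dict(bulk_density=0.0),
            dict(pool_total=0.0),
            dict(activity_product=0.0, activity_substrate=0.0),
            dict(activity_product=-1.0),
        ],
    )
    def test_invalid_vials_rejected(self, bad):
        with pytest.raises(ValueError):
            make_vial(**bad)


class TestTotalPool:
    def test_medium_only(self):
        # 5 mmol/L in 5 mL of medium, no porewater contribution
        assert rt.total_pool_moles(5e-3, 5.0) == pytest.approx(2.5e-5)

    def test_medium_plus_porewater(self):
        # 0.677 mmol/L DIC medium in 5 mL + 1 mmol/L porewater in
        # 0.35 * 5 mL pore volume
        pool = rt.total_pool_moles(0.677e-3, 5.0, 1e-3, 5.0, 0.35)
        assert pool == pytest.approx(3.385e-6 + 1.75e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rt.total_pool_moles(-1e-3, 5.0)

    def test_counts_helper_passthrough_and_efficiency(self):
        assert rt.counts_to_becquerel(60.0) == pytest.approx(1.0)
        assert rt.counts_to_becquerel(60.0, 0.5) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            rt.counts_to_becquerel(60.0, 0.0)


def killed(values, assay=rt.Assay.SR) -> rt.ControlSeries:
    return rt.ControlSeries(rt.ControlType.killed, assay, tuple(values))


class TestMbql:
    def test_zero_spread_gives_the_common_value(self):
        assert rt.mbql(killed([0.04, 0.04, 0.04])).mbql == pytest.approx(0.04)

    def test_hand_computed_sample_sd(self):
        # mean 0.03, sample sd 0.02 -> 0.03 + 3*0.02 = 0.09
        limit = rt.mbql(killed([0.01, 0.03, 0.05]))
        assert limit.mean_killed == pytest.approx(0.03)
        assert limit.sd_killed == pytest.approx(0.02)
        assert limit.mbql == pytest.approx(0.09)

    def test_population_sd_convention_is_lower(self):
        sample = rt.mbql(killed([0.01, 0.03, 0.05]), "sample").mbql
        popn = rt.mbql(killed([0.01, 0.03, 0.05]), "population").mbql
        assert popn < sample

    def test_requires_killed_series_with_two_values(self):
        with pytest.raises(ValueError):
            rt.mbql(killed([0.03]))
        with pytest.raises(ValueError):
            rt.mbql(rt.ControlSeries(rt.ControlType.medium, rt.Assay.SR, (0.1, 0.2)))

    # NOTE: mean + 3*SD is not monotone in every individual value (raising a
    # value far below the mean shrinks the SD faster than it lifts the mean),
    # so the meaningful monotonicity properties are equivariance under shift
    # and scale and monotonicity in the largest value.
    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8),
        shift=st.floats(0.0, 2.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mbql_equivariance_under_shift_and_scale(self, values, shift, scale):
        base = rt.mbql(killed(values)).mbql
        shifted = rt.mbql(killed([v + shift for v in values])).mbql
        scaled = rt.mbql(killed([v * scale for v in values])).mbql
        assert shifted == pytest.approx(base + shift, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)

    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8),
        bump=st.floats(1e-6, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_mbql_nondecreasing_in_the_largest_value(self, values, bump):
        lo = rt.mbql(killed(values)).mbql
        bumped = list(values)
        bumped[int(np.argmax(bumped))] += bump
        hi = rt.mbql(killed(bumped)).mbql
        assert hi >= lo - 1e-12


def result(rate, assay=rt.Assay.SR) -> rt.RateResult:
    return rt.RateResult("S", assay, 100.0, rate, 0.5)


class TestCensor:
    def test_below_limit_censored_above_not(self):
        limit = rt.DetectionLimit(rt.Assay.SR, 0.09, 0.03, 0.02)
        out = rt.censor([result(0.05), result(0.5)], limit)
        assert [r.censored for r in out] == [True, False]
        assert all(r.limit_used == pytest.approx(0.09) for r in out)

    def test_exactly_at_limit_is_not_censored(self):
        limit = rt.DetectionLimit(rt.Assay.SR, 0.09, 0.03, 0.02)
        (out,) = rt.censor([result(0.09)], limit)
        assert not out.censored

    def test_counts_match_brute_force_filter(self):
        rng = np.random.default_rng(7)
        rates = rng.exponential(0.2, 100)
        limit = rt.DetectionLimit(rt.Assay.SR, 0.09, 0.03, 0.02)
        out = rt.censor([result(r) for r in rates], limit)
        assert sum(not r.censored for r in out) == int((rates >= 0.09).sum())
        # censoring flags, never deletes
        assert [r.rate for r in out] == pytest.approx(list(rates))

    def test_assay_mismatch_rejected(self):
        limit = rt.DetectionLimit(rt.Assay.MG, 0.09, 0.03, 0.02)
        with pytest.raises(ValueError):
            rt.censor([result(0.5)], limit)


class TestControlConsistency:
    @staticmethod
    def series(ctype, values, assay=rt.Assay.SR):
        return rt.ControlSeries(ctype, assay, tuple(values))

    def test_identical_series_all_pass(self):
        vals = [0.1, 0.12, 0.11]
        report = rt.control_consistency(
            [
                self.series(rt.ControlType.medium, vals),
                self.series(rt.ControlType.drill_fluid, vals),
                self.series(rt.ControlType.killed, vals),
            ]
        )
        assert all(entry["within_one_sd"] for entry in report.values())

    def test_large_shift_flagged(self):
        medium = self.series(rt.ControlType.medium, [0.1, 0.12, 0.11])
        sd = medium.sd()
        shifted = self.series(rt.ControlType.drill_fluid, [v + 5 * sd for v in (0.1, 0.12, 0.11)])
        report = rt.control_consistency([medium, shifted])
        assert not report[("SR", "drill_fluid")]["within_one_sd"]

    def test_flags_match_direct_evaluation(self):
        rng = np.random.default_rng(11)
        medium = self.series(rt.ControlType.medium, rng.normal(0.1, 0.02, 6).clip(0))
        others = [
            self.series(ct, rng.normal(0.1, 0.05, 6).clip(0))
            for ct in (rt.ControlType.drill_fluid, rt.ControlType.sediment, rt.ControlType.killed)
        ]
        report = rt.control_consistency([medium, *others])
        for s in others:
            expected = abs(s.mean() - medium.mean()) <= medium.sd()
            assert report[("SR", s.control_type.value)]["within_one_sd"] == expected

    def test_missing_medium_series_rejected(self):
        with pytest.raises(ValueError, match="medium"):
            rt.control_consistency([self.series(rt.ControlType.killed, [0.1, 0.2])])
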