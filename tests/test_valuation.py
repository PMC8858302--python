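"""Valuation: discount kernel oracle, VSL transfer, streams, BCA identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutribca import (
    ag_base_value,
    agriculture_benefit,
    bca_summary,
    bca_table,
    calibrate_ag_base,
    growth_discount_sum,
    mortality_benefit,
    productivity_benefit,
    vsl_transfer,
)


def gds_loop(g, d, t0, t1, s):
    """Explicit year-by-year oracle for the growth-discount sum."""
    return sum((s * (1 + g) ** t + (1 - s)) / (1 + d) ** t for t in range(t0, t1 + 1))


class TestGrowthDiscountSum:
    def test_equal_rates_full_growth(self):
        assert growth_discount_sum(0.05, 0.05, 1, 20, 1.0) == pytest.approx(20.0)

    def test_no_growth_is_annuity(self):
        # closed-form 20-year annuity at 3%
        assert growth_discount_sum(0.0, 0.03, 1, 20, 0.7) == pytest.approx(14.877, abs=5e-4)

    def test_working_life_window(self):
        got = growth_discount_sum(0.0446, 0.03, 14, 58, 1.0)
        assert got == pytest.approx(gds_loop(0.0446, 0.03, 14, 58, 1.0), rel=1e-12)
        assert got == pytest.approx(75.94, abs=0.01)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            growth_discount_sum(0.03, 0.03, 5, 4)

    def test_vectorized_matches_scalar(self):
        g = np.array([0.02, 0.0446, 0.07])
        out = growth_discount_sum(g, 0.10, 1, 20, 0.5)
        for gi, oi in zip(g, out):
            assert oi == pytest.approx(growth_discount_sum(float(gi), 0.10, 1, 20, 0.5), rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        g=st.floats(-0.05, 0.15),
        d=st.floats(0.0, 0.25),
        t0=st.integers(0, 30),
        span=st.integers(0, 40),
        s=st.floats(0.0, 1.0),
    )
    def test_oracle_equivalence(self, g, d, t0, span, s):
        t1 = t0 + span
        assert growth_discount_sum(g, d, t0, t1, s) == pytest.approx(
            gds_loop(g, d, t0, t1, s), rel=1e-12
        )

    @settings(max_examples=50, derandomize=True)
    @given(g=st.floats(0.0, 0.1), d=st.floats(0.0, 0.2))
    def test_full_growth_matches_geometric_closed_form(self, g, d):
        q = (1 + g) / (1 + d)
        t0, t1 = 1, 20
        if abs(q - 1) < 1e-12:
            closed = t1 - t0 + 1
        else:
            closed = q**t0 * (1 - q ** (t1 - t0 + 1)) / (1 - q)
        assert growth_discount_sum(g, d, t0, t1, 1.0) == pytest.approx(closed, rel=1e-9)


class TestVSLTransfer:
    def test_us_extrapolation(self, base):
        est = vsl_transfer("us_extrapolation", base)
        assert est.value_intl == pytest.approx(28_751, abs=1)
        assert est.value_usd == pytest.approx(7_389, abs=1)

    def test_ratio_methods_exact(self, base):
        assert vsl_transfer("us_ratio", base).value_intl == 195_200
        assert vsl_transfer("oecd_ratio", base).value_intl == 122_000

    def test_vsly(self, base):
        est = vsl_transfer("vsly", base)
        assert est.value_intl == pytest.approx(53_844, abs=1)
        assert est.value_usd == pytest.approx(13_838, abs=1)

    def test_usd_is_intl_times_ppp_ratio(self, base):
        for m in ("us_extrapolation", "vsly", "us_ratio", "oecd_ratio"):
            est = vsl_transfer(m, base)
            assert est.value_usd == pytest.approx(est.value_intl * 0.257, rel=1e-9)

    def test_increasing_in_gni_decreasing_in_elasticity(self, base):
        richer = base.model_copy(update={"gni_pc_ppp_mwi": 2000.0})
        assert vsl_transfer("us_extrapolation", richer).value_intl > vsl_transfer(
            "us_extrapolation", base
        ).value_intl
        flatter = base.model_copy(update={"income_elasticity": 1.0})
        assert vsl_transfer("us_extrapolation", flatter).value_intl > vsl_transfer(
            "us_extrapolation", base
        ).value_intl

    def test_unknown_method(self, base):
        with pytest.raises(ValueError):
            vsl_transfer("guesswork", base)


class TestMortality:
    def test_published_value(self, base):
        vsl = vsl_transfer("us_extrapolation", base).value_usd
        assert round(mortality_benefit(base.deaths_averted_unrounded, vsl)) == pytest.approx(
            79_653, abs=10
        )

    def test_identity_and_zero(self):
        assert mortality_benefit(0, 7389) == 0
        assert mortality_benefit(1, 50_166) == 50_166


class TestProductivity:
    @pytest.mark.parametrize(
        "d,published,rel",
        [(0.03, 4_616_473, 0.001), (0.05, 2_276_826, 0.005), (0.10, 528_044, 0.005)],
    )
    def test_published_streams(self, base, d, published, rel):
        assert productivity_benefit(base, d) == pytest.approx(published, rel=rel)

    def test_zero_premium_gives_zero(self, base):
        p = base.model_copy(update={"wage_premium": 0.0})
        assert productivity_benefit(p, 0.03) == 0.0


class TestAgriculture:
    def test_ag_base_value_arithmetic(self):
        assert ag_base_value({"ofsp": 10}, {"ofsp": 0.21}, 900) == pytest.approx(1_890)
        assert ag_base_value({}, {"ofsp": 0.21}, 900) == 0.0

    def test_missing_price_rejected(self):
        with pytest.raises(ValueError, match="ofsp"):
            ag_base_value({"ofsp": 10}, {"beans": 0.7}, 900)

    def test_calibration(self, base):
        annual = calibrate_ag_base(179_509, base, 0.03)
        assert annual == pytest.approx(9_413, abs=1)
        assert annual == pytest.approx(base.ag_base_annual_value, rel=1e-12)

    def test_calibration_round_trip(self, base):
        assert agriculture_benefit(base, 0.03) == pytest.approx(179_509, abs=1)

    @pytest.mark.parametrize("d,published", [(0.05, 147_636), (0.10, 97_270)])
    def test_cross_rate_consistency(self, base, d, published):
        # base calibrated at 3% must land on the published 5%/10% values:
        # structural check of the mixed sold/consumed growth model
        assert agriculture_benefit(base, d) == pytest.approx(published, rel=0.005)

    def test_zero_base_gives_zero(self, base):
        p = base.model_copy(update={"ag_base_annual_value": 0.0})
        assert agriculture_benefit(p, 0.05) == 0.0


class TestBCA:
    @pytest.mark.parametrize(
        "d,total,net,bcr",
        [
            (0.03, 4_875_635, 4_678_258, 24.70),
            (0.05, 2_504_115, 2_306_737, 12.69),
            (0.10, 704_967, 507_589, 3.57),
        ],
    )
    def test_published_summaries(self, base, d, total, net, bcr):
        r = bca_summary(base, d)
        assert r.total_benefit == pytest.approx(total, rel=0.001)
        assert r.net_benefit == pytest.approx(net, rel=0.005)
        assert round(r.bcr, 2) == bcr

    def test_identities_exact(self, base):
        r = bca_summary(base, 0.05)
        s = r.streams
        assert r.total_benefit == s.mortality + s.productivity + s.agriculture
        assert r.net_benefit == r.total_benefit - r.total_cost
        assert r.bcr == r.total_benefit / r.total_cost
        assert (r.bcr > 1) == (r.net_benefit > 0)

    def test_zero_streams(self, base):
        p = base.model_copy(
            update={
                "deaths_averted_unrounded": 0.0,
                "stunting_cases_averted": 0.0,
                "wage_premium": 0.0,
                "ag_base_annual_value": 0.0,
            }
        )
        r = bca_summary(p, 0.10)
        assert r.net_benefit == pytest.approx(-197_377)
        assert r.bcr == 0.0

    def test_streams_non_increasing_in_rate(self, base):
        rates = [0.0, 0.02, 0.03, 0.05, 0.08, 0.10, 0.15]
        tbl = bca_table(base, rates)
        for col in ("productivity", "agriculture", "total_benefit"):
            assert tbl[col].is_monotonic_decreasing, col
        assert tbl["mortality"].nunique() == 1  # valued at time of aversion
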