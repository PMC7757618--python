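import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iddburden import (
    EconParams,
    annual_earnings,
    annuity_factor,
    cohort_npv_loss,
    derive_deficit_fraction,
    npv_loss,
    work_life_years,
)


def _annuity_closed_form(r, delay, w):
    """Geometric-series oracle for whole work lives: (1/r) * ((1+r)^-(delay-1)
    - (1+r)^-(delay-1+w))."""
    if r == 0:
        return float(w)
    return (1 / r) * ((1 + r) ** -(delay - 1) - (1 + r) ** -(delay - 1 + w))


def _annuity_brute_force(r, delay, w):
    total, t, remaining = 0.0, delay, w
    while remaining > 1e-12:
        year = min(1.0, remaining)
        total += year * (1 + r) ** -t
        t += 1
        remaining -= year
    return total


class TestDeficitChain:
    def test_published_coefficients_give_literal_product(self):
        d = derive_deficit_fraction(8.18, 1.18, 0.64)
        assert d == pytest.approx(0.061775, abs=1e-6)
        # brackets the published chain value (0.0612) and the literal product
        assert 0.0612 <= round(d, 4) <= 0.0618

    @pytest.mark.parametrize(
        "args,expected", [((10, 1, 1), 0.10), ((0, 5, 0.5), 0.0)]
    )
    def test_degenerate_products(self, args, expected):
        assert derive_deficit_fraction(*args) == pytest.approx(expected)

    def test_params_default_to_published_chain_value(self):
        p = EconParams()
        assert p.deficit() == 0.0612
        assert p.deficit(derived=True) == pytest.approx(0.061775, abs=1e-6)


class TestEarningsAndWorkLife:
    def test_earnings_is_gni_times_wage_share(self):
        assert annual_earnings(2000.0, 0.5) == 1000.0
        assert annual_earnings(0.0, 0.5) == 0.0
        assert annual_earnings(1592.0, 0.72) == pytest.approx(1146.24)

    def test_work_life_is_hale_minus_entry_age(self):
        assert work_life_years(60.0, 15) == 45.0
        assert work_life_years(15.5, 15) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            work_life_years(15.0, 15)


class TestAnnuityFactor:
    def test_undiscounted_equals_work_life(self):
        assert annuity_factor(0.0, 0, 10.0) == 10.0
        assert annuity_factor(0.0, 11, 37.5) == 37.5

    def test_published_discounting_convention(self):
        # 3% rate, cohort enters work 11 years after the reference year
        value = annuity_factor(0.03, 11, 45.0)
        assert value == pytest.approx(18.244, abs=0.001)
        assert value == pytest.approx(_annuity_closed_form(0.03, 11, 45), rel=1e-12)

    def test_payment_at_reference_year_is_undiscounted(self):
        assert annuity_factor(0.03, 0, 1.0) == 1.0

    @pytest.mark.parametrize("r", [0.0, 0.01, 0.03, 0.1])
    @pytest.mark.parametrize("delay", [0, 11])
    def test_matches_brute_force_summation_over_work_life_grid(self, r, delay):
        for w in range(1, 61):
            assert annuity_factor(r, delay, float(w)) == pytest.approx(
                _annuity_brute_force(r, delay, w), abs=1e-10
            )
            if r > 0:
                assert annuity_factor(r, delay, float(w)) == pytest.approx(
                    _annuity_closed_form(r, delay, w), abs=1e-10
                )

    def test_fractional_final_year_is_prorated(self):
        r = 0.03
        assert annuity_factor(r, 0, 1.5) == pytest.approx(
            1.0 + 0.5 * (1 + r) ** -1, rel=1e-12
        )

    def test_monotonicities(self):
        base = annuity_factor(0.03, 11, 45.0)
        assert annuity_factor(0.05, 11, 45.0) < base  # decreasing in rate
        assert annuity_factor(0.03, 12, 45.0) < base  # decreasing in delay
        assert annuity_factor(0.03, 11, 46.0) > base  # increasing in work life

    def test_payments_at_start_shifts_one_year_earlier(self):
        r = 0.03
        assert annuity_factor(r, 11, 45.0, payments_at_start=True) == pytest.approx(
            annuity_factor(r, 11, 45.0) * (1 + r), rel=1e-12
        )


class TestNPVLoss:
    def test_regional_cohort_with_unit_annuity(self):
        # newborn cohort of 1.74 million, 71.8% participation, 1146 USD/yr
        loss = npv_loss(1740.0, 0.718, 1146.0, 0.0612, 1.0)
        assert loss.npv_loss_usd_thousands == pytest.approx(87_621.3, abs=1.0)

    def test_zero_cohort_and_negative_inputs(self):
        assert npv_loss(0.0, 0.5, 1000.0, 0.06, 10.0).npv_loss_usd_thousands == 0.0
        with pytest.raises(ValueError):
            npv_loss(-1.0, 0.5, 1000.0, 0.06, 10.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        newborns=st.floats(0.0, 1e5),
        part=st.floats(0.0, 1.0),
        income=st.floats(0.0, 1e5),
        deficit=st.floats(0.0, 1.0),
        ann=st.floats(0.0, 40.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_in_each_factor(self, newborns, part, income, deficit, ann, scale):
        base = npv_loss(newborns, part, income, deficit, ann).npv_loss_usd_thousands
        for i, args in enumerate(
            (
                (newborns * scale, part, income, deficit, ann),
                (newborns, part, income * scale, deficit, ann),
                (newborns, part, income, deficit, ann * scale),
            )
        ):
            scaled = npv_loss(*args).npv_loss_usd_thousands
            assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)

    def test_cohort_chain_composes_the_primitives(self):
        params = EconParams()
        loss = cohort_npv_loss(
            newborns_thousands=1000.0,
            gni_per_capita_usd=2000.0,
            wage_share_fraction=0.5,
            labor_participation_fraction=0.6,
            hale_years=60.0,
            params=params,
            scope="Africa",
        )
        expected = (
            1000.0 * 0.6 * 1000.0 * 0.0612 * annuity_factor(0.03, 11, 45.0)
        )
        assert loss.npv_loss_usd_thousands == pytest.approx(expected, rel=1e-12)
        assert loss.work_life_years == 45.0
        assert math.isclose(loss.annuity_factor, annuity_factor(0.03, 11, 45.0))
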