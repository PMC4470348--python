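"""Closed-form model: double-stranded length, expectations, intensity
maps and their inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unwindfit import (
    ConfigurationError,
    EffectiveParams,
    ExpFitParams,
    ModelDomainError,
    UnwindingConfig,
    dose_equivalent_total,
    equivalent_dose,
    exp_form_from_effective,
    expected_ds_length,
    expected_ds_length_conditional,
    intensity_exp_form,
    intensity_from_effective,
    relative_ds_length,
)

DONOR1 = ExpFitParams(B=0.122, P0=0.79, beta=0.18)


class TestRelativeDsLength:
    @pytest.mark.parametrize(
        "breaks, mu, expected",
        [
            ([], 0.1, 0.8),  # single gap of length 1
            ([0.5], 0.1, 0.6),  # (0.5-0.2) + (0.5-0.2)
            ([0.4, 0.45], 0.1, 0.55),  # middle gap fully unwound by interference
            ([0.5], 0.3, 0.0),  # both gaps <= 2 mu
            ([0.5, 0.5], 0.1, 0.6),  # tied positions: zero-length gap contributes 0
            ([0.25, 0.5, 0.75], 0.0, 1.0),  # no unwinding
        ],
    )
    def test_hand_computed_lengths(self, breaks, mu, expected):
        assert relative_ds_length(UnwindingConfig(breaks, mu)) == pytest.approx(
            expected, abs=1e-15
        )

    @pytest.mark.parametrize(
        "breaks, mu",
        [([1.5], 0.1), ([0.0], 0.1), ([1.0], 0.1), ([0.6, 0.4], 0.1), ([0.5], -0.1)],
    )
    def test_malformed_configurations_rejected(self, breaks, mu):
        with pytest.raises(ConfigurationError):
            UnwindingConfig(breaks, mu)

    @given(
        breaks=st.lists(
            st.floats(0.001, 0.999, allow_nan=False), min_size=0, max_size=30
        ),
        mu=st.floats(0.0, 0.7),
        extra=st.floats(0.001, 0.999),
    )
    @settings(deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, breaks, mu, extra):
        """L lies in [0,1]; adding a break or increasing mu never
        increases the remaining double-stranded length."""
        breaks = sorted(breaks)
        L = relative_ds_length(UnwindingConfig(breaks, mu))
        assert 0.0 <= L <= 1.0
        L_more_breaks = relative_ds_length(UnwindingConfig(sorted(breaks + [extra]), mu))
        assert L_more_breaks <= L + 1e-12
        L_more_mu = relative_ds_length(UnwindingConfig(breaks, mu + 0.05))
        assert L_more_mu <= L + 1e-12


class TestConditionalExpectation:
    @pytest.mark.parametrize(
        "m, mu, expected",
        [
            (0, 0.0, 1.0),
            (7, 0.0, 1.0),
            (1, 0.25, 0.25),  # (1 - 0.5)^2
            (9, 0.1, 0.8**10),
            (3, 0.5, 0.0),  # 2 mu >= 1
            (2, 0.7, 0.0),
        ],
    )
    def test_closed_form(self, m, mu, expected):
        assert expected_ds_length_conditional(m, mu) == pytest.approx(expected)

    def test_monotone_in_m_and_mu(self):
        vals_m = [expected_ds_length_conditional(m, 0.1) for m in range(30)]
        assert all(a >= b for a, b in zip(vals_m, vals_m[1:]))
        vals_mu = [
            expected_ds_length_conditional(5, mu) for mu in np.linspace(0, 0.6, 25)
        ]
        assert all(a >= b for a, b in zip(vals_mu, vals_mu[1:]))

    @pytest.mark.parametrize("m", [-1, 2.5])
    def test_rejects_invalid_break_count(self, m):
        with pytest.raises(ConfigurationError):
            expected_ds_length_conditional(m, 0.1)


class TestEffectiveModel:
    def test_no_unwinding_gives_full_length(self):
        p = EffectiveParams(d0_eff=5, gamma_eff=2, mu_eff=0.0)
        assert expected_ds_length(p, 10) == 1.0

    def test_zero_dose_exponent(self):
        p = EffectiveParams(d0_eff=2, gamma_eff=0, mu_eff=0.1)
        assert expected_ds_length(p, 7.3) == pytest.approx(0.64)

    def test_non_integer_exponent(self):
        p = EffectiveParams(d0_eff=2, gamma_eff=1, mu_eff=0.1)
        assert expected_ds_length(p, 3) == pytest.approx(0.8**5)
        assert expected_ds_length(p, 0.5) == pytest.approx(0.8**2.5)

    def test_intensity_composition(self):
        p = EffectiveParams(d0_eff=2, gamma_eff=1, mu_eff=0.1, B=0.122)
        assert intensity_from_effective(p, 3) == pytest.approx(
            0.122 + 0.878 * 0.8**5
        )

    def test_saturated_unwinding_returns_background(self):
        p = EffectiveParams(d0_eff=2, gamma_eff=1, mu_eff=0.6, B=0.122)
        assert intensity_from_effective(p, 0) == pytest.approx(0.122)


class TestExpFormReparameterisation:
    def test_values(self):
        p = EffectiveParams(d0_eff=2, gamma_eff=1, mu_eff=0.1, B=0.122)
        fit = exp_form_from_effective(p)
        assert fit.P0 == pytest.approx(0.122 + 0.878 * 0.64)
        assert fit.beta == pytest.approx(-math.log(0.8))

    def test_mu_zero_limit(self):
        fit = exp_form_from_effective(EffectiveParams(d0_eff=3, gamma_eff=1, mu_eff=0.0))
        assert (fit.P0, fit.beta) == (1.0, 0.0)

    def test_saturated_mu_rejected(self):
        with pytest.raises(ModelDomainError):
            exp_form_from_effective(EffectiveParams(d0_eff=2, gamma_eff=1, mu_eff=0.5))

    @given(
        d0=st.floats(0.5, 60),
        gamma=st.floats(0.0, 5),
        mu=st.floats(0.001, 0.45),
        B=st.floats(0.0, 0.8),
        dose=st.floats(0.0, 20),
    )
    @settings(deadline=None, derandomize=True)
    def test_reproduces_mechanistic_intensity_pointwise(self, d0, gamma, mu, B, dose):
        """The (P0, beta) reparameterisation is an exact algebraic identity
        with the mechanistic intensity at every dose."""
        p = EffectiveParams(d0_eff=d0, gamma_eff=gamma, mu_eff=mu, B=B)
        fit = exp_form_from_effective(p)
        assert intensity_exp_form(fit, dose) == pytest.approx(
            intensity_from_effective(p, dose), rel=1e-12, abs=1e-14
        )


class TestExponentialForm:
    def test_zero_dose_and_flat_curve(self):
        assert intensity_exp_form(DONOR1, 0.0) == pytest.approx(0.79)
        flat = ExpFitParams(B=0.122, P0=0.79, beta=0.0)
        assert intensity_exp_form(flat, 12.0) == pytest.approx(0.79)

    def test_reference_donor_high_dose(self):
        expected = 0.122 + 0.668 * math.exp(-0.18 * 14.9)
        assert intensity_exp_form(DONOR1, 14.9) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        d = np.linspace(0, 50, 200)
        P = intensity_exp_form(DONOR1, d)
        assert np.all(np.diff(P) <= 0)
        assert np.all((P >= DONOR1.B) & (P <= DONOR1.P0))


class TestInversions:
    def test_zero_dose_at_p0(self):
        assert equivalent_dose(DONOR1.P0, DONOR1) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("d", [0.3, 1.9, 14.9])
    def test_equivalent_dose_round_trip(self, d):
        assert equivalent_dose(intensity_exp_form(DONOR1, d), DONOR1) == pytest.approx(d)

    def test_reference_inversion(self):
        P = 0.122 + 0.668 * math.exp(-0.18 * 14.9)
        assert equivalent_dose(P, DONOR1) == pytest.approx(14.9)

    @pytest.mark.parametrize("P", [0.122, 0.05, 0.80])
    def test_out_of_range_intensity_rejected(self, P):
        with pytest.raises(ModelDomainError):
            equivalent_dose(P, DONOR1)

    def test_degenerate_flat_curve_rejected(self):
        flat = ExpFitParams(B=0.122, P0=0.79, beta=0.0)
        with pytest.raises(ModelDomainError):
            equivalent_dose(0.5, flat)

    def test_dtot_zero_at_full_length(self):
        assert dose_equivalent_total(1.0, 0.122, 0.18) == pytest.approx(0.0, abs=1e-12)

    def test_dtot_reference_value(self):
        # -(1/0.18) ln(0.668 / 0.878)
        assert dose_equivalent_total(0.79, 0.122, 0.18) == pytest.approx(
            1.5186578894359495
        )

    @pytest.mark.parametrize("d", [1.0, 5.0])
    def test_dtot_additivity_in_dose(self, d):
        """D_tot at the model intensity for dose d exceeds the zero-dose
        D_tot by exactly d (baseline and induced damage add)."""
        base = dose_equivalent_total(DONOR1.P0, DONOR1.B, DONOR1.beta)
        at_d = dose_equivalent_total(
            intensity_exp_form(DONOR1, d), DONOR1.B, DONOR1.beta
        )
        assert at_d - base == pytest.approx(d)

    def test_dtot_out_of_range_rejected(self):
        with pytest.raises(ModelDomainError):
            dose_equivalent_total(0.1, 0.122, 0.18)
        with pytest.raises(ModelDomainError):
            dose_equivalent_total(1.2, 0.122, 0.18)
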