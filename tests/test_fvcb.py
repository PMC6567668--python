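"""FvCB forward model and A_n–C_i parameter estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soyco2 import (
    ACiCurve,
    FitConfig,
    FvCBParams,
    GasExchangePoint,
    compute_wue,
    fit_aci,
    fvcb_assimilation,
    jmax_from_j,
)
from soyco2.errors import DomainError, FitError
from soyco2.fvcb import fvcb_curve
from soyco2.profiles import CI_LADDER
from soyco2.simulate import generate_aci_curve


class TestForwardModel:
    def test_compensation_point_gives_minus_rd(self, canonical_params):
        an, _ = fvcb_assimilation(canonical_params, canonical_params.gamma_star)
        assert an == pytest.approx(-canonical_params.rd, abs=1e-12)

    def test_min_limb_selection_at_ci_300(self, canonical_params):
        # hand evaluation: Km = 404.9*(1 + 210/278.4) = 710.3;
        # A_c = 23.96 > A_j = 23.52, so the RuBP limb limits
        an, limb = fvcb_assimilation(canonical_params, 300.0)
        assert an == pytest.approx(23.52, abs=0.005)
        assert limb == "rubp"

    def test_rubisco_limb_at_low_ci(self, canonical_params):
        an, limb = fvcb_assimilation(canonical_params, 100.0)
        assert limb == "rubisco"
        # A_c = 100*(100-42.75)/(100+710.32) - 1.5
        assert an == pytest.approx(100 * 57.25 / 810.32 - 1.5, rel=1e-6)

    def test_high_ci_asymptote_is_j_over_4_minus_rd(self, canonical_params):
        an, limb = fvcb_assimilation(canonical_params, 1e7)
        assert limb == "rubp"
        assert an == pytest.approx(150.0 / 4.0 - 1.5, rel=1e-4)

    def test_nonpositive_ci_rejected(self, canonical_params):
        with pytest.raises(DomainError):
            fvcb_assimilation(canonical_params, 0.0)

    def test_nonpositive_kinetics_rejected(self):
        with pytest.raises(DomainError):
            FvCBParams(vcmax=100, j=150, rd=1.5, kc=-1.0)

    @given(
        ci=st.floats(min_value=43.0, max_value=2000.0),
        dci=st.floats(min_value=0.1, max_value=500.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_min_limb_nondecreasing_in_ci(self, ci, dci):
        p = FvCBParams(vcmax=100.0, j=150.0, rd=1.5)
        a1, _ = fvcb_assimilation(p, ci)
        a2, _ = fvcb_assimilation(p, ci + dci)
        assert a2 >= a1 - 1e-9


class TestWUE:
    @pytest.mark.parametrize(
        "an, tr, expected",
        [(20.0, 4.0, 5.0), (0.0, 3.0, 0.0), (23.52, 5.6, 4.2)],
    )
    def test_ratio(self, an, tr, expected):
        assert compute_wue(an, tr) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_transpiration_rejected(self):
        with pytest.raises(DomainError):
            compute_wue(20.0, 0.0)


class TestJmaxFromJ:
    def test_closed_form(self):
        assert jmax_from_j(150, 1500, theta=0.9, alpha=0.3) == pytest.approx(157.5)

    def test_half_saturation_limit(self):
        # theta -> 1 with j = alpha*ppfd/2 collapses to jmax = j
        j = 0.3 * 1500 / 2
        assert jmax_from_j(j, 1500, theta=0.9999, alpha=0.3) == pytest.approx(
            j, rel=1e-3
        )

    def test_insufficient_light_rejected(self):
        with pytest.raises(DomainError):
            jmax_from_j(450, 1500, theta=0.9, alpha=0.3)


class TestCurveContainer:
    def test_too_few_points_rejected(self, canonical_params):
        pts = tuple(
            GasExchangePoint(ci=c, an=1.0) for c in (50, 100, 150, 200, 300)
        )
        with pytest.raises(FitError, match="insufficient"):
            ACiCurve(points=pts, growth_co2=400)

    def test_points_sorted_on_construction(self, canonical_params):
        cis = [300, 50, 150, 600, 100, 200]
        pts = tuple(GasExchangePoint(ci=c, an=1.0) for c in cis)
        curve = ACiCurve(points=pts, growth_co2=400)
        assert list(curve.ci) == sorted(cis)

    def test_duplicate_ci_rejected(self):
        pts = tuple(
            GasExchangePoint(ci=c, an=1.0) for c in (50, 100, 100, 200, 300, 400)
        )
        with pytest.raises(DomainError, match="strictly increasing"):
            ACiCurve(points=pts, growth_co2=400)


class TestFitACi:
    @pytest.mark.parametrize(
        "vcmax, j, rd",
        [(100.0, 150.0, 1.5), (60.0, 110.0, 0.8), (150.0, 210.0, 2.5)],
    )
    def test_noiseless_round_trip(self, vcmax, j, rd):
        truth = FvCBParams(vcmax=vcmax, j=j, rd=rd)
        curve = generate_aci_curve(truth, CI_LADDER, 0.0, seed=0)
        fit = fit_aci(curve)
        assert fit.params.vcmax == pytest.approx(vcmax, rel=1e-4)
        assert fit.params.j == pytest.approx(j, rel=1e-4)
        assert fit.params.rd == pytest.approx(rd, rel=1e-3)
        assert fit.sse < 1e-10
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_limb_labels_and_min_count(self, canonical_params):
        curve = generate_aci_curve(canonical_params, CI_LADDER, 0.0, seed=0)
        fit = fit_aci(curve)
        labels = list(fit.limb_labels)
        assert labels.count("rubisco") >= 3 and labels.count("rubp") >= 3
        # labels are a contiguous split at the transition
        first_rubp = labels.index("rubp")
        assert all(l == "rubp" for l in labels[first_rubp:])
        assert curve.ci[first_rubp - 1] < fit.transition_ci < curve.ci[first_rubp]

    def test_rd_fixed_to_measured(self, canonical_params):
        curve = generate_aci_curve(canonical_params, CI_LADDER, 0.0, seed=0)
        fit = fit_aci(curve, FitConfig(rd_policy="measured"))
        assert fit.params.rd == pytest.approx(canonical_params.rd)
        assert fit.params.vcmax == pytest.approx(100.0, rel=1e-6)

    def test_rd_measured_missing_raises(self, canonical_params):
        pts = tuple(
            GasExchangePoint(ci=c, an=a)
            for c, a in zip(CI_LADDER, fvcb_curve(canonical_params, CI_LADDER)[0])
        )
        curve = ACiCurve(points=pts, growth_co2=400)
        with pytest.raises(FitError, match="rd_measured"):
            fit_aci(curve, FitConfig(rd_policy="measured"))

    def test_noisy_recovery_median_error_below_5_percent(self):
        truth = FvCBParams(vcmax=100.0, j=150.0, rd=1.5)
        rng = np.random.default_rng(2024)
        errs_v, errs_j = [], []
        for _ in range(100):
            curve = generate_aci_curve(truth, CI_LADDER, 0.5, seed=rng)
            fit = fit_aci(curve)
            errs_v.append(abs(fit.params.vcmax - 100.0) / 100.0)
            errs_j.append(abs(fit.params.j - 150.0) / 150.0)
        assert np.median(errs_v) <= 0.05
        assert np.median(errs_j) <= 0.05
        # mean recovered vcmax close to truth (no systematic bias)
        assert np.mean(errs_v) <= 0.05
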