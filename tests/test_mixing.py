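import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from throughfall import (
    EndmemberSpec,
    OutOfEnvelopeError,
    UndefinedMixtureError,
    attribute_nitrification,
    concentration_increase_pct,
    implied_new_delta15N,
    mixing_fraction,
    new_to_original_pct,
    nitrification_endmember,
)


class TestEndmember:
    def test_default_rule_gives_published_interval(self):
        e = nitrification_endmember(-10.0, -5.0, 23.5, 2.0 / 3.0)
        assert round(e.endmember_low, 1) == 1.2
        assert round(e.endmember_high, 1) == 4.5

    def test_degenerate_water_range(self):
        e = nitrification_endmember(-5.0, -5.0, 23.5, 2.0 / 3.0)
        assert e.endmember_low == e.endmember_high == pytest.approx(4.5, abs=0.05)

    @pytest.mark.parametrize("frac", [0.0, 0.3, 2.0 / 3.0, 1.0])
    def test_identical_sources_collapse(self, frac):
        e = nitrification_endmember(7.0, 7.0, 7.0, frac)
        assert e.endmember_low == e.endmember_high == pytest.approx(7.0)

    def test_interval_width_scales_with_water_fraction(self):
        e = nitrification_endmember(-10.0, -5.0, 23.5, 2.0 / 3.0)
        assert e.width == pytest.approx((2.0 / 3.0) * 5.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            nitrification_endmember(-5.0, -10.0)
        with pytest.raises(ValueError):
            EndmemberSpec(endmember_low=4.5, endmember_high=1.2)

    def test_water_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            nitrification_endmember(-10.0, -5.0, 23.5, 1.5)


class TestMixingFraction:
    def test_published_endpoint_case(self):
        assert mixing_fraction(74.1, 49.8, 1.2) == pytest.approx(24.3 / 72.9, abs=1e-9)

    def test_no_change_gives_zero(self):
        assert mixing_fraction(74.1, 74.1, 1.2) == 0.0

    def test_full_replacement_gives_one(self):
        assert mixing_fraction(74.1, 1.2, 1.2) == 1.0

    def test_coincident_endmembers_undefined(self):
        with pytest.raises(UndefinedMixtureError):
            mixing_fraction(74.1, 50.0, 74.1)

    def test_small_envelope_violation_clamped_with_warning(self):
        # 0.5 per mil above the initial bound, within 2 x 0.59
        with pytest.warns(UserWarning, match="clamp"):
            f = mixing_fraction(74.1, 74.6, 1.2)
        assert f == 0.0

    def test_large_envelope_violation_raises_with_raw_value(self):
        with pytest.raises(OutOfEnvelopeError) as exc:
            mixing_fraction(74.1, 80.0, 1.2)
        assert exc.value.raw_delta_final == 80.0
        assert exc.value.raw_fraction == 0.0

    def test_strictly_decreasing_in_delta_final(self):
        finals = np.linspace(1.2, 74.1, 30)
        fracs = [mixing_fraction(74.1, d, 1.2) for d in finals]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))
        assert all(0.0 <= f <= 1.0 for f in fracs)


class TestNewToOriginal:
    @pytest.mark.parametrize(
        "f, expected", [(0.0, 0.0), (0.5, 100.0), (24.3 / 72.9, 50.0)]
    )
    def test_values(self, f, expected):
        assert new_to_original_pct(f) == pytest.approx(expected, abs=0.05)

    def test_full_replacement_is_infinite_ratio(self):
        with pytest.raises(UndefinedMixtureError):
            new_to_original_pct(1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_round_trip_with_inverse(self, f):
        p = new_to_original_pct(f)
        assert p / (100.0 + p) == pytest.approx(f, abs=1e-12)


class TestConcentrationIncrease:
    @pytest.mark.parametrize(
        "ci, cf, expected", [(219.0, 332.0, 51.6), (100.0, 100.0, 0.0), (100.0, 150.0, 50.0)]
    )
    def test_values(self, ci, cf, expected):
        assert concentration_increase_pct(ci, cf) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_initial_rejected(self):
        with pytest.raises(ValueError):
            concentration_increase_pct(0.0, 100.0)


class TestAttribution:
    def test_published_worked_example(self, analysis_endmember, cj1_case):
        res = attribute_nitrification(
            cj1_case["delta18O_initial"],
            cj1_case["delta18O_final"],
            analysis_endmember,
            c_initial=cj1_case["no3_initial_uM"],
            c_final=cj1_case["no3_final_uM"],
        )
        assert res.new_to_original_pct_low == pytest.approx(50.0, abs=0.1)
        assert res.new_to_original_pct_high == pytest.approx(53.6, abs=0.1)
        assert res.conc_based_pct == pytest.approx(51.6, abs=0.05)
        assert res.consistent is True

    def test_no_change_anywhere_is_consistent_zero(self, analysis_endmember):
        res = attribute_nitrification(
            74.1, 74.1, analysis_endmember, c_initial=219.0, c_final=219.0
        )
        assert res.new_to_original_pct_low == res.new_to_original_pct_high == 0.0
        assert res.conc_based_pct == 0.0
        assert res.consistent is True

    def test_disjoint_intervals_flagged_inconsistent(self):
        # isotope interval ~[10, 12] % vs concentration-based 40 %
        e = EndmemberSpec(endmember_low=1.2, endmember_high=4.5)
        f_target = 0.10 / 1.10  # new:original 10 %
        d_final_low = 74.1 - f_target * (74.1 - 1.2)
        res = attribute_nitrification(
            74.1, d_final_low, e, c_initial=100.0, c_final=140.0, tolerance_pp=2.0
        )
        assert res.new_to_original_pct_high < 38.0
        assert res.consistent is False

    def test_without_concentrations_consistency_undetermined(self, analysis_endmember):
        res = attribute_nitrification(74.1, 49.8, analysis_endmember)
        assert res.conc_based_pct is None and res.consistent is None

    def test_interval_brackets_any_pointwise_water_value(self, cj1_case):
        """Propagating the water-range interval must bracket every pointwise
        attribution computed at a single water delta-18O inside the range."""
        interval = nitrification_endmember(-10.0, -5.0)
        res = attribute_nitrification(
            cj1_case["delta18O_initial"], cj1_case["delta18O_final"], interval
        )
        for w in np.linspace(-10.0, -5.0, 21):
            point = nitrification_endmember(w, w)
            f = mixing_fraction(
                cj1_case["delta18O_initial"], cj1_case["delta18O_final"],
                point.endmember_low,
            )
            assert res.frac_new_of_final_low - 1e-12 <= f <= res.frac_new_of_final_high + 1e-12


class TestImpliedDelta15N:
    def test_published_case_implies_light_source(self):
        implied = implied_new_delta15N(6.1, -1.7, 1.0 / 3.0)
        assert implied == pytest.approx(-17.3, abs=0.05)
        assert implied < 0.0  # consistent with an ammonium-derived source

    def test_identity_when_unchanged(self):
        assert implied_new_delta15N(5.0, 5.0, 0.4) == pytest.approx(5.0)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            implied_new_delta15N(6.1, -1.7, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-20.0, max_value=80.0),
        st.floats(min_value=-20.0, max_value=80.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_forward_then_inverse_recovers_endmember(self, d_init, d_new, f):
        d_final = (1.0 - f) * d_init + f * d_new
        assert implied_new_delta15N(d_init, d_final, f) == pytest.approx(
            d_new, abs=1e-6, rel=1e-6
        )


def test_forward_mixing_oracle_grid():
    """Brute-force oracle: mix C_old at delta_old with C_new at delta_new,
    then mixing_fraction must recover C_new / (C_old + C_new) to 1e-9."""
    deltas_old = [30.0, 62.0, 74.1, 90.0]
    deltas_new = [-5.0, 1.2, 4.5, 10.0]
    ratios = [0.01, 0.1, 0.3333, 0.5, 0.9]
    for d_old, d_new, r in itertools.product(deltas_old, deltas_new, ratios):
        c_old = 219.0
        c_new = c_old * r / (1.0 - r)
        d_mix = (c_old * d_old + c_new * d_new) / (c_old + c_new)
        f = mixing_fraction(d_old, d_mix, d_new)
        assert f == pytest.approx(c_new / (c_old + c_new), abs=1e-9)
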