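"""Two-end-member mixing: point estimates, validity, uncertainty propagation."""

import math

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import assume, given

from rnacarbon import mixing as mx
from rnacarbon.errors import ConfigurationError, DegenerateEndmembersError, OutOfRangeError
from rnacarbon.mixing import (
    CarbonSourceMixingModel,
    EndMember,
    Validity,
    apportion_all_pairs,
    check_validity,
    delta_method_sigma,
    infer_het_endmember,
    mc_uncertainty,
    mixing_fraction,
)

RNA = -193.4
RNA_SIGMA = 5.6


def _oracle_delta_sigma(s, ss, a, sa, b, sb):
    """Independent first-order propagation: partials written out directly."""
    w = a - b
    dfds = 1.0 / w
    dfda = -(s - b) / w**2
    dfdb = (s - a) / w**2
    return math.sqrt((dfds * ss) ** 2 + (dfda * sa) ** 2 + (dfdb * sb) ** 2)


class TestMixingFraction:
    def test_dic_doc_pair(self, dic, doc):
        f = mixing_fraction(RNA, dic, doc)
        assert f == pytest.approx(0.513, abs=0.002)

    def test_dic_soc_pair(self, dic, soc):
        f = mixing_fraction(RNA, dic, soc)
        assert f == pytest.approx(0.897, abs=0.002)

    def test_sample_equal_to_dic_gives_one(self, dic, doc):
        assert mixing_fraction(dic.delta14c_permil, dic, doc) == pytest.approx(1.0)

    def test_sample_equal_to_organic_gives_zero(self, dic, doc):
        assert mixing_fraction(doc.delta14c_permil, dic, doc) == pytest.approx(0.0)

    def test_linear_in_sample(self, dic, doc):
        f0 = mixing_fraction(-200.0, dic, doc)
        f1 = mixing_fraction(-190.0, dic, doc)
        fm = mixing_fraction(-195.0, dic, doc)
        assert fm == pytest.approx((f0 + f1) / 2, rel=1e-12)

    def test_degenerate_endmembers_raise(self):
        with pytest.raises(DegenerateEndmembersError):
            mixing_fraction(-100.0, EndMember("A", -150.0), EndMember("B", -150.0))

    @given(
        s=st.floats(-900, 400),
        a=st.floats(-900, 400),
        b=st.floats(-900, 400),
        shift=st.floats(-500, 500),
    )
    def test_affine_invariance(self, s, a, b, shift):
        assume(abs(a - b) > 1.0)
        f1 = mixing_fraction(s, EndMember("A", a), EndMember("B", b))
        f2 = mixing_fraction(s + shift, EndMember("A", a + shift), EndMember("B", b + shift))
        assert f2 == pytest.approx(f1, abs=1e-9)

    @given(
        s=st.floats(-900, 400),
        a=st.floats(-900, 400),
        b=st.floats(-900, 400),
    )
    def test_swap_symmetry(self, s, a, b):
        assume(abs(a - b) > 1.0)
        f = mixing_fraction(s, EndMember("A", a), EndMember("B", b))
        f_swapped = mixing_fraction(s, EndMember("B", b), EndMember("A", a))
        assert f_swapped == pytest.approx(1.0 - f, abs=1e-9)


class TestCheckValidity:
    def test_plant_pairing_invalid(self, dic, plant):
        assert check_validity(RNA, dic, plant) is Validity.SAMPLE_OUTSIDE_INTERVAL

    def test_doc_pairing_valid(self, dic, doc):
        assert check_validity(RNA, dic, doc) is Validity.VALID

    def test_boundary_is_valid(self, dic, doc):
        assert check_validity(dic.delta14c_permil, dic, doc) is Validity.VALID

    def test_degenerate(self):
        assert (
            check_validity(-100.0, EndMember("A", -150.0), EndMember("B", -150.0))
            is Validity.DEGENERATE_ENDMEMBERS
        )


class TestDeltaMethodSigma:
    def test_all_zero_sigmas(self, dic, doc):
        d0 = EndMember("DIC", dic.delta14c_permil, 0.0)
        o0 = EndMember("DOC", doc.delta14c_permil, 0.0)
        assert delta_method_sigma(RNA, 0.0, d0, o0) == 0.0

    def test_symmetric_under_endmember_swap(self):
        a = EndMember("A", -100.0, 3.0)
        b = EndMember("B", -300.0, 3.0)
        s, ss = -200.0, 4.0  # midway
        assert delta_method_sigma(s, ss, a, b) == pytest.approx(
            delta_method_sigma(s, ss, b, a), rel=1e-12
        )

    def test_matches_independent_partials(self, dic, doc):
        got = delta_method_sigma(RNA, RNA_SIGMA, dic, doc)
        want = _oracle_delta_sigma(RNA, RNA_SIGMA, -157.7, 1.7, -231.0, 1.7)
        assert got == pytest.approx(want, rel=1e-12)


class TestMonteCarlo:
    def test_zero_sigma_collapses_to_point(self, dic, doc):
        d0 = EndMember("DIC", dic.delta14c_permil, 0.0)
        o0 = EndMember("DOC", doc.delta14c_permil, 0.0)
        r = mc_uncertainty(RNA, 0.0, d0, o0, n_draws=1000, seed=1)
        assert r.ci_low == r.f_autotrophy == r.ci_high
        assert r.sigma_f == 0.0

    def test_dic_doc_mean_and_interval(self, dic, doc):
        r = mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=100_000, seed=7)
        assert r.mc_mean == pytest.approx(r.f_autotrophy, abs=0.01)
        sd_oracle = _oracle_delta_sigma(RNA, RNA_SIGMA, -157.7, 1.7, -231.0, 1.7)
        half_width = (r.ci_high - r.ci_low) / 2.0
        assert half_width == pytest.approx(1.96 * sd_oracle, rel=0.15)
        assert r.validity is Validity.VALID

    def test_dic_soc_wide_interval(self, dic, soc):
        r = mc_uncertainty(RNA, RNA_SIGMA, dic, soc, n_draws=100_000, seed=7)
        assert r.f_autotrophy == pytest.approx(0.897, abs=0.002)
        # SOC heterogeneity (sigma 173 permil) makes the interval much wider
        assert (r.ci_high - r.ci_low) > 0.2

    def test_reproducible_for_fixed_seed(self, dic, doc):
        r1 = mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=5000, seed=3)
        r2 = mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=5000, seed=3)
        assert r1 == r2

    def test_mc_mean_converges_to_point(self, dic, doc):
        small = mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=1000, seed=5)
        large = mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=100_000, seed=5)
        point = small.f_autotrophy
        assert abs(large.mc_mean - point) <= abs(small.mc_mean - point) + 0.005

    def test_out_of_interval_draws_reported_not_clamped(self, dic, soc):
        r = mc_uncertainty(RNA, RNA_SIGMA, dic, soc, n_draws=50_000, seed=11)
        assert 0.0 < r.frac_draws_outside < 1.0

    def test_rejects_too_few_draws(self, dic, doc):
        with pytest.raises(ValueError):
            mc_uncertainty(RNA, RNA_SIGMA, dic, doc, n_draws=10, seed=0)


class TestApportionAllPairs:
    def test_rifle_fixture(self, rifle_endmembers):
        results = apportion_all_pairs(RNA, RNA_SIGMA, rifle_endmembers, "DIC", seed=0)
        by_pair = {r.pair_name: r for r in results}
        assert set(by_pair) == {"DIC-DOC", "DIC-SOC", "DIC-plant"}
        assert by_pair["DIC-DOC"].f_autotrophy == pytest.approx(0.513, abs=0.002)
        assert by_pair["DIC-DOC"].validity is Validity.VALID
        assert by_pair["DIC-SOC"].f_autotrophy == pytest.approx(0.897, abs=0.002)
        assert by_pair["DIC-SOC"].validity is Validity.VALID
        assert by_pair["DIC-plant"].validity is Validity.SAMPLE_OUTSIDE_INTERVAL

    def test_only_dic_yields_empty(self, dic):
        assert apportion_all_pairs(RNA, RNA_SIGMA, [dic], "DIC", seed=0) == []

    def test_missing_dic_is_configuration_error(self, doc):
        with pytest.raises(ConfigurationError):
            apportion_all_pairs(RNA, RNA_SIGMA, [doc], "DIC")

    def test_synthetic_three_sources_match_direct_formula(self):
        ems = [
            EndMember("DIC", -100.0, 0.0),
            EndMember("X", -300.0, 0.0),
            EndMember("Y", -500.0, 0.0),
        ]
        results = apportion_all_pairs(-250.0, 0.0, ems, "DIC", method="point")
        expected = {
            "DIC-X": (-250.0 + 300.0) / (-100.0 + 300.0),
            "DIC-Y": (-250.0 + 500.0) / (-100.0 + 500.0),
        }
        for r in results:
            assert r.f_autotrophy == pytest.approx(expected[r.pair_name], rel=1e-12)


class TestInferHetEndmember:
    def test_zero_autotrophy_returns_sample(self, dic):
        assert infer_het_endmember(0.0, RNA, dic) == pytest.approx(RNA)

    def test_community_fraction_points_to_doc(self, dic):
        implied = infer_het_endmember(0.525, RNA, dic)
        assert implied == pytest.approx(-232.9, abs=0.1)
        assert abs(implied - (-231.0)) < 10.0

    def test_all_autotroph_undefined(self, dic):
        with pytest.raises(OutOfRangeError):
            infer_het_endmember(1.0, RNA, dic)

    @given(
        f=st.floats(0.0, 0.99),
        s=st.floats(-500, 100),
        a=st.floats(-500, 100),
    )
    def test_round_trip_with_mixing_fraction(self, f, s, a):
        assume(abs(a - s) > 1.0)
        dic = EndMember("DIC", a)
        implied = infer_het_endmember(f, s, dic)
        back = mixing_fraction(s, dic, EndMember("org", implied))
        assert back == pytest.approx(f, abs=1e-9)


class TestModelResults:
    def test_fit_from_bundled_files(self):
        from rnacarbon import datasets

        model = CarbonSourceMixingModel.from_files(
            datasets.path("rifle_sample.csv"), datasets.path("rifle_endmembers.csv")
        )
        res = model.fit(seed=0, n_draws=10_000)
        assert res.by_pair("DIC-DOC").percent == pytest.approx(51.3, abs=0.2)
        assert res.by_pair("DIC-SOC").percent == pytest.approx(89.7, abs=0.2)
        frame = res.to_frame()
        assert set(frame["pair"]) == {"DIC-DOC", "DIC-SOC", "DIC-plant"}

    def test_summary_carries_reported_percentages(self, rifle_endmembers):
        model = CarbonSourceMixingModel(RNA, RNA_SIGMA, rifle_endmembers)
        text = model.fit(seed=0, n_draws=10_000).summary()
        assert "51.3" in text and "89.7" in text
        assert "sample-outside-interval" in text

    def test_infer_heterotroph_endmember_names_closest_pool(self, rifle_endmembers):
        model = CarbonSourceMixingModel(RNA, RNA_SIGMA, rifle_endmembers)
        res = model.fit(method="point")
        implied, name = res.infer_heterotroph_endmember(0.525)
        assert name == "DOC"
        assert implied == pytest.approx(-232.9, abs=0.1)

    def test_duplicate_endmember_names_rejected(self, dic):
        with pytest.raises(ConfigurationError):
            CarbonSourceMixingModel(RNA, RNA_SIGMA, [dic, dic])
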