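"""Acute (IESTI/%ARfD) and chronic (NEDI/%ADI) exposure arithmetic."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import primorisk as pk
from primorisk._rounding import round_sig


def make_profile(**overrides):
    params = dict(
        label="test", body_weight=10.20, large_portion=166.70,
        mean_consumption=0.344, unit_weight=20.0,
    )
    params.update(overrides)
    return pk.ConsumptionProfile(**params)


class TestIesti:
    def test_worked_example_flupyradifurone(self, profile):
        value = pk.iesti(0.68, profile)
        assert round_sig(value, 3) == 0.0111

    def test_zero_residue_gives_zero(self, profile):
        assert pk.iesti(0.0, profile) == 0.0

    def test_tebufenpyrad_hand_arithmetic(self, profile):
        assert pk.iesti(0.133, profile) == pytest.approx(0.133 * 0.1667 / 10.20, rel=1e-3)

    def test_negative_residue_rejected(self, profile):
        with pytest.raises(ValueError):
            pk.iesti(-0.1, profile)

    def test_scales_inversely_with_body_weight(self, profile):
        doubled_bw = make_profile(body_weight=2 * profile.body_weight)
        assert pk.iesti(0.5, doubled_bw) == pytest.approx(pk.iesti(0.5, profile) / 2)

    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_linear_in_residue(self, hr):
        profile = make_profile()
        assert pk.iesti(2 * hr, profile) == pytest.approx(2 * pk.iesti(hr, profile))

    def test_case_2a_unit_based_formula(self):
        # one 100 g unit eaten at variability 3, rest of the portion at bulk residue
        profile = make_profile(unit_weight=100.0, variability_factor=3.0)
        assert pk.iesti_case(profile) == "2a"
        expected = (0.1 * 0.5 * 3 + (0.1667 - 0.1) * 0.5) / 10.20
        assert pk.iesti(0.5, profile) == pytest.approx(expected)

    def test_case_2b_unit_larger_than_portion(self):
        profile = make_profile(unit_weight=500.0, variability_factor=3.0)
        assert pk.iesti_case(profile) == "2b"
        assert pk.iesti(0.5, profile) == pytest.approx(0.1667 * 0.5 * 3 / 10.20)

    def test_case_boundary_at_25_g_is_case_1(self):
        assert pk.iesti_case(make_profile(unit_weight=25.0)) == "1"


class TestPercentArfd:
    def test_worked_example(self):
        assert pk.round_half_up(pk.percent_arfd(0.0111133, 0.15), 2) == 7.41

    def test_boundary_is_100(self):
        assert pk.percent_arfd(0.15, 0.15) == 100.0

    def test_tebufenpyrad_highest(self, profile):
        assert pk.round_half_up(pk.percent_arfd(pk.iesti(0.133, profile), 0.02), 2) == 10.87

    def test_absent_arfd_never_silently_zero(self):
        with pytest.raises(ValueError, match="not established"):
            pk.percent_arfd(0.01, None)


class TestNedi:
    def test_worked_example_cyflumetofen(self):
        assert pk.nedi(0.112, 0.344) == pytest.approx(0.000038528, abs=1e-12)

    def test_zero_apr(self):
        assert pk.nedi(0.0, 0.344) == 0.0

    def test_hand_arithmetic_emamectin(self):
        assert pk.nedi(0.022, 0.344) == pytest.approx(7.568e-6, abs=1e-12)

    def test_negative_apr_rejected(self):
        with pytest.raises(ValueError):
            pk.nedi(-0.1, 0.344)

    def test_independent_of_body_weight(self, profile):
        # consumption is already per kg bw, so only those two numbers matter
        assert pk.nedi(0.1, profile.mean_consumption) == 0.1 * 0.344 / 1000


class TestPercentAdi:
    def test_worked_example(self):
        assert pk.round_half_up(pk.percent_adi(0.000038528, 0.17), 3) == 0.023

    def test_boundary_is_100(self):
        assert pk.percent_adi(0.17, 0.17) == 100.0

    def test_lambda_cyhalothrin(self):
        assert pk.round_half_up(pk.percent_adi(pk.nedi(0.015, 0.344), 0.0025), 2) == 0.21

    def test_absent_adi_never_silently_zero(self):
        with pytest.raises(ValueError, match="not established"):
            pk.percent_adi(0.01, None)


class TestAssessAcute:
    def test_campaign_has_19_assessable_substances(self, campaign, refs, profile):
        results, not_assessable = pk.assess_acute(campaign, refs, profile)
        assert len(results) == 19
        assert len(not_assessable) == 12

    def test_every_percent_arfd_below_100(self, campaign, refs, profile):
        results, _ = pk.assess_acute(campaign, refs, profile)
        assert all(r.percent_arfd < 100 for r in results)

    def test_hr_is_campaign_maximum(self, campaign, refs, profile):
        results, _ = pk.assess_acute(campaign, refs, profile)
        for r in results:
            brute_max = max(
                m.concentration for m in campaign.measurements if m.pesticide == r.pesticide
            )
            assert r.hr == brute_max

    def test_single_measurement_dataset(self, refs, profile):
        ds = pk.ResidueDataset(
            (pk.ResidueMeasurement("A1", "captan", 0.03),), n_samples_total=1
        )
        results, _ = pk.assess_acute(ds, refs, profile)
        assert results[0].hr == 0.03 and results[0].case_used == "1"

    def test_empty_dataset_rejected(self, refs, profile):
        with pytest.raises(ValueError):
            pk.assess_acute(pk.ResidueDataset((), n_samples_total=5), refs, profile)


class TestAssessChronic:
    @pytest.mark.parametrize(
        "pesticide, expected",
        [("fluxapyroxad", 0.46), ("tebufenpyrad", 0.25), ("lambda-cyhalothrin", 0.21)],
    )
    def test_campaign_percent_adi(self, campaign, refs, profile, pesticide, expected):
        results, _ = pk.assess_chronic(campaign, refs, profile)
        by_name = {r.pesticide: r for r in results}
        assert pk.round_half_up(by_name[pesticide].percent_adi, 2) == expected

    def test_ethirimol_not_assessable(self, campaign, refs, profile):
        results, not_assessable = pk.assess_chronic(campaign, refs, profile)
        assert not_assessable == ["ethirimol"]
        assert len(results) == 30

    def test_apr_matches_summary_mean(self, campaign, refs, profile):
        results, _ = pk.assess_chronic(campaign, refs, profile)
        summaries = pk.summarize_all(campaign)
        for r in results:
            assert r.apr == summaries[r.pesticide].mean


class TestHazardIndex:
    def test_additivity_of_two_residues(self, refs, profile):
        # fluxapyroxad at 0.65 contributes 4.25, lambda-cyhalothrin at 0.015 gives 4.90
        ds = pk.ResidueDataset(
            (
                pk.ResidueMeasurement("A1", "fluxapyroxad", 0.65),
                pk.ResidueMeasurement("A1", "lambda-cyhalothrin", 0.015),
            ),
            n_samples_total=1,
        )
        hi, excluded = pk.hazard_index("A1", ds, refs, profile)
        assert pk.round_half_up(hi, 2) == 9.15
        assert excluded == []

    def test_sample_without_arfd_bearing_residues(self, refs, profile):
        ds = pk.ResidueDataset(
            (pk.ResidueMeasurement("A1", "pyrimethanil", 0.5),), n_samples_total=1
        )
        hi, excluded = pk.hazard_index("A1", ds, refs, profile)
        assert hi == 0.0 and excluded == ["pyrimethanil"]

    def test_single_residue_equals_its_percent_arfd(self, refs, profile):
        ds = pk.ResidueDataset(
            (pk.ResidueMeasurement("A1", "captan", 0.03),), n_samples_total=1
        )
        hi, _ = pk.hazard_index("A1", ds, refs, profile)
        assert hi == pytest.approx(pk.percent_arfd(pk.iesti(0.03, profile), 0.9))

    def test_unknown_sample_rejected(self, campaign, refs, profile):
        with pytest.raises(KeyError):
            pk.hazard_index("ZZ99", campaign, refs, profile)

    def test_campaign_hazard_never_reaches_arfd_sum_threshold(self, campaign, refs, profile):
        # even the worst multi-residue sample stays far below 100%
        worst = max(
            pk.hazard_index(s, campaign, refs, profile)[0] for s in campaign.sample_ids
        )
        assert worst < 100
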