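import pandas as pd
import pytest

from throughfall import (
    ClassificationThresholds,
    MissingDataError,
    NSpeciesProfile,
    ValidationError,
    load_profiles,
    mineral_nitrogen,
    summarize_all,
    summarize_budget,
)
from throughfall.simulate import RateSet, simulate
from dataclasses import replace


def profile(week, nh4, no2, no3, source="Cj1", treatment="unfiltered"):
    return NSpeciesProfile(
        sample_id=f"{source}-{treatment}-w{week}",
        source=source,
        treatment=treatment,
        week=week,
        nh4_uM=nh4,
        no2_uM=no2,
        no3_uM=no3,
    )


class TestLoadProfiles:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            "sample_id,source,treatment,week,nh4_uM,no2_uM,no3_uM\n"
            "a,Cj1,unfiltered,0,174,11,219\n"
            "b,Cj1,unfiltered,4,,0,332\n"
            "c,RF,unfiltered,0,30,1,28\n"
        )
        profiles = load_profiles(p)
        assert len(profiles) == 3
        # not-determined NH4 is preserved as None, never imputed
        assert profiles[1].nh4_uM is None and profiles[1].no3_uM == 332.0

    def test_negative_concentration_reported_with_row(self, tmp_path):
        p = tmp_path / "chem.csv"
        p.write_text(
            "sample_id,source,treatment,week,nh4_uM,no2_uM,no3_uM\n"
            "a,Cj1,unfiltered,0,-1,11,219\n"
        )
        with pytest.raises(ValidationError, match="row 0"):
            load_profiles(p)

    def test_unknown_treatment_and_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "source": ["Cj1", "Cj1", "Cj1"],
                "treatment": ["unfiltered", "unfiltered", "f37um"],
                "week": [0, 0, 1],
                "nh4_uM": [1.0, 1.0, 1.0],
                "no2_uM": [0.0, 0.0, 0.0],
                "no3_uM": [2.0, 2.0, 2.0],
            }
        )
        with pytest.raises(ValidationError) as exc:
            load_profiles(df)
        msg = str(exc.value)
        assert "duplicate" in msg and "f37um" in msg


class TestMineralNitrogen:
    def test_published_sums(self):
        assert mineral_nitrogen(profile(0, 174.0, 11.0, 219.0)) == pytest.approx(404.0)
        # second tree: printed total is 677 from rounded components
        assert mineral_nitrogen(profile(0, 404.0, 5.0, 267.0)) == pytest.approx(676.0)
        assert mineral_nitrogen(profile(0, 0.0, 0.0, 0.0)) == 0.0

    def test_additive_and_permutation_invariant(self):
        a, b, c = 17.0, 3.0, 41.0
        assert mineral_nitrogen(profile(0, a, b, c)) == mineral_nitrogen(
            profile(0, c, a, b)
        )
        assert mineral_nitrogen(profile(0, a + 1, b, c)) == pytest.approx(
            mineral_nitrogen(profile(0, a, b, c)) + 1
        )

    def test_missing_species_is_error(self):
        with pytest.raises(MissingDataError, match="nh4"):
            mineral_nitrogen(profile(0, None, 11.0, 219.0))


class TestSummarizeBudget:
    def test_nitrifying_pattern_with_mineralization_excess(self):
        series = [profile(0, 174.0, 11.0, 219.0), profile(4, 94.0, 0.0, 332.0)]
        s = summarize_budget(series)
        assert s.delta_no3 == pytest.approx(113.0)
        assert s.delta_no2 == pytest.approx(-11.0)
        assert s.delta_nh4 == pytest.approx(-80.0)
        assert s.oxidized_n_produced == pytest.approx(102.0)
        assert s.excess_over_nh4_consumption == pytest.approx(22.0)
        assert s.classification == "nitrifying"

    def test_all_flat_is_inactive(self):
        s = summarize_budget([profile(0, 10.0, 1.0, 20.0), profile(4, 10.0, 1.0, 20.0)])
        assert s.excess_over_nh4_consumption == 0.0
        assert s.classification == "inactive"

    def test_nitrite_accumulation_pattern(self):
        s = summarize_budget(
            [profile(0, 174.0, 11.0, 219.0), profile(4, 139.0, 41.0, 219.0)]
        )
        assert s.delta_no2 == pytest.approx(30.0)
        assert s.classification == "nitrite_accumulating"

    def test_missing_intermediate_nh4_does_not_block_no3_delta(self):
        series = [
            profile(0, 174.0, 11.0, 219.0),
            profile(1, 150.0, 12.0, 240.0),
            profile(2, None, 10.0, 270.0),
            profile(3, None, 2.0, 300.0),
            profile(4, None, 0.0, 332.0),
        ]
        s = summarize_budget(series)
        assert s.delta_no3 == pytest.approx(113.0)
        # NH4 delta falls back to the latest determined week (week 1)
        assert s.delta_nh4 == pytest.approx(-24.0)

    def test_no_post_incubation_data_is_error(self):
        with pytest.raises(ValidationError, match="post-incubation"):
            summarize_budget([profile(0, 174.0, 11.0, 219.0)])

    def test_classification_scale_invariant_above_thresholds(self):
        base = [profile(0, 174.0, 11.0, 219.0), profile(4, 94.0, 0.0, 332.0)]
        scaled = [
            profile(0, 174.0 * 3, 11.0 * 3, 219.0 * 3),
            profile(4, 94.0 * 3, 0.0, 332.0 * 3),
        ]
        assert summarize_budget(base).classification == summarize_budget(
            scaled
        ).classification

    def test_custom_thresholds_change_class(self):
        series = [profile(0, 100.0, 0.0, 100.0), profile(4, 90.0, 0.0, 112.0)]
        assert summarize_budget(series).classification == "inactive"
        loose = ClassificationThresholds(min_dno3_abs_uM=10.0, min_dno3_frac=0.05)
        assert summarize_budget(series, loose).classification == "nitrifying"


def test_summarize_all_reports_unevaluable_groups():
    rows = [
        profile(0, 174.0, 11.0, 219.0),
        profile(4, 94.0, 0.0, 332.0),
        profile(0, 404.0, 5.0, 267.0, source="Cj2"),
    ]
    frame = summarize_all(rows)
    by = frame.set_index("source")["classification"]
    assert by["Cj1"] == "nitrifying"
    assert by["Cj2"] == "not_evaluable"


def test_budget_conserves_simulated_nitrogen(cj1_config):
    """With immobilization off and no noise, oxidized-N produced plus final
    NH4 and DON equals the initial NH4 + DON + oxidized N pool exactly."""
    rates = replace(cj1_config.rates["unfiltered"], k_immob=0.0)
    cfg = replace(cj1_config, rates={"unfiltered": rates}, conc_cv=0.0)
    exp = simulate(cfg)
    s = summarize_budget(exp.profiles_true)
    final = {p.week: p for p in exp.profiles_true}[cfg.weeks]
    final_don = exp.truth["treatments"]["unfiltered"][str(cfg.weeks)]["don_uM"]
    i = cfg.initial
    lhs = s.oxidized_n_produced + final.nh4_uM + final_don
    rhs = i.nh4_uM + i.don_uM
    assert lhs == pytest.approx(rhs, abs=1e-9)
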