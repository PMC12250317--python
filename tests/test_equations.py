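import json
import math

import numpy as np
import pytest

from anthroagree import (
    AnthroProfile,
    EquationOptions,
    ValidationError,
    bd_to_fp,
    estimate,
    estimate_bd,
    estimate_fm,
    estimate_fp,
    estimate_lm,
    estimate_lp,
    get_spec,
    list_equations,
    registry_json,
)
from anthroagree.equations import BD_CONVERTERS, FAMILIES

from conftest import make_profile, SKINFOLDS, GIRTHS


class TestBodyDensity:
    def test_durnin_womersley_round_sum(self):
        # four folds summing to 100 -> log10 = 2 exactly
        p = make_profile(sex="male", BI=25, TR=25, SS=25, SI=25)
        assert estimate_bd("durnin_womersley", p) == pytest.approx(1.1765 - 2 * 0.0744, abs=1e-12)

    def test_durnin_womersley_at_sample_means(self, male_profile):
        assert estimate_bd("durnin_womersley", male_profile) == pytest.approx(1.04411, abs=5e-6)

    def test_female_branch_differs(self, female_profile, male_profile):
        assert estimate_bd("durnin_womersley", female_profile) != estimate_bd(
            "durnin_womersley", male_profile
        )

    def test_every_bd_equation_in_physiological_range(self, male_profile):
        for spec in list_equations("BD"):
            bd = estimate_bd(spec.equation_id, male_profile)
            assert 0.98 < bd < 1.10, spec.equation_id

    def test_bd_non_increasing_in_skinfolds(self, male_profile):
        for spec in list_equations("BD"):
            base = estimate_bd(spec.equation_id, male_profile)
            fatter = make_profile(sex="male", **{s: make_profile().skinfolds_mm[s] * 1.5 for s in SKINFOLDS})
            assert estimate_bd(spec.equation_id, fatter) <= base + 1e-12, spec.equation_id


class TestConverters:
    def test_siri_zero_point(self):
        assert bd_to_fp("siri", 1.1) == pytest.approx(0.0, abs=1e-9)

    def test_brozek_value(self):
        assert bd_to_fp("brozek", 1.1) == pytest.approx(457 / 1.1 - 414.2, abs=1e-9)

    def test_chained_with_durnin_womersley(self, male_profile):
        fp = estimate_fp("durnin_womersley+siri", male_profile)
        assert fp == pytest.approx(24.09, abs=0.01)

    def test_out_of_range_bd_warns_but_returns(self):
        with pytest.warns(UserWarning):
            v = bd_to_fp("siri", 1.3)
        assert v < 0

    def test_siri_brozek_crossover(self):
        """Siri exceeds Brozek exactly below BD = 0.38/0.358, near FP ~ 16.3%."""
        crossover = 0.38 / 0.358
        grid = np.linspace(0.98, 1.12, 2001)
        for bd in grid:
            siri, brozek = (100 * (4.95 / bd - 4.5), 100 * (4.57 / bd - 4.142))  # oracle
            assert (bd_to_fp("siri", bd) > bd_to_fp("brozek", bd)) == (siri > brozek)
            assert (siri > brozek) == (bd < crossover)
        fp_at_cross = bd_to_fp("siri", crossover)
        assert fp_at_cross == pytest.approx(16.3, abs=0.1)


class TestFatPercent:
    def test_hastuti_male_hand_value(self):
        p = make_profile(sex="male", TR=11.8, SI=23.07)
        assert estimate_fp("hastuti", p) == pytest.approx(
            17.026 + 0.509 * 11.8 + 0.342 * 23.07 - 5.594, abs=1e-9
        )

    def test_hastuti_intercept_limit(self):
        # folds -> 0: intercept minus the male sex term (11.432)
        p = make_profile(sex="male", TR=1e-9, SI=1e-9)
        assert estimate_fp("hastuti", p) == pytest.approx(11.432, abs=1e-6)

    def test_hastuti_mean_profile_matches_reported_cohort_mean(self, mean_profile):
        """Linearity: the estimate at the sample means with sex = 22/27
        equals the reported cohort mean 26.36."""
        assert estimate_fp("hastuti", mean_profile) == pytest.approx(26.36, abs=0.005)

    def test_sex_specific_dispatch(self):
        m, f = make_profile(sex="male"), make_profile(sex="female")
        for eq in ("carter", "faulkner", "yuhasz", "lean_wc", "lean_bmi"):
            assert estimate_fp(eq, m) != estimate_fp(eq, f), eq

    def test_sex_fraction_mixes_branches_linearly(self):
        m, f = make_profile(sex="male"), make_profile(sex="female")
        frac = make_profile(sex=0.25)
        for eq in ("faulkner", "hastuti", "minematsu"):
            expected = 0.25 * estimate_fp(eq, m) + 0.75 * estimate_fp(eq, f)
            assert estimate_fp(eq, frac) == pytest.approx(expected, abs=1e-9), eq

    def test_isak5_fp_is_kerr_fm_over_weight(self, male_profile):
        fp = estimate_fp("isak5_fp", male_profile)
        fm = estimate_fm("isak5_fm", male_profile)
        assert fp == pytest.approx(fm / male_profile.body_weight_kg * 100.0, abs=1e-9)

    def test_oconnor_printed_vs_squared_variant(self, male_profile):
        printed = estimate_fp("oconnor", male_profile)
        squared = estimate_fp("oconnor", male_profile, EquationOptions(oconnor_squared=True))
        s = 11.8 + 23.07 + 14.4
        assert printed == pytest.approx(0.272 * s - 0.0005 * s + 4.972, abs=1e-9)
        assert squared == pytest.approx(0.272 * s - 0.0005 * s * s + 4.972, abs=1e-9)

    def test_race_offset_applied(self):
        base = estimate_fp("evans", make_profile(sex="male", race="white"))
        afro = estimate_fp("evans", make_profile(sex="male", race="afro_descendant"))
        assert afro == pytest.approx(base - 1.998, abs=1e-9)

    def test_lee_dh_race_unprinted_category_uses_others(self):
        other = estimate_fp("lee_dh_fp", make_profile(sex="male", race="white"))
        hisp = estimate_fp("lee_dh_fp", make_profile(sex="male", race="hispanic"))
        assert other - hisp == pytest.approx(0.7 - 0.19, abs=1e-9)

    def test_cavedon_needs_axillary_fold(self, male_profile):
        from anthroagree import MissingSiteError

        with pytest.raises(MissingSiteError, match="AX"):
            estimate_fp("cavedon1", male_profile)
        p = make_profile()
        p.skinfolds_mm.update(AX=12.0, CH=10.0)
        assert estimate_fp("cavedon1", p) > 0
        assert estimate_fp("cavedon2", p) > 0


class TestFatMass:
    def test_de_rose_intercept_limit(self):
        # folds -> 0 at BW = 100: 0.01 * 100 * 5.783
        p = make_profile(sex="male", bw=100.0, SS=1e-9, TR=1e-9, SSP=1e-9, AB=1e-9)
        assert estimate_fm("de_rose_fm", p) == pytest.approx(5.783, abs=1e-6)

    def test_de_rose_at_sample_means(self, male_profile):
        s4 = 18.3 + 11.8 + 15.31 + 25.45
        assert estimate_fm("de_rose_fm", male_profile) == pytest.approx(
            0.01 * 69.52 * (s4 * 0.153 + 5.783), abs=1e-9
        )

    def test_kerr_fm_zero_z_score_at_phantom_height(self):
        # six folds scaled so the height-adjusted sum equals the phantom
        # mean -> Z = 0 -> adipose mass is the phantom's 25.6 kg
        target = 116.41 / 6
        p = make_profile(sex="male", h=170.18, TR=target, SS=target, SI=target, AB=target, TH=target, C=target)
        assert estimate_fm("isak5_fm", p) == pytest.approx(25.6, abs=1e-9)

    def test_kerr_literal_printed_form_is_nonphysical(self, male_profile):
        literal = estimate_fm("isak5_fm", male_profile, EquationOptions(as_printed=True))
        assert literal > 400  # the printed arithmetic, kept only for audit


class TestLeanMassAndPercent:
    def test_lee_rc_2_hand_value(self):
        p = make_profile(sex="male", race="white", age=30.0, bw=70.0, h=170.0)
        assert estimate_lm("lee_rc_2", p) == pytest.approx(
            0.244 * 70 + 7.8 * 1.70 + 6.6 - 0.098 * 30 - 3.3, abs=1e-9
        )

    def test_de_rose_closure(self, male_profile):
        """De Rose: fat + bone + residual + lean must sum to body weight."""
        res = estimate("de_rose_lm", male_profile)
        total = res.value + res.intermediate["FM"] + res.intermediate["BM"] + res.intermediate["RM"]
        assert total == pytest.approx(male_profile.body_weight_kg, abs=1e-9)
        assert 5.0 < res.intermediate["BM"] < 20.0  # plausible bone mass

    def test_de_rose_needs_diameters(self):
        p = make_profile()
        p.diameters_cm.clear()
        from anthroagree import MissingSiteError

        with pytest.raises(MissingSiteError, match="WD"):
            estimate_lm("de_rose_lm", p)

    def test_kerr_lm_zero_z_at_phantom(self):
        # build girths so the corrected five-girth sum is exactly the
        # phantom 207.21 at phantom height -> muscle Z = 0 -> LM 24.5
        p = make_profile(sex="male", h=170.18)
        cg_wo_fa = (
            (p.circumferences_cm["Ac"] - p.skinfolds_mm["TR"] * 0.3141)
            + (p.circumferences_cm["THc"] - p.skinfolds_mm["TH"] * 0.3141)
            + (p.circumferences_cm["Cc"] - p.skinfolds_mm["C"] * 0.3141)
            + (p.circumferences_cm["CHc"] - p.skinfolds_mm["SS"] * 0.3141)
        )
        p.circumferences_cm["FAc"] = 207.21 - cg_wo_fa
        assert estimate_lm("isak5_lm", p) == pytest.approx(24.5, abs=1e-9)

    def test_isak5_lp_is_lm_over_weight(self, male_profile):
        lp = estimate_lp("isak5_lp", male_profile)
        lm = estimate_lm("isak5_lm", male_profile)
        assert lp == pytest.approx(lm / male_profile.body_weight_kg * 100.0, abs=1e-9)

    def test_lee_rc_lp_is_lee_rc_1_over_weight(self, male_profile):
        assert estimate_lp("lee_rc_lp", male_profile) == pytest.approx(
            estimate_lm("lee_rc_1", male_profile) / 69.52 * 100.0, abs=1e-9
        )

    def test_poortmans_hand_value(self, male_profile):
        # oracle: direct evaluation of the printed formula (H in metres)
        h_m = 167.63 / 100
        expected = (
            h_m * 0.0264 * 32.05**2 + 0.0032 * 55.59**2 + 0.0015 * 36.76**2 + 2.56 + 0.136 * 32.85
        )
        assert estimate_lp("poortmans", male_profile) == pytest.approx(expected, abs=1e-9)

    def test_heymsfield_variants(self, male_profile):
        printed = estimate_lm("heymsfield", male_profile)
        published = estimate_lm(
            "heymsfield", male_profile, EquationOptions(heymsfield_coefficient=0.0264)
        )
        assert printed - published == pytest.approx(167.63 * (0.284 - 0.0264), abs=1e-9)
        assert 25 < published < 40  # the published coefficient gives plausible lean mass

    def test_lee_rc_race_without_printed_offset_errors(self):
        with pytest.raises(ValidationError, match="race"):
            estimate_lm("lee_rc_1", make_profile(sex="male", race="mexican"))


class TestRegistry:
    def test_family_counts_match_comparison_counts(self):
        assert len(list_equations("FP")) == 34
        assert len(list_equations("FM")) == 6
        assert len(list_equations("LP")) == 3
        assert len(list_equations("LM")) == 13
        assert len(list_equations("BD")) == 8

    def test_untested_registry_entries(self):
        ids = {s.equation_id for s in list_equations("FP", include_untested=True)}
        assert {"cavedon1", "cavedon2"} <= ids
        assert len(ids) == 36

    def test_every_spec_satisfiable_by_a_full_profile(self):
        p = make_profile()
        p.skinfolds_mm.update(AX=12.0, CH=10.0)
        for spec in list_equations(include_untested=True):
            estimate(spec.equation_id, p)  # must not raise

    def test_required_fields_consistent(self):
        for spec in list_equations(include_untested=True):
            for site in spec.required_skinfolds:
                assert site in ("BI", "TR", "SS", "SI", "SSP", "AB", "TH", "C", "AX", "CH")
            for site in spec.required_circumferences:
                assert site in GIRTHS
            if spec.sex_coding and isinstance(next(iter(spec.sex_coding.values())), (int, float)):
                assert set(spec.sex_coding) == {"male", "female"}

    def test_registry_export_is_json_serializable(self):
        doc = json.dumps(registry_json())
        assert "hastuti" in doc and "durnin_womersley+siri" in doc

    def test_deterministic_order(self):
        assert [s.equation_id for s in list_equations("FM")] == [
            "al_guindan", "de_rose_fm", "isak5_fm", "heitmann", "lee_dh_fm", "salamat_fm",
        ]

    def test_family_mismatch_rejected(self, male_profile):
        with pytest.raises(ValueError):
            estimate_fm("hastuti", male_profile)


class TestLinearity:
    AFFINE = ["hastuti", "deurenberg", "minematsu", "salamat_fm", "salamat_lm", "faulkner", "eston"]

    @pytest.mark.parametrize("equation_id", AFFINE)
    def test_mean_profile_equals_mean_of_estimates(self, equation_id, rng):
        """For affine equations the estimate at the mean profile equals
        the mean of per-subject estimates (brute-force oracle loop).

        BMI-linear equations are fed an explicit BMI so the mean profile
        carries the mean BMI (BMI itself is not affine in weight/height).
        """
        n = 40
        profiles = []
        for i in range(n):
            profiles.append(
                make_profile(
                    sex="male",
                    subject_id=f"P{i}",
                    age=float(rng.uniform(20, 50)),
                    bw=float(rng.uniform(55, 95)),
                    h=float(rng.uniform(155, 190)),
                    **{s: float(rng.uniform(4, 35)) for s in SKINFOLDS},
                    **{g: float(rng.uniform(25, 110)) for g in GIRTHS},
                )
            )
        for p in profiles:
            p.bmi_given = p.body_weight_kg / (p.height_cm / 100) ** 2
        mean_p = make_profile(
            sex="male",
            age=float(np.mean([p.age for p in profiles])),
            bw=float(np.mean([p.body_weight_kg for p in profiles])),
            h=float(np.mean([p.height_cm for p in profiles])),
            **{s: float(np.mean([p.skinfolds_mm[s] for p in profiles])) for s in SKINFOLDS},
            **{g: float(np.mean([p.circumferences_cm[g] for p in profiles])) for g in GIRTHS},
        )
        mean_p.bmi_given = float(np.mean([p.bmi for p in profiles]))
        per_subject = np.mean([estimate(equation_id, p).value for p in profiles])
        at_mean = estimate(equation_id, mean_p).value
        assert at_mean == pytest.approx(per_subject, abs=1e-9)


class TestMonotonicity:
    FP_EQS = ["eston", "carter", "faulkner", "yuhasz", "hastuti", "giro", "lean_log4sk"]

    @pytest.mark.parametrize("equation_id", FP_EQS)
    def test_fp_non_decreasing_in_each_skinfold(self, equation_id):
        base_p = make_profile(sex="male")
        base = estimate(equation_id, base_p).value
        for site in SKINFOLDS:
            bumped = make_profile(sex="male", **{site: base_p.skinfolds_mm[site] + 5.0})
            assert estimate(equation_id, bumped).value >= base - 1e-12, site

    def test_fm_non_decreasing(self, male_profile):
        base = estimate_fm("de_rose_fm", male_profile)
        bumped = make_profile(sex="male", AB=30.0)
        assert estimate_fm("de_rose_fm", bumped) > base
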