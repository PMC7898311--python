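"""Covariate equations, sampling distributions and population generation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from renalpbpk.population import (
    MG_DL_PER_UMOL_L,
    UMOL_L_PER_MG_DL,
    ConfigurationError,
    bsa_dubois,
    derive_caucasian_mild,
    generate_population,
    gfr_cockcroft_gault,
    height_from_age,
    kidney_volume,
    sample_age,
    sample_blood_params,
    sample_serum_creatinine,
    subjects_to_frame,
    validate_population,
    weight_from_height,
)


class TestHeightWeight:
    @pytest.mark.parametrize("sex,age,expected", [
        ("male", 41.96, 166.97),    # quadratic at the observed male mean age
        ("female", 42.76, 157.98),  # quadratic at the observed female mean age
    ])
    def test_height_polynomial(self, mild, sex, age, expected):
        assert height_from_age(age, sex, mild) == pytest.approx(expected, abs=0.01)

    def test_constant_polynomial(self, mild):
        p = mild.model_copy(deep=True)
        p.male.height_age_coeffs = (170.0, 0.0, 0.0)
        assert height_from_age(20, "male", p) == height_from_age(65, "male", p) == 170.0

    @pytest.mark.parametrize("sex,height,expected", [
        ("male", 167.06, 71.4),   # exp(2.13 + 0.0128*167.06)
        ("female", 157.67, 57.5),  # exp(0.93 + 0.0198*157.67)
    ])
    def test_weight_exponential(self, mild, sex, height, expected):
        assert weight_from_height(height, sex, mild) == pytest.approx(expected, abs=0.05)

    def test_weight_independent_of_height_when_slope_zero(self, mild):
        p = mild.model_copy(deep=True)
        p.male.weight_height_coeffs = (math.log(70.0), 0.0)
        assert weight_from_height(150, "male", p) == pytest.approx(70.0)
        assert weight_from_height(200, "male", p) == pytest.approx(70.0)

    def test_height_residual_centered(self, mild):
        rng = np.random.default_rng(0)
        draws = [height_from_age(40, "male", mild, rng) for _ in range(4000)]
        det = height_from_age(40, "male", mild)
        assert np.mean(draws) == pytest.approx(det, abs=0.3)
        assert np.std(draws) == pytest.approx(mild.male.height_residual_sd, rel=0.1)


class TestAgeSampling:
    def test_range_containment(self, mild):
        rng = np.random.default_rng(1)
        ages = [sample_age(mild, "male", rng) for _ in range(500)]
        lo, hi = mild.male.age_range
        assert all(lo <= a <= hi for a in ages)

    def test_degenerate_range(self, mild):
        p = mild.model_copy(deep=True)
        p.female.age_range = (40.0, 40.0)
        assert sample_age(p, "female", np.random.default_rng(0)) == 40.0

    def test_uniform_mean(self, mild):
        rng = np.random.default_rng(2)
        ages = np.array([sample_age(mild, "male", rng) for _ in range(100_000)])
        assert ages.mean() == pytest.approx((18 + 69) / 2, abs=0.2)

    def test_empirical_plugin(self, mild):
        age = sample_age(mild, "male", np.random.default_rng(0),
                         age_dist=lambda rng: 33.0)
        assert age == 33.0


class TestSerumCreatinine:
    def test_band_mean_recovery(self, mild):
        rng = np.random.default_rng(3)
        draws = np.array([sample_serum_creatinine(45, "male", mild, rng)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(118, abs=1)
        assert draws.min() > 0

    def test_cv_zero_degenerate(self, mild):
        p = mild.model_copy(deep=True)
        p.male.scr_bands[0].cv = 1e-12
        rng = np.random.default_rng(4)
        d = [sample_serum_creatinine(30, "male", p, rng) for _ in range(10)]
        assert np.allclose(d, 118, rtol=1e-4)

    def test_band_switch_at_50_female(self, mild):
        rng = np.random.default_rng(5)
        young = np.mean([sample_serum_creatinine(45, "female", mild, rng)
                         for _ in range(20_000)])
        old = np.mean([sample_serum_creatinine(55, "female", mild, rng)
                       for _ in range(20_000)])
        assert young == pytest.approx(93, rel=0.02)
        assert old == pytest.approx(78, rel=0.02)

    def test_uncovered_age_errors(self, mild):
        p = mild.model_copy(deep=True)
        p.male.age_range = (18.0, 69.0)
        with pytest.raises(ConfigurationError, match="band"):
            sample_serum_creatinine(80, "male", p, np.random.default_rng(0))


class TestBsaGfr:
    @pytest.mark.parametrize("bw,bh,expected", [
        (70, 170, 1.809), (71.07, 167.06, 1.80),
    ])
    def test_dubois(self, bw, bh, expected):
        assert bsa_dubois(bw, bh) == pytest.approx(expected, abs=0.005)

    def test_power_law_scaling(self):
        assert bsa_dubois(140, 340) / bsa_dubois(70, 170) == pytest.approx(2**1.15)

    def test_cockcroft_gault_reference_case(self):
        scr = 116.03 * MG_DL_PER_UMOL_L
        bsa = bsa_dubois(71.07, 167.06)
        gfr_abs, gfr_norm = gfr_cockcroft_gault(41.96, 71.07, scr, "male", bsa)
        assert gfr_abs == pytest.approx(73.7, abs=0.1)
        assert gfr_norm == pytest.approx(70.9, abs=0.2)
        assert 60 <= gfr_norm <= 89

    def test_inverse_in_scr_and_female_factor(self):
        a1, _ = gfr_cockcroft_gault(50, 70, 1.0, "male", 1.8)
        a2, _ = gfr_cockcroft_gault(50, 70, 2.0, "male", 1.8)
        f1, _ = gfr_cockcroft_gault(50, 70, 1.0, "female", 1.8)
        assert a1 == pytest.approx(2 * a2)
        assert f1 == pytest.approx(0.85 * a1)

    def test_age_domain(self):
        with pytest.raises(ValueError):
            gfr_cockcroft_gault(150, 70, 1.0, "male", 1.8)

    @given(st.floats(10, 2000))
    def test_unit_round_trip(self, umol):
        assert umol * MG_DL_PER_UMOL_L * UMOL_L_PER_MG_DL == pytest.approx(
            umol, rel=1e-9
        )


class TestBloodParams:
    def test_severe_male_hematocrit_mean(self, severe):
        rng = np.random.default_rng(6)
        hct = np.array([sample_blood_params(50, "male", severe, rng)[0]
                        for _ in range(100_000)])
        assert hct.mean() * 100 == pytest.approx(33.2, abs=0.3)

    def test_mild_female_agp_degenerate(self, mild):
        p = mild.model_copy(deep=True)
        p.female.agp = (0.575, 1e-12)
        _, agp, _ = sample_blood_params(40, "female", p, np.random.default_rng(0))
        assert agp == pytest.approx(0.575, rel=1e-4)

    def test_hsa_constant_when_higher_coeffs_zero(self, mild):
        p = mild.model_copy(deep=True)
        p.male.hsa_coeffs = (47.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        for age in (20, 45, 68):
            assert sample_blood_params(age, "male", p, rng)[2] == 47.0


class TestKidneyVolume:
    def test_category_formulas(self, mild, severe):
        assert kidney_volume(68.05, 164.82, mild) == pytest.approx(239.6, abs=0.1)
        assert kidney_volume(62.04, 163.01, severe) == pytest.approx(118.8, abs=0.1)

    def test_baseline_only(self, mild):
        p = mild.model_copy(deep=True)
        p.kidney_volume_coeffs = (200.0, 0.0, 0.0)
        assert kidney_volume(90, 190, p) == 200.0

    def test_monotone_decrease_with_severity(self, mild, moderate, severe):
        vols = [kidney_volume(65, 164, p) for p in (mild, moderate, severe)]
        assert vols[0] > vols[1] > vols[2]


class TestGeneratePopulation:
    def test_band_containment_and_size(self, mild):
        subs = generate_population(mild, 300, seed=11)
        df = subjects_to_frame(subs)
        assert len(df) == 300
        assert df.gfr_norm.between(60, 89).all()
        assert (df[["height", "weight", "scr_umol_L", "agp", "hsa",
                    "kidney_volume", "hematocrit"]] > 0).all().all()
        assert df.bsa.between(1.0, 3.0).all()
        np.testing.assert_allclose(
            df.scr_mg_dL, df.scr_umol_L * MG_DL_PER_UMOL_L, rtol=1e-9
        )

    def test_seeded_determinism(self, mild):
        a = subjects_to_frame(generate_population(mild, 25, seed=7))
        b = subjects_to_frame(generate_population(mild, 25, seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = subjects_to_frame(generate_population(mild, 25, seed=8))
        assert not a.equals(c)

    def test_order_independence(self, mild):
        one = generate_population(mild, 1, seed=7)[0]
        many = generate_population(mild, 10, seed=7)[0]
        assert one.age == many.age and one.scr_umol_L == many.scr_umol_L

    def test_sex_ratio_override(self, mild):
        df = subjects_to_frame(generate_population(mild, 400, seed=12,
                                                   sex_ratio_override=1.0))
        assert (df.sex == "female").all()

    def test_scr_severity_monotonicity(self, mild, moderate, severe):
        means = [
            subjects_to_frame(generate_population(p, 400, seed=13)).scr_umol_L.mean()
            for p in (mild, moderate, severe)
        ]
        assert means[0] < means[1] < means[2]

    def test_blood_param_severity_trends(self, mild, moderate, severe):
        dfs = [subjects_to_frame(generate_population(p, 400, seed=14))
               for p in (mild, moderate, severe)]
        hct = [d.hematocrit.mean() for d in dfs]
        agp = [d.agp.mean() for d in dfs]
        kv = [d.kidney_volume.mean() for d in dfs]
        assert hct[0] > hct[1] > hct[2]
        assert agp[0] < agp[1] < agp[2]
        assert kv[0] > kv[1] > kv[2]


class TestDeriveCaucasianMild:
    def test_scr_scaled_all_else_unchanged(self, healthy):
        derived = derive_caucasian_mild(healthy)
        for sex in ("male", "female"):
            ref, new = healthy.sex_params(sex), derived.sex_params(sex)
            for b_ref, b_new in zip(ref.scr_bands, new.scr_bands):
                assert b_new.mean == pytest.approx(1.5 * b_ref.mean)
                assert b_new.cv == b_ref.cv
            assert new.height_age_coeffs == ref.height_age_coeffs
            assert new.hematocrit == ref.hematocrit
        assert derived.category == "mild"
        assert derived.scr_scale_applied == pytest.approx(1.5)

    def test_double_application_warns_and_compounds(self, healthy):
        once = derive_caucasian_mild(healthy)
        with pytest.warns(UserWarning, match="already-scaled"):
            twice = derive_caucasian_mild(once)
        assert twice.male.scr_bands[0].mean == pytest.approx(
            2.25 * healthy.male.scr_bands[0].mean
        )


class TestValidatePopulation:
    def test_self_generated_coverage_near_90(self, mild):
        subs = generate_population(mild, 3000, seed=15)
        obs_subjects = generate_population(mild, 400, seed=16)
        rows = []
        for s in obs_subjects:
            for var, val in (("height", s.height), ("weight", s.weight),
                             ("scr", s.scr_umol_L), ("gfr", s.gfr_norm)):
                rows.append({"age": s.age, "sex": s.sex,
                             "variable": var, "value": val})
        rep = validate_population(subs, pd.DataFrame(rows))
        for cov in ("height", "weight", "scr", "gfr"):
            assert rep.coverage[cov] == pytest.approx(0.90, abs=0.06)
            env = rep.envelopes[cov]
            assert (env.p5 <= env["mean"]).all() and (env["mean"] <= env.p95).all()

    def test_point_at_mean_inside(self, mild):
        subs = generate_population(mild, 500, seed=17)
        df = subjects_to_frame(subs)
        obs = pd.DataFrame([{"age": 40, "sex": "male", "variable": "height",
                             "value": df[df.sex == "male"].height.mean()}])
        rep = validate_population(subs, obs)
        assert rep.coverage["height"] == 1.0

    def test_empty_observed_flagged(self, mild):
        subs = generate_population(mild, 200, seed=18)
        rep = validate_population(subs, pd.DataFrame())
        assert all(np.isnan(v) for v in rep.coverage.values())
        assert len(rep.envelopes["height"]) > 0

    def test_unknown_covariate_listed(self, mild):
        subs = generate_population(mild, 50, seed=19)
        obs = pd.DataFrame([{"age": 40, "sex": "male",
                             "variable": "creatinine", "value": 100}])
        with pytest.raises(ValueError, match="gfr"):
            validate_population(subs, obs)
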