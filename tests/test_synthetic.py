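"""Generator contracts: determinism, planted structure, round trips."""

import numpy as np
import pandas as pd
import pytest

from psyflex import bade, survey_models, survey_scores, synthetic
from psyflex.errors import ConfigurationError
from psyflex.synthetic import GroupParams, PhysioGenConfig, SurveyGenConfig


class TestDeterminism:
    def test_survey_same_seed_byte_identical(self):
        a = synthetic.generate_survey(SurveyGenConfig(n_respondents=300, seed=9))
        b = synthetic.generate_survey(SurveyGenConfig(n_respondents=300, seed=9))
        assert a.to_csv() == b.to_csv()
        c = synthetic.generate_survey(SurveyGenConfig(n_respondents=300, seed=10))
        assert a.to_csv() != c.to_csv()

    def test_bade_same_seed_identical(self):
        a = bade.ratings_to_long(synthetic.generate_bade_ratings(5, 0.5, seed=1))
        b = bade.ratings_to_long(synthetic.generate_bade_ratings(5, 0.5, seed=1))
        assert a.to_csv() == b.to_csv()

    def test_physio_same_seed_identical(self, schedule):
        cfg = PhysioGenConfig(groups={"g": GroupParams(n_subjects=3)}, seed=2)
        ra, ta, _ = synthetic.generate_physio(cfg, schedule)
        rb, tb, _ = synthetic.generate_physio(cfg, schedule)
        assert ra.to_csv() == rb.to_csv() and ta.to_csv() == tb.to_csv()


class TestSurveyGenerator:
    def test_prevalences_converge(self):
        df = synthetic.generate_survey(SurveyGenConfig(n_respondents=10_000, seed=3))
        for drug, p in synthetic.DEFAULT_PREVALENCE.items():
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(df[f"ever_{drug}"].mean() - p) < 4 * se

    def test_psychedelic_prevalence_within_three_se(self):
        cfg = SurveyGenConfig(
            n_respondents=10_000,
            prevalence={**synthetic.DEFAULT_PREVALENCE, "psychedelics": 0.283},
            seed=4,
        )
        df = synthetic.generate_survey(cfg)
        se = np.sqrt(0.283 * 0.717 / 10_000)
        assert abs(df["ever_psychedelics"].mean() - 0.283) < 3 * se

    def test_null_effects_give_null_slopes(self):
        cfg = SurveyGenConfig(
            n_respondents=4000, effects={k: 0.0 for k in synthetic.DEFAULT_EFFECTS}, seed=5
        )
        scored = survey_scores.score_survey_table(synthetic.generate_survey(cfg))
        rep = survey_models.fit_adjusted_model(
            scored, "schizotypy_composite", [f"ever_{c}" for c in survey_scores.DRUG_CLASSES]
        )
        terms = rep.terms[rep.terms["term"] != "const"]
        # every slope CI straddles zero at ~3 SE (conservative for one draw)
        assert (np.abs(terms["t"]) < 3.5).all()

    def test_planted_stimulant_slope_recovered_on_average(self):
        """Simulation oracle: the mean fitted latent-scale stimulant slope
        across replicates equals the planted value."""
        slopes = []
        for rep_i in range(60):
            cfg = SurveyGenConfig(n_respondents=4000, seed=100 + rep_i)
            df = synthetic.generate_survey(cfg)
            rep = survey_models.fit_adjusted_model(
                df, "latent_true", [f"ever_{c}" for c in survey_scores.DRUG_CLASSES]
            )
            slopes.append(rep.coef("ever_stimulants"))
        mc_se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(0.065, abs=3.5 * mc_se)

    def test_questionnaire_totals_monotone_in_latent(self):
        df = synthetic.generate_survey(SurveyGenConfig(n_respondents=3000, seed=6))
        scored = survey_scores.score_survey_table(df)
        corr = np.corrcoef(scored["latent_true"], scored["olife_total"])[0, 1]
        assert corr > 0.5

    def test_never_users_have_zero_frequency_and_recency(self):
        df = synthetic.generate_survey(SurveyGenConfig(n_respondents=500, seed=7))
        never = df["ever_psychedelics"] == 0
        assert (df.loc[never, "freq_psychedelics"] == 0).all()
        assert (df.loc[~never, "freq_psychedelics"] >= 1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_respondents": 1},
            {"noise_sd": 0.0},
            {"diagnosis_prevalence": 1.5},
            {"prevalence": {"alcohol": -0.1}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SurveyGenConfig(**kwargs)


class TestBadeGenerator:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.generate_bade_ratings(5, 0.5, rating_scale_max=0)
        with pytest.raises(ConfigurationError):
            synthetic.generate_bade_ratings(5, 1.5)


class TestPhysioGenerator:
    def test_noiseless_responses_equal_model_expectation(self, schedule):
        from psyflex.rw import RWParameters, simulate_trajectory

        gp = GroupParams(
            n_subjects=1, sigma=1e-12, beta0_mean=0.0, beta0_sd=0.0, beta1_mean=1.0, beta1_sd=0.0
        )
        responses, truth, _ = synthetic.generate_physio(
            PhysioGenConfig(groups={"g": gp}, seed=8), schedule
        )
        p = truth.iloc[0]
        tr = simulate_trajectory(
            RWParameters(p["alpha"], p["rho"], p["v0"], 0.0, 1.0, 1e-12), schedule
        )
        assert np.allclose(responses["response"], tr.v_presented, atol=1e-9)

    def test_instruction_sensitive_cohort_reacts_faster_after_reversal(self, schedule):
        """rho=1 cohort shows higher early post-reversal responses to the new
        CS+ than a rho=0 cohort (forward-simulation oracle)."""
        out = {}
        for rho, name in [(0.999, "hi"), (0.001, "lo")]:
            gp = GroupParams(n_subjects=12, rho_mean=rho, rho_kappa=2000.0, sigma=0.05)
            responses, _, _ = synthetic.generate_physio(
                PhysioGenConfig(groups={name: gp}, seed=9), schedule
            )
            sched = schedule.to_frame().set_index("trial")
            merged = responses.join(sched["condition"], on="trial")
            early = merged[
                (merged.trial.between(21, 26)) & (merged.condition == "CS+")
            ]
            out[name] = early["response"].mean()
        assert out["hi"] > out["lo"]

    def test_study_arm_sizes(self, schedule):
        responses, truth, _ = synthetic.generate_physio(PhysioGenConfig(seed=10), schedule)
        assert truth["group"].value_counts().to_dict() == {"users": 22, "non-users": 16}
        assert responses["subject"].nunique() == 38
        assert len(responses) == 38 * 80

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            PhysioGenConfig(sampling_rate=0.0)
        with pytest.raises(ConfigurationError):
            GroupParams(n_subjects=2, sigma=-1.0)
        with pytest.raises(ConfigurationError):
            GroupParams(n_subjects=2, rho_mean=1.2)


def test_ground_truth_split(scored_frame):
    df = synthetic.generate_survey(SurveyGenConfig(n_respondents=50, seed=11))
    obs, truth = synthetic.split_ground_truth(df)
    assert "latent_true" not in obs.columns
    assert list(truth.columns) == ["id", "latent_true"]
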