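import warnings

import pytest

from psyflex import fear_task, synthetic

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def schedule():
    return fear_task.generate_schedule(0)


@pytest.fixture(scope="session")
def survey_frame():
    """One study-scale synthetic survey (defaults = study conditions)."""
    return synthetic.generate_survey(synthetic.SurveyGenConfig(seed=1))


@pytest.fixture(scope="session")
def scored_frame(survey_frame):
    from psyflex import survey_scores

    return survey_scores.score_survey_table(survey_frame)


@pytest.fixture(scope="session")
def small_cohort(schedule):
    """10-subject simulated cohort with broad rho spread and low noise."""
    gp = synthetic.GroupParams(n_subjects=10, rho_mean=0.5, rho_kappa=2.0, sigma=0.1)
    cfg = synthetic.PhysioGenConfig(groups={"sim": gp}, seed=5)
    responses, truth, _ = synthetic.generate_physio(cfg, schedule)
    return responses, truth
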