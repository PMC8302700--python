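"""Seeded simulation studies: parameter recovery, power, and error control.

These studies quantify how well the pipeline's estimators behave under the
generators' study-like conditions: recovery of the instruction-sensitivity
parameter rho across its whole range, detection power for a large
between-group rho gap at the experimental arm's sample sizes, type-I error
of the survey regression battery under a null generator, and unbiasedness
of planted regression slopes. All are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import survey_models, survey_scores, synthetic
from .fear_task import generate_schedule
from .rw import InstructedRWModel, RWParameters, simulate_trajectory
from .survey_scores import DRUG_CLASSES


def rho_recovery_study(
    n_subjects: int = 50,
    sigma: float = 0.1,
    method: str = "mcmc",
    n_steps: int = 700,
    n_burn: int = 300,
    seed: int = 0,
) -> dict:
    """Fit simulated subjects with rho ~ Uniform(0, 1); report recovery.

    The noise level is the recovery study's design point: single-trial
    responses at a signal-to-noise ratio typical of trial-averaged
    pupillometric readouts (sigma = 0.1 against a unit response gain).
    """
    schedule = generate_schedule(seed)
    gp = synthetic.GroupParams(n_subjects=n_subjects, rho_mean=0.5, rho_kappa=2.0, sigma=sigma)
    cfg = synthetic.PhysioGenConfig(groups={"sim": gp}, seed=seed + 1)
    responses, truth, _ = synthetic.generate_physio(cfg, schedule)
    model = InstructedRWModel(responses, schedule)
    fit = model.fit(method=method, seed=seed + 2, n_steps=n_steps, n_burn=n_burn)
    merged = truth.set_index("subject").join(fit.estimates, rsuffix="_hat")
    corr = float(np.corrcoef(merged["rho"], merged["rho_hat"])[0, 1])
    r2m, r2c = fit.r_squared()
    return {
        "correlation": corr,
        "alpha_correlation": float(np.corrcoef(merged["alpha"], merged["alpha_hat"])[0, 1]),
        "r_squared_marginal": r2m,
        "r_squared_conditional": r2c,
        "n_subjects": n_subjects,
        "fit": fit,
        "truth": truth,
    }


def noiseless_bias_study(seed: int = 0) -> dict:
    """MAP recovery bias on essentially noise-free responses."""
    schedule = generate_schedule(seed)
    rng = np.random.default_rng(seed + 1)
    grid = [(a, r) for a in (0.2, 0.45, 0.7) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
    frames, truths = [], []
    for i, (a, r) in enumerate(grid):
        p = RWParameters(alpha=a, rho=r, v0=0.8, beta0=0.2, beta1=1.0, sigma=0.01)
        tr = simulate_trajectory(p, schedule)
        resp = tr.expected_response + rng.normal(0, 1e-3, len(tr.v_presented))
        frames.append(
            pd.DataFrame({"subject": f"s{i:02d}", "trial": np.arange(1, 81), "response": resp})
        )
        truths.append({"subject": f"s{i:02d}", "alpha": a, "rho": r})
    responses = pd.concat(frames, ignore_index=True)
    fit = InstructedRWModel(responses, schedule).fit(method="map", seed=seed + 2)
    truth = pd.DataFrame(truths).set_index("subject")
    bias_rho = float(np.max(np.abs(fit.estimates["rho"] - truth["rho"])))
    bias_alpha = float(np.max(np.abs(fit.estimates["alpha"] - truth["alpha"])))
    return {"max_bias_rho": bias_rho, "max_bias_alpha": bias_alpha, "n_subjects": len(grid)}


def rho_power_study(
    n_replicates: int = 100,
    n_users: int = 22,
    n_non_users: int = 16,
    rho_users: float = 0.8,
    rho_non_users: float = 0.3,
    sigma: float = 0.3,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> dict:
    """One-tailed detection power for the experimental-arm rho gap.

    Each replicate simulates the two cohorts at the study's sample sizes,
    fits every subject by MAP, and tests users > non-users with a Welch
    one-tailed contrast at ``alpha_level``.
    """
    schedule = generate_schedule(seed)
    hits = 0
    for rep in range(n_replicates):
        cfg = synthetic.PhysioGenConfig(
            groups={
                "users": synthetic.GroupParams(n_subjects=n_users, rho_mean=rho_users, sigma=sigma),
                "non-users": synthetic.GroupParams(
                    n_subjects=n_non_users, rho_mean=rho_non_users, sigma=sigma
                ),
            },
            seed=seed * 100_003 + rep,
        )
        responses, truth, _ = synthetic.generate_physio(cfg, schedule)
        fit = InstructedRWModel(responses, schedule).fit(method="map", seed=rep)
        groups = truth.set_index("subject")["group"].reindex(fit.estimates.index)
        labels = np.where(groups == "users", "a_users", "b_non")
        contrast = survey_models.group_contrast(
            fit.estimates["rho"].to_numpy(), labels, tail="greater"
        )
        hits += contrast.p < alpha_level
    return {"power": hits / n_replicates, "n_replicates": n_replicates}


def type_i_error_study(
    n_replicates: int = 200,
    n_respondents: int = 701,
    alpha_level: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive rate of drug terms under a fully null survey generator."""
    null_effects = {k: 0.0 for k in synthetic.DEFAULT_EFFECTS}
    drug_terms = [f"ever_{c}" for c in DRUG_CLASSES]
    n_sig = 0
    n_tests = 0
    for rep in range(n_replicates):
        cfg = synthetic.SurveyGenConfig(
            n_respondents=n_respondents, effects=null_effects, seed=seed * 99_991 + rep
        )
        scored = survey_scores.score_survey_table(synthetic.generate_survey(cfg))
        report = survey_models.fit_adjusted_model(scored, "schizotypy_composite", drug_terms)
        terms = report.terms[report.terms["term"] != "const"]
        n_sig += int((terms["p"] < alpha_level).sum())
        n_tests += len(terms)
    return {"rate": n_sig / n_tests, "n_tests": n_tests, "n_replicates": n_replicates}


def stimulant_slope_study(
    n_replicates: int = 100,
    n_respondents: int = 4000,
    planted: float = 0.065,
    seed: int = 0,
) -> dict:
    """Mean recovered latent-scale stimulant slope across replicates."""
    drug_terms = [f"ever_{c}" for c in DRUG_CLASSES]
    slopes = []
    for rep in range(n_replicates):
        cfg = synthetic.SurveyGenConfig(
            n_respondents=n_respondents,
            effects={**synthetic.DEFAULT_EFFECTS, "stimulants": planted},
            seed=seed * 7_919 + rep,
        )
        df = synthetic.generate_survey(cfg)
        report = survey_models.fit_adjusted_model(df, "latent_true", drug_terms)
        slopes.append(report.coef("ever_stimulants"))
    return {
        "mean_slope": float(np.mean(slopes)),
        "mc_se": float(np.std(slopes, ddof=1) / np.sqrt(len(slopes))),
        "planted": planted,
        "n_replicates": n_replicates,
    }


def group_shift_d_study(
    n_replicates: int = 200,
    shift: float = 0.16,
    n_users: int = 323,
    n_non_users: int = 709,
    seed: int = 0,
) -> dict:
    """Mean Cohen's d recovered from cohorts with a planted small shift."""
    rng = np.random.default_rng(seed)
    ds = []
    for _ in range(n_replicates):
        users = rng.normal(shift, 1.0, n_users)
        non = rng.normal(0.0, 1.0, n_non_users)
        contrast = survey_models.group_contrast(
            np.r_[users, non],
            np.r_[np.zeros(n_users), np.ones(n_non_users)],
            tail="greater",
        )
        ds.append(contrast.cohen_d)
    return {"mean_d": float(np.mean(ds)), "planted": shift, "n_replicates": n_replicates}
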