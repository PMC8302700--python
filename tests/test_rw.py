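"""Instructed Rescorla-Wagner model: update rules, trajectories, fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyflex import synthetic
from psyflex.errors import ParameterError, StructuralError
from psyflex.fear_task import generate_schedule
from psyflex.rw import (
    InstructedRWModel,
    RWParameters,
    apply_instruction,
    fit_subjects,
    rho_group_analysis,
    rw_update,
    simulate_trajectory,
)

unit = st.floats(0.0, 1.0, allow_nan=False)


@pytest.mark.parametrize(
    "v,outcome,alpha,expected",
    [(0.5, 1, 0.0, 0.5), (0.5, 1, 1.0, 1.0), (0.3, 0, 1.0, 0.0), (0.5, 1, 0.3, 0.65)],
)
def test_rw_update_delta_rule(v, outcome, alpha, expected):
    assert rw_update(v, outcome, alpha) == pytest.approx(expected)


def test_rw_update_rejects_alpha_outside_unit_interval():
    with pytest.raises(ParameterError):
        rw_update(0.5, 1, 1.2)


@pytest.mark.parametrize("pair", [(0.8, 0.2), (0.0, 1.0), (0.33, 0.91)])
def test_instruction_operator_identity_swap_and_midpoint(pair):
    assert apply_instruction(pair, 0.0) == pytest.approx(pair)
    assert apply_instruction(pair, 1.0) == pytest.approx(pair[::-1])
    mid = apply_instruction(pair, 0.5)
    assert mid[0] == pytest.approx(mid[1]) == pytest.approx(sum(pair) / 2)


@given(va=unit, vb=unit, rho=unit)
@settings(derandomize=True, max_examples=200)
def test_instruction_operator_conserves_value_sum(va, vb, rho):
    out = apply_instruction((va, vb), rho)
    assert out[0] + out[1] == pytest.approx(va + vb, abs=1e-12)
    assert 0.0 <= out[0] <= 1.0 and 0.0 <= out[1] <= 1.0


def test_instruction_operator_rejects_bad_rho():
    with pytest.raises(ParameterError):
        apply_instruction((0.5, 0.5), -0.1)


def test_full_swap_no_learning_trajectory(schedule):
    """rho=1, alpha=0: values swap exactly at trials 21/41/61, constant otherwise."""
    tr = simulate_trajectory(RWParameters(alpha=0.0, rho=1.0, v0=0.9), schedule)
    v = np.column_stack([tr.v_cue_a, tr.v_cue_b])
    for blk, expected in zip(range(4), [(0.9, 0.1), (0.1, 0.9), (0.9, 0.1), (0.1, 0.9)]):
        seg = v[blk * 20 : (blk + 1) * 20]
        assert np.allclose(seg, expected)


def test_rho_zero_equals_plain_rescorla_wagner(schedule):
    """With rho=0 the instructed trajectory equals an instruction-free run."""
    params = RWParameters(alpha=0.35, rho=0.0, v0=0.7)
    tr = simulate_trajectory(params, schedule)
    # independent oracle: plain RW loop ignoring instruction events entirely
    values = {"A": 0.7, "B": 0.3}
    expected = []
    for cue, reinforced in zip(schedule.cue, schedule.reinforced):
        expected.append(values[cue])
        values[cue] += 0.35 * (float(reinforced) - values[cue])
    assert np.allclose(tr.v_presented, expected, atol=1e-12)


@given(alpha=unit, rho=unit, v0=unit)
@settings(derandomize=True, max_examples=50, deadline=None)
def test_values_stay_bounded(alpha, rho, v0):
    sched = generate_schedule(0)
    tr = simulate_trajectory(RWParameters(alpha=alpha, rho=rho, v0=v0), sched)
    for arr in (tr.v_cue_a, tr.v_cue_b, tr.v_presented):
        assert np.all(arr >= -1e-12) and np.all(arr <= 1 + 1e-12)


def test_value_sum_changes_only_at_updates_not_instructions(schedule):
    params = RWParameters(alpha=0.4, rho=0.63, v0=0.8)
    tr = simulate_trajectory(params, schedule)
    sums = tr.v_cue_a + tr.v_cue_b
    # post-update sum of trial t-1 = pre-trial sum of t when t is an
    # instruction trial (the instruction itself must not move the sum)
    for t0 in (20, 40, 60):  # 0-based indices of trials 21/41/61
        post_prev = sums[t0 - 1] + params.alpha * tr.prediction_error[t0 - 1]
        assert sums[t0] == pytest.approx(post_prev, abs=1e-12)


def test_invalid_schedule_rejected(schedule):
    df = schedule.to_frame()
    df.loc[5, "reinforced"] = 1
    df.loc[6, "reinforced"] = 1
    from psyflex.fear_task import TrialSchedule

    bad = TrialSchedule.from_frame(df)
    with pytest.raises(StructuralError):
        simulate_trajectory(RWParameters(0.3, 0.5, 0.5), bad)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _simulate_cohort(schedule, params_list, sigma, seed):
    rng = np.random.default_rng(seed)
    frames = []
    for i, p in enumerate(params_list):
        tr = simulate_trajectory(p, schedule)
        r = tr.expected_response + rng.normal(0, sigma, len(tr.v_presented))
        frames.append(
            pd.DataFrame({"subject": f"s{i:02d}", "trial": np.arange(1, 81), "response": r})
        )
    return pd.concat(frames, ignore_index=True)


def test_noiseless_map_recovery_is_nearly_unbiased(schedule):
    """Posterior mode concentrates on the truth when responses are noise-free."""
    truths = [
        RWParameters(alpha=a, rho=r, v0=0.8, beta0=0.2, beta1=1.0, sigma=0.01)
        for a, r in [(0.2, 0.1), (0.2, 0.5), (0.2, 0.9), (0.5, 0.3), (0.5, 0.7), (0.35, 0.85)]
    ]
    responses = _simulate_cohort(schedule, truths, sigma=1e-3, seed=0)
    fit = fit_subjects(responses, schedule, method="map", seed=1)
    for i, p in enumerate(truths):
        est = fit.estimates.loc[f"s{i:02d}"]
        assert abs(est["rho"] - p.rho) < 0.05
        assert abs(est["alpha"] - p.alpha) < 0.05


def test_likelihood_peaks_at_true_parameters_on_noiseless_data(schedule):
    truth = RWParameters(alpha=0.4, rho=0.6, v0=0.75, beta0=0.1, beta1=1.2, sigma=0.05)
    responses = _simulate_cohort(schedule, [truth], sigma=1e-4, seed=3)
    model = InstructedRWModel(responses, schedule)
    ll_true = model.log_likelihood("s00", truth)
    for d_alpha, d_rho in [(0.15, 0.0), (-0.15, 0.0), (0.0, 0.2), (0.0, -0.2), (0.1, 0.1)]:
        perturbed = RWParameters(
            alpha=truth.alpha + d_alpha,
            rho=truth.rho + d_rho,
            v0=truth.v0,
            beta0=truth.beta0,
            beta1=truth.beta1,
            sigma=truth.sigma,
        )
        assert model.log_likelihood("s00", perturbed) < ll_true


def test_mcmc_fit_reports_intervals_and_diagnostics(schedule):
    truth = RWParameters(alpha=0.3, rho=0.8, v0=0.8, beta0=0.2, beta1=1.0, sigma=0.1)
    responses = _simulate_cohort(schedule, [truth], sigma=0.1, seed=4)
    fit = fit_subjects(responses, schedule, method="mcmc", seed=2, n_steps=500, n_burn=200)
    est = fit.estimates.loc["s00"]
    for p in ("alpha", "rho", "v0", "beta0", "beta1", "sigma"):
        assert est[f"{p}_lo"] <= est[f"{p}_median"] <= est[f"{p}_hi"]
        assert np.isfinite(est[f"{p}_rhat"]) and est[f"{p}_ess"] > 10
    assert 0.5 < est["rho"] <= 1.0  # concentrated near the (high) truth
    assert fit.converged.index.tolist() == ["s00"]


def test_recovery_intervals_widen_with_noise(schedule):
    """More response noise -> wider rho credible intervals, no silent bias."""
    truth = RWParameters(alpha=0.3, rho=0.6, v0=0.8, beta0=0.2, beta1=1.0, sigma=0.1)
    widths = []
    for sigma in (0.05, 0.4):
        responses = _simulate_cohort(schedule, [truth] * 4, sigma=sigma, seed=9)
        fit = fit_subjects(responses, schedule, method="map", seed=5)
        widths.append((fit.estimates["rho_hi"] - fit.estimates["rho_lo"]).mean())
    assert widths[1] > widths[0]


def test_too_few_usable_trials_raises(schedule):
    responses = pd.DataFrame(
        {"subject": "s0", "trial": np.arange(1, 81), "response": np.r_[np.full(70, np.nan), np.zeros(10)]}
    )
    with pytest.raises(StructuralError):
        InstructedRWModel(responses, schedule)


def test_rho_group_analysis_null_and_planted(schedule, small_cohort):
    responses, truth = small_cohort
    fit = fit_subjects(responses, schedule, method="map", seed=0)
    # identical groups -> null contrast
    half = pd.Series(["g1"] * 5 + ["g2"] * 5, index=fit.estimates.index)
    rho_vals = fit.estimates["rho"].copy()
    fit.estimates["rho"] = np.tile(rho_vals.values[:5], 2)  # force identical groups
    contrast, _ = rho_group_analysis(fit, half, tail="two-sided")
    assert contrast.t == pytest.approx(0.0, abs=1e-12)
    assert contrast.cohen_d == pytest.approx(0.0, abs=1e-12)
    fit.estimates["rho"] = rho_vals
    # planted positive exposure-rho association -> positive recovered slope
    exposures = pd.DataFrame(
        {"exposure_psychedelics": 2.0 * truth.set_index("subject")["rho"] + 0.01},
        index=fit.estimates.index,
    )
    _, reg = rho_group_analysis(fit, half, exposures=exposures, tail="two-sided")
    assert reg.coef("exposure_psychedelics") > 0


def test_summary_mentions_method_and_subjects(schedule, small_cohort):
    responses, _ = small_cohort
    fit = fit_subjects(responses, schedule, method="map", seed=0)
    text = fit.summary()
    assert "map" in text and "10" in text and "rho" in text
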