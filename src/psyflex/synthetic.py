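"""Synthetic survey, BADE and physiology datasets with known ground truth.

Three generators emulate the statistical structure the analyses assume:

* :func:`generate_survey` — respondents with demographics, diagnosis flags,
  drug-use history and questionnaire item responses. A latent schizotypy
  score is a linear predictor over planted standardized slopes plus
  Gaussian noise; binary items come from a graded-threshold model (item
  endorsed when latent + item noise exceeds the item's threshold), so
  questionnaire totals are monotone in the latent score. Defaults mirror
  the survey's descriptive statistics: drug-class prevalences
  (psychedelics 0.283, stimulants 0.305, ...), the printed regression
  slopes, ~15/43 expected O-LIFE and ~6/26 PDI+ endorsement, and age /
  diagnosis distributions under which the expected young-healthy retention
  is ≈ 701 of 1032.
* :func:`generate_bade_ratings` — per-subject BADE batteries (12 emotional
  + 12 neutral scorable scenarios + 6 distractors) whose downstream EII is
  stochastically increasing in a planted impairment level.
* :func:`generate_physio` — trial responses drawn from the instructed
  Rescorla–Wagner forward model at known (alpha, rho, v0, beta0, beta1,
  sigma), optionally embedded into raw traces as a gamma-shaped waveform
  peaking 2 s into the post-offset window so that peak-change extraction
  recovers each response.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bade import N_DISTRACTOR, N_EMOTIONAL, N_NEUTRAL, BadeScenarioRatings
from .errors import ConfigurationError, StructuralError
from .fear_task import TrialSchedule
from .physio import PhysioTrace
from .rw import RWParameters, _simulate_values_batch, _schedule_arrays
from .survey_scores import DRUG_CLASSES, EXCLUSION_FLAGS, N_OLIFE, N_PDI_PLUS

#: survey-arm drug-class lifetime prevalences (whole screened sample)
DEFAULT_PREVALENCE = {
    "alcohol": 0.9274,
    "tobacco": 0.7077,
    "cannabis": 0.5531,
    "psychedelics": 0.2829,
    "mdma": 0.3134,
    "stimulants": 0.3049,
    "opiates": 0.1251,
}

#: planted standardized slopes of each covariate on latent schizotypy
#: (whole-sample adjusted model: stimulants positive, alcohol negative,
#: psychedelics essentially null)
DEFAULT_EFFECTS = {
    "alcohol": -0.02,
    "tobacco": 0.0,
    "cannabis": 0.0,
    "psychedelics": 0.003,
    "mdma": 0.0,
    "stimulants": 0.065,
    "opiates": 0.0,
    "diagnosis": 0.075,
}


def _check_prob(p: float, name: str):
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"{name}={p} is not a probability in [0, 1]")


@dataclass(frozen=True)
class SurveyGenConfig:
    """Configuration of the survey generator.

    ``prevalence`` — lifetime ever-used probability per drug class;
    ``effects`` — standardized slope of each covariate on the latent
    schizotypy score; ``group_shift_d`` — additional direct standardized
    shift for psychedelic users (for contrast simulations);
    ``diagnosis_prevalence`` — probability of carrying at least one
    exclusion diagnosis; ``p_young`` — probability of age falling in the
    young band (18–35). Expected young-healthy retention is
    ``p_young * (1 - diagnosis_prevalence)`` ≈ 0.68 at the defaults.
    """

    n_respondents: int = 1032
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    diagnosis_prevalence: float = 0.15
    group_shift_d: float = 0.0
    noise_sd: float = 1.0
    p_young: float = 0.80
    olife_endorsement: float = 15.0 / 43.0
    pdi_endorsement: float = 6.0 / 26.0
    threshold_spread: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_respondents < 2:
            raise ConfigurationError("n_respondents must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        _check_prob(self.diagnosis_prevalence, "diagnosis_prevalence")
        _check_prob(self.p_young, "p_young")
        for k, p in self.prevalence.items():
            _check_prob(p, f"prevalence[{k}]")


def _item_thresholds(n_items: int, endorsement: float, spread: float) -> np.ndarray:
    """Evenly spread graded-response thresholds whose average marginal
    endorsement probability (over a standard-normal latent plus unit item
    noise) equals ``endorsement``."""
    center = -np.sqrt(2.0) * stats.norm.ppf(endorsement)
    qs = (np.arange(n_items) + 0.5) / n_items
    return center + spread * stats.norm.ppf(qs)


def generate_survey(config: SurveyGenConfig) -> pd.DataFrame:
    """Generate one survey table; deterministic given ``config.seed``.

    The returned frame carries demographics, diagnosis flags, per-class
    drug-use columns (``ever_<class>``, ``freq_<class>``, ``rec_<class>``;
    frequency/recency are 1–7 ordinals for ever-users, 0 for never-users),
    the questionnaire items, and the ground-truth ``latent_true`` column.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    age = np.where(
        rng.random(n) < config.p_young,
        rng.integers(18, 36, n),
        rng.integers(36, 71, n),
    )
    sex = rng.choice(["F", "M"], size=n, p=[0.65, 0.35])
    education_years = rng.integers(0, 13, n)

    # at least one of the four exclusion diagnoses with the configured
    # prevalence; individual flags i.i.d. at the complementary rate
    p_each = 1.0 - (1.0 - config.diagnosis_prevalence) ** (1.0 / len(EXCLUSION_FLAGS))
    flags = {c: rng.random(n) < p_each for c in EXCLUSION_FLAGS}
    any_diag = np.logical_or.reduce(list(flags.values()))

    ever = {c: rng.random(n) < config.prevalence.get(c, 0.0) for c in DRUG_CLASSES}

    latent = np.zeros(n)
    for c in DRUG_CLASSES:
        latent += config.effects.get(c, 0.0) * ever[c]
    latent += config.effects.get("diagnosis", 0.0) * any_diag
    latent += config.group_shift_d * ever["psychedelics"]
    latent += rng.normal(0.0, config.noise_sd, n)

    olife_tau = _item_thresholds(N_OLIFE, config.olife_endorsement, config.threshold_spread)
    pdi_tau = _item_thresholds(N_PDI_PLUS, config.pdi_endorsement, config.threshold_spread)
    olife_items = (latent[:, None] + rng.normal(0, 1, (n, N_OLIFE)) > olife_tau[None, :]).astype(int)
    pdi_items = (latent[:, None] + rng.normal(0, 1, (n, N_PDI_PLUS)) > pdi_tau[None, :]).astype(int)

    data = {
        "id": [f"S{i:05d}" for i in range(1, n + 1)],
        "age": age,
        "sex": sex,
        "education_years": education_years,
        "latent_true": latent,
    }
    data.update({c: flags[c].astype(int) for c in EXCLUSION_FLAGS})
    for c in DRUG_CLASSES:
        u = ever[c]
        # ever-users get correlated 1-7 frequency/recency ordinals driven by
        # a per-drug exposure latent; never-users are exactly zero
        expo = rng.normal(0, 1, n)
        freq = np.clip(np.round(4 + 1.5 * expo + rng.normal(0, 0.8, n)), 1, 7)
        rec = np.clip(np.round(4 + 1.5 * expo + rng.normal(0, 0.8, n)), 1, 7)
        data[f"ever_{c}"] = u.astype(int)
        data[f"freq_{c}"] = np.where(u, freq, 0).astype(int)
        data[f"rec_{c}"] = np.where(u, rec, 0).astype(int)
    for i in range(N_OLIFE):
        data[f"olife_item_{i + 1}"] = olife_items[:, i]
    for i in range(N_PDI_PLUS):
        data[f"pdi_item_{i + 1}"] = pdi_items[:, i]
    return pd.DataFrame(data)


def split_ground_truth(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate observable columns from the ground-truth latent score."""
    truth = df[["id", "latent_true"]].copy()
    return df.drop(columns=["latent_true"]), truth


# ---------------------------------------------------------------------------
# BADE generator
# ---------------------------------------------------------------------------

# mean rating trajectories on a [0, 1] scale; `w` is the impairment level.
# True becomes dominant late unless impaired; Lures start plausible and are
# revised unless impaired; Absurd stays low unless impaired.
def _bade_means(w: float) -> np.ndarray:
    return np.array(
        [
            [0.50, 0.65, 0.80 - 0.50 * w],  # True
            [0.70, 0.50, 0.30 + 0.40 * w],  # Lure-A
            [0.70, 0.50, 0.30 + 0.40 * w],  # Lure-B
            [0.10 + 0.40 * w] * 3,  # Absurd
        ]
    )


def generate_bade_ratings(
    n_subjects: int,
    impairment_level,
    rating_scale_max: float = 10.0,
    seed: int = 0,
    noise_sd: float = 0.12,
) -> dict[int, list[BadeScenarioRatings]]:
    """Per-subject BADE batteries with a planted impairment level.

    ``impairment_level`` is a scalar or an array of length ``n_subjects``
    on [0, 1]; higher levels yield stochastically higher Absurd/final-Lure
    ratings and lower final True ratings, so downstream EII increases with
    impairment. Each battery has 12 emotional + 12 neutral scorable
    scenarios and 6 distractors. ``noise_sd`` is on the unit scale.
    """
    if rating_scale_max < 1:
        raise ConfigurationError("rating_scale_max must be >= 1")
    w = np.broadcast_to(np.asarray(impairment_level, float), (n_subjects,))
    if np.any(w < 0) or np.any(w > 1):
        raise ConfigurationError("impairment_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[int, list[BadeScenarioRatings]] = {}
    classes = ["emotional"] * N_EMOTIONAL + ["neutral"] * N_NEUTRAL + ["distractor"] * N_DISTRACTOR
    for s in range(n_subjects):
        means = _bade_means(float(w[s]))
        scenarios = []
        for k, cls in enumerate(classes):
            if cls == "distractor":
                mat = rng.uniform(0, 1, (4, 3))
            else:
                mat = np.clip(means + rng.normal(0, noise_sd, (4, 3)), 0, 1)
            scenarios.append(
                BadeScenarioRatings(
                    scenario_id=f"sc{k + 1:02d}",
                    scenario_class=cls,
                    ratings=mat * rating_scale_max,
                    scale_max=rating_scale_max,
                )
            )
        out[s] = scenarios
    return out


# ---------------------------------------------------------------------------
# physiology generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """True-parameter distributions for one cohort.

    Bounded parameters (alpha, rho, v0) are Beta-distributed via mean and
    concentration kappa (a = mean*kappa, b = (1-mean)*kappa); beta0/beta1
    are Normal; sigma is a fixed positive SD.
    """

    n_subjects: int
    rho_mean: float = 0.5
    rho_kappa: float = 12.0
    alpha_mean: float = 0.30
    alpha_kappa: float = 10.0
    v0_mean: float = 0.5
    v0_kappa: float = 8.0
    beta0_mean: float = 0.2
    beta0_sd: float = 0.1
    beta1_mean: float = 1.0
    beta1_sd: float = 0.2
    sigma: float = 0.30

    def __post_init__(self):
        for name in ("rho_mean", "alpha_mean", "v0_mean"):
            _check_prob(getattr(self, name), name)
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")


@dataclass(frozen=True)
class PhysioGenConfig:
    """Configuration of the physiology generator.

    Defaults reflect the experimental arm: 22 psychedelic users with high
    instruction sensitivity versus 16 non-users with low sensitivity, with
    identical learning-rate and readout distributions.
    """

    groups: dict = field(
        default_factory=lambda: {
            "users": GroupParams(n_subjects=22, rho_mean=0.8),
            "non-users": GroupParams(n_subjects=16, rho_mean=0.3),
        }
    )
    sampling_rate: float = 10.0  # Hz; keeps waveform peaks exactly on-grid
    cs_duration: float = 4.0  # seconds
    iti: float = 3.0  # seconds between response window end and next onset
    lead_in: float = 5.0  # seconds of trace before the first trial
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.cs_duration <= 0 or self.iti < 0:
            raise ConfigurationError("cs_duration must be > 0 and iti >= 0")


def _beta_ab(mean: float, kappa: float) -> tuple[float, float]:
    eps = 1e-6
    m = min(max(mean, eps), 1 - eps)
    return m * kappa, (1 - m) * kappa


def _draw_params(gp: GroupParams, rng: np.random.Generator) -> RWParameters:
    a, b = _beta_ab(gp.alpha_mean, gp.alpha_kappa)
    alpha = rng.beta(a, b)
    a, b = _beta_ab(gp.rho_mean, gp.rho_kappa)
    rho = rng.beta(a, b)
    a, b = _beta_ab(gp.v0_mean, gp.v0_kappa)
    v0 = rng.beta(a, b)
    return RWParameters(
        alpha=float(alpha),
        rho=float(rho),
        v0=float(v0),
        beta0=float(rng.normal(gp.beta0_mean, gp.beta0_sd)),
        beta1=float(rng.normal(gp.beta1_mean, gp.beta1_sd)),
        sigma=gp.sigma,
    )


_WAVEFORM_PEAK_S = 2.0  # bump peaks 2 s after response-window onset
_WAVEFORM_SHAPE = 2.0


def _bump(tau: np.ndarray) -> np.ndarray:
    """Gamma-like waveform on [0, 8] s, normalised to peak exactly 1 at 2 s."""
    x = np.clip(tau / _WAVEFORM_PEAK_S, 0, None)
    return x**_WAVEFORM_SHAPE * np.exp(_WAVEFORM_SHAPE * (1.0 - x))


def generate_physio(
    config: PhysioGenConfig,
    schedule: TrialSchedule,
    raw_traces: bool = False,
    channel: str = "pupil",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, PhysioTrace]]:
    """Simulate trial responses (and optionally raw traces) for all cohorts.

    Returns ``(responses, truth, traces)``:

    * ``responses`` — tidy frame (subject, group, trial, block, cue,
      reinforced, response) with r_t = beta0 + beta1*V_t + N(0, sigma);
    * ``truth`` — per-subject true parameters;
    * ``traces`` — subject -> :class:`PhysioTrace` when ``raw_traces``;
      each response is embedded as a positive-going bump peaking 2 s after
      window onset on a flat zero baseline (exact round trip through
      peak-change extraction for non-negative responses).
    """
    cue_idx, outcome, instruct, first_plus = _schedule_arrays(schedule)
    n_trials = len(cue_idx)
    rng = np.random.default_rng(config.seed)
    sched_frame = schedule.to_frame()

    resp_rows, truth_rows = [], []
    traces: dict[str, PhysioTrace] = {}

    period = config.cs_duration + 8.0 + config.iti
    onsets = config.lead_in + np.arange(n_trials) * period
    offsets = onsets + config.cs_duration

    for gname, gp in config.groups.items():
        for j in range(gp.n_subjects):
            sid = f"{gname}-{j + 1:02d}"
            params = _draw_params(gp, rng)
            v = _simulate_values_batch(
                params.alpha, params.rho, params.v0, cue_idx, outcome, instruct, first_plus
            )[0]
            r = params.beta0 + params.beta1 * v + rng.normal(0, params.sigma, n_trials)
            resp_rows.append(
                pd.DataFrame(
                    {
                        "subject": sid,
                        "group": gname,
                        "trial": sched_frame["trial"],
                        "block": sched_frame["block"],
                        "cue": sched_frame["cue"],
                        "reinforced": sched_frame["reinforced"],
                        "response": r,
                    }
                )
            )
            truth_rows.append(
                {
                    "subject": sid,
                    "group": gname,
                    **{k: getattr(params, k) for k in ("alpha", "rho", "v0", "beta0", "beta1", "sigma")},
                }
            )
            if raw_traces:
                duration = offsets[-1] + 8.0 + 1.0
                t = np.arange(int(round(duration * config.sampling_rate)) + 1) / config.sampling_rate
                samples = np.zeros_like(t)
                for k in range(n_trials):
                    in_win = (t > offsets[k]) & (t <= offsets[k] + 8.0)
                    samples[in_win] += r[k] * _bump(t[in_win] - offsets[k])
                traces[sid] = PhysioTrace(
                    channel=channel,
                    sampling_rate=config.sampling_rate,
                    samples=samples,
                    events=pd.DataFrame(
                        {"trial": sched_frame["trial"], "onset": onsets, "offset": offsets}
                    ),
                    subject=sid,
                )

    responses = pd.concat(resp_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return responses, truth, traces
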