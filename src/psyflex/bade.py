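"""Bias Against Disconfirmatory Evidence (BADE) scoring.

Subjects rate the plausibility of four interpretations of a scenario after
each of three sequentially disambiguating hints. Two interpretations are
Lures (initially plausible, requiring revision), one is Absurd, one is True
(gradually becomes most plausible). The score of interest is Evidence
Integration Impairment (EII), per scenario:

    EII = Absurd1 + Absurd2 + Absurd3 + LureA3 + LureB3 − True3

i.e. the Absurd ratings after every hint, plus the final Lure ratings,
minus the final True rating — higher values mean a weaker revision of
beliefs in the face of disconfirming hints. The battery has 24 scorable
scenarios (12 emotional, 12 neutral) and 6 distractors, which are never
scored. Subject-level EII is the mean over scorable scenarios (robust to a
missing scenario; a sum-based aggregate is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingDataError, NotScorableError, ValidationError

ROLES = ("True", "Lure-A", "Lure-B", "Absurd")
TIMEPOINTS = (1, 2, 3)
N_EMOTIONAL = 12
N_NEUTRAL = 12
N_DISTRACTOR = 6
SCENARIO_CLASSES = ("emotional", "neutral", "distractor")


@dataclass(frozen=True)
class BadeScenarioRatings:
    """Plausibility ratings of one scenario: 4 roles × 3 timepoints.

    ``ratings`` rows follow :data:`ROLES` order (True, Lure-A, Lure-B,
    Absurd); columns are the three hint timepoints. Scale is [0, scale_max].
    """

    scenario_id: str
    scenario_class: str
    ratings: np.ndarray  # (4, 3), may contain NaN for missing cells
    scale_max: float = 10.0

    def __post_init__(self):
        r = np.asarray(self.ratings, float)
        if r.shape != (4, 3):
            raise ValidationError(f"ratings must be 4x3 (roles x timepoints), got {r.shape}")
        if self.scenario_class not in SCENARIO_CLASSES:
            raise ValidationError(f"unknown scenario class {self.scenario_class!r}")
        finite = r[np.isfinite(r)]
        if np.any(finite < 0) or np.any(finite > self.scale_max):
            raise ValidationError(f"ratings outside [0, {self.scale_max}]")
        object.__setattr__(self, "ratings", r)

    @property
    def scorable(self) -> bool:
        return self.scenario_class != "distractor"

    def rating(self, role: str, timepoint: int) -> float:
        return float(self.ratings[ROLES.index(role), timepoint - 1])


def score_eii(scenario: BadeScenarioRatings) -> float:
    """Per-scenario Evidence Integration Impairment.

    Raises :class:`NotScorableError` on distractors and
    :class:`MissingDataError` if any required cell is NaN. Range for a
    [0, R] scale is [−R, 5R].
    """
    if not scenario.scorable:
        raise NotScorableError(f"scenario {scenario.scenario_id!r} is a distractor")
    r = scenario.rating
    cells = [
        r("Absurd", 1),
        r("Absurd", 2),
        r("Absurd", 3),
        r("Lure-A", 3),
        r("Lure-B", 3),
        r("True", 3),
    ]
    if not np.all(np.isfinite(cells)):
        raise MissingDataError(f"scenario {scenario.scenario_id!r} has missing required ratings")
    return float(sum(cells[:5]) - cells[5])


def aggregate_eii(
    scenarios: list[BadeScenarioRatings],
    method: str = "mean",
    scenario_class: str | None = None,
) -> float:
    """Subject-level EII: mean (default) or sum of per-scenario EII over
    scorable scenarios, optionally restricted to one scenario class."""
    eligible = [s for s in scenarios if s.scorable]
    if scenario_class is not None:
        eligible = [s for s in eligible if s.scenario_class == scenario_class]
    if not eligible:
        raise DegenerateInputError("no scorable scenarios to aggregate")
    vals = [score_eii(s) for s in eligible]
    return float(np.mean(vals) if method == "mean" else np.sum(vals))


def subject_eii_table(
    rating_sets: dict | list,
    method: str = "mean",
    standardize: bool = True,
) -> pd.DataFrame:
    """Aggregate a cohort: one row per subject with raw and (optionally)
    sample-standardised EII (mean 0, SD 1 over the analysed subjects)."""
    if isinstance(rating_sets, list):
        rating_sets = {i: s for i, s in enumerate(rating_sets)}
    rows = [
        {"subject": sid, "eii": aggregate_eii(scen, method=method)}
        for sid, scen in rating_sets.items()
    ]
    df = pd.DataFrame(rows)
    if standardize:
        sd = df["eii"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError("EII has zero variance across subjects")
        df["eii_z"] = (df["eii"] - df["eii"].mean()) / sd
    return df


def eii_exposure_model(
    eii: pd.Series,
    exposures: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
):
    """Regress subject EII on drug-exposure composites (± demographics).

    Delegates to :func:`psyflex.survey_models.fit_adjusted_model`; returns
    its RegressionReport. Inputs are subject-indexed and aligned by index.
    """
    from .survey_models import fit_adjusted_model

    tab = exposures.copy()
    if demographics is not None:
        tab = tab.join(demographics, how="inner")
    tab = tab.join(eii.rename("eii"), how="inner")
    if len(tab.dropna()) < 10:
        raise DegenerateInputError("fewer than 10 complete cases for the EII exposure model")
    predictors = [c for c in tab.columns if c != "eii"]
    return fit_adjusted_model(tab, "eii", predictors)


# -- long-format I/O ---------------------------------------------------------


def ratings_to_long(rating_sets: dict) -> pd.DataFrame:
    """Serialise rating sets to the long CSV layout
    (subject, scenario, scenario_class, role, timepoint, rating)."""
    rows = []
    for sid, scenarios in rating_sets.items():
        for s in scenarios:
            for i, role in enumerate(ROLES):
                for j, tp in enumerate(TIMEPOINTS):
                    rows.append(
                        {
                            "subject": sid,
                            "scenario": s.scenario_id,
                            "scenario_class": s.scenario_class,
                            "role": role,
                            "timepoint": tp,
                            "rating": s.ratings[i, j],
                        }
                    )
    return pd.DataFrame(rows)


def ratings_from_long(df: pd.DataFrame, scale_max: float = 10.0) -> dict:
    """Inverse of :func:`ratings_to_long`."""
    need = {"subject", "scenario", "scenario_class", "role", "timepoint", "rating"}
    if not need <= set(df.columns):
        raise ValidationError(f"long ratings table needs columns {sorted(need)}")
    out: dict = {}
    for (sid, scen), grp in df.groupby(["subject", "scenario"], sort=True):
        mat = np.full((4, 3), np.nan)
        for _, r in grp.iterrows():
            mat[ROLES.index(r["role"]), int(r["timepoint"]) - 1] = r["rating"]
        out.setdefault(sid, []).append(
            BadeScenarioRatings(
                scenario_id=str(scen),
                scenario_class=str(grp["scenario_class"].iloc[0]),
                ratings=mat,
                scale_max=scale_max,
            )
        )
    return out
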