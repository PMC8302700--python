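"""End-to-end orchestration: simulate → score → fit → analyse → report.

:func:`run` reproduces the study's two arms from a single
:class:`RunConfig`, writing tidy CSV tables, advisory figures and a
manifest (package version, seeds, config hash) sufficient to reproduce
every table bit for bit. Tables are the tested surface; figures are
advisory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bade, survey_models, survey_scores, synthetic
from ._version import __version__
from .errors import ConfigurationError
from .fear_task import generate_schedule
from .rw import InstructedRWModel, rho_group_analysis
from .survey_scores import DRUG_CLASSES

_DRUG_TERMS = [f"ever_{c}" for c in DRUG_CLASSES]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``arm`` selects the survey arm, the experimental arm, or both. When
    ``survey_path`` is None the survey table is simulated from
    ``survey_config``; otherwise it is read from CSV/XLSX (with an optional
    codebook mapping).
    """

    arm: str = "both"  # survey | experimental | both
    seed: int = 0
    output_dir: str = "psyflex_run"
    survey_path: str | None = None
    codebook_path: str | None = None
    survey_config: synthetic.SurveyGenConfig | None = None
    physio_config: synthetic.PhysioGenConfig | None = None
    fit_method: str = "mcmc"  # "map" for fast runs
    mcmc_steps: int = 800
    mcmc_burn: int = 300
    bade_impairment: dict = field(default_factory=lambda: {"users": 0.45, "non-users": 0.52})
    bade_impairment_sd: float = 0.15
    contrast_tail: str = "greater"  # hypothesis: users > non-users

    def __post_init__(self):
        if self.arm not in ("survey", "experimental", "both"):
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.survey_path is not None and not Path(self.survey_path).exists():
            raise ConfigurationError(f"survey_path {self.survey_path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "survey_config" in raw and raw["survey_config"] is not None:
            raw["survey_config"] = synthetic.SurveyGenConfig(**raw["survey_config"])
        if "physio_config" in raw and raw["physio_config"] is not None:
            groups = raw["physio_config"].pop("groups", None)
            pc = synthetic.PhysioGenConfig(**raw["physio_config"])
            if groups:
                pc = synthetic.PhysioGenConfig(
                    groups={k: synthetic.GroupParams(**v) for k, v in groups.items()},
                    sampling_rate=pc.sampling_rate,
                    cs_duration=pc.cs_duration,
                    iti=pc.iti,
                    lead_in=pc.lead_in,
                    seed=pc.seed,
                )
            raw["physio_config"] = pc
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if is_dataclass(v):
                d[k] = asdict(v)
        return d


@dataclass
class ReportBundle:
    output_dir: Path
    tables: dict  # name -> Path
    manifest: dict

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.tables[name])


def _write(df: pd.DataFrame, path: Path, tables: dict, name: str):
    df.to_csv(path, index=False, float_format="%.10g")
    tables[name] = path


def _report_frame(report: survey_models.RegressionReport) -> pd.DataFrame:
    df = report.terms.copy()
    df["df_resid"] = report.df_resid
    df["n"] = report.n
    df["r_squared"] = report.r_squared
    df["pseudo_r_squared_cu"] = report.pseudo_r_squared_cu
    df["aic"] = report.aic
    return df


def _contrast_frame(c: survey_models.ContrastReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_1": c.labels[0],
                "group_2": c.labels[1],
                "mean_1": c.mean_1,
                "mean_2": c.mean_2,
                "sd_1": c.sd_1,
                "sd_2": c.sd_2,
                "n_1": c.n_1,
                "n_2": c.n_2,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "tail": c.tail,
                "cohen_d": c.cohen_d,
                "d_ci_lo": c.d_ci[0],
                "d_ci_hi": c.d_ci[1],
            }
        ]
    )


def _run_survey_arm(config: RunConfig, out: Path, tables: dict) -> None:
    if config.survey_path:
        codebook = None
        if config.codebook_path:
            with open(config.codebook_path) as fh:
                codebook = yaml.safe_load(fh)
        df = survey_scores.read_survey(config.survey_path, codebook)
    else:
        scfg = config.survey_config or synthetic.SurveyGenConfig(seed=config.seed)
        df = synthetic.generate_survey(scfg)
    scored = survey_scores.score_survey_table(df)
    scored["is_female"] = (scored["sex"] == "F").astype(int)
    scored["any_diagnosis"] = (
        scored[[c for c in survey_scores.EXCLUSION_FLAGS if c in scored.columns]]
        .astype(bool)
        .any(axis=1)
        .astype(int)
    )

    qc = survey_models.qc_screen(scored["schizotypy_composite"])
    _write(
        pd.DataFrame(
            [
                {
                    "n": qc.n,
                    "shapiro_w": qc.shapiro_w,
                    "shapiro_p": qc.shapiro_p,
                    "n_outliers": qc.n_outliers,
                    "fence_lo": qc.fences[0],
                    "fence_hi": qc.fences[1],
                }
            ]
        ),
        out / "survey_qc.csv",
        tables,
        "survey_qc",
    )

    demo = ["age", "is_female", "education_years"]
    full = survey_models.fit_adjusted_model(
        scored, "schizotypy_composite", _DRUG_TERMS + demo
    )
    _write(_report_frame(full), out / "coefficients_full.csv", tables, "coefficients_full")

    young, filt = survey_scores.young_healthy_filter(scored)
    # re-standardise the composite within the analysis subsample
    young = young.copy()
    young["schizotypy_composite"] = survey_scores.composite_schizotypy(
        young["olife_total"], young["pdi_plus_total"]
    )
    yh = survey_models.fit_adjusted_model(young, "schizotypy_composite", _DRUG_TERMS + demo)
    _write(_report_frame(yh), out / "coefficients_young_healthy.csv", tables, "coefficients_young_healthy")
    _write(
        pd.DataFrame([asdict(filt)]), out / "young_healthy_filter.csv", tables, "young_healthy_filter"
    )

    diag = survey_models.fit_adjusted_model(
        scored.assign(
            diag_by_group=scored["any_diagnosis"] * scored["ever_psychedelics"]
        ),
        "schizotypy_composite",
        ["ever_psychedelics", "any_diagnosis", "diag_by_group"],
    )
    _write(_report_frame(diag), out / "coefficients_diagnosis.csv", tables, "coefficients_diagnosis")

    facet_frames = []
    for f in survey_scores.FACETS:
        rep = survey_models.fit_adjusted_model(scored, f"olife_{f}", _DRUG_TERMS + demo)
        fr = _report_frame(rep)
        fr.insert(0, "facet", f)
        facet_frames.append(fr)
    _write(pd.concat(facet_frames, ignore_index=True), out / "coefficients_facets.csv", tables, "coefficients_facets")

    groups = np.where(scored["ever_psychedelics"] == 1, "user", "non-user")
    # "user" sorts after "non-user": test non-user < user via tail="less"
    contrast = survey_models.group_contrast(
        scored["schizotypy_composite"], groups, tail="less"
    )
    _write(_contrast_frame(contrast), out / "survey_contrast.csv", tables, "survey_contrast")

    try:
        from .plotting import coefficient_plot

        coefficient_plot(
            {"full sample": full, "young healthy": yh},
            out / "fig_survey_coefficients.png",
        )
    except Exception:
        pass  # figures are advisory


def _run_experimental_arm(config: RunConfig, out: Path, tables: dict) -> None:
    rng = np.random.default_rng(config.seed + 1)
    schedule = generate_schedule(config.seed)
    _write(schedule.to_frame(), out / "schedule.csv", tables, "schedule")

    pcfg = config.physio_config or synthetic.PhysioGenConfig(seed=config.seed + 2)
    responses, truth, _ = synthetic.generate_physio(pcfg, schedule)
    _write(responses, out / "trial_responses.csv", tables, "trial_responses")
    _write(truth, out / "ground_truth_parameters.csv", tables, "ground_truth_parameters")

    model = InstructedRWModel(responses, schedule)
    fit = model.fit(
        method=config.fit_method,
        seed=config.seed + 3,
        n_steps=config.mcmc_steps,
        n_burn=config.mcmc_burn,
    )
    _write(fit.to_frame(), out / "rw_estimates.csv", tables, "rw_estimates")

    subj_group = truth.set_index("subject")["group"]
    subjects = fit.estimates.index
    is_user = (subj_group.reindex(subjects) == "users").to_numpy()

    # drug-exposure composites for the experimental subsample: psychedelic
    # frequency/recency of users generated to track their true instruction
    # sensitivity (more recent/frequent use <-> larger instructed effects);
    # stimulant and MDMA exposures are unrelated noise covariates
    true_rho = truth.set_index("subject")["rho"].reindex(subjects).to_numpy()
    rho_z = (true_rho - true_rho[is_user].mean()) / max(true_rho[is_user].std(), 1e-9)
    freq = np.clip(np.round(4 + 1.5 * rho_z + rng.normal(0, 0.8, len(subjects))), 1, 7)
    rec = np.clip(np.round(4 + 1.5 * rho_z + rng.normal(0, 0.8, len(subjects))), 1, 7)
    expo_psy = survey_scores.exposure_composite(freq, rec, never_user=~is_user)
    exposures = pd.DataFrame(
        {
            "exposure_psychedelics": expo_psy,
            "exposure_stimulants": rng.normal(0, 1, len(subjects)),
            "exposure_mdma": rng.normal(0, 1, len(subjects)),
            "age": rng.integers(20, 36, len(subjects)),
            "is_female": rng.integers(0, 2, len(subjects)),
        },
        index=subjects,
    )

    group_labels = pd.Series(
        np.where(is_user, "a_users", "b_non-users"), index=subjects
    )  # users sort first => tail="greater" tests users > non-users
    contrast, regression = rho_group_analysis(
        fit, group_labels, exposures=exposures, tail=config.contrast_tail
    )
    _write(_contrast_frame(contrast), out / "rho_contrast.csv", tables, "rho_contrast")
    _write(_report_frame(regression), out / "rho_regression.csv", tables, "rho_regression")

    # BADE: users planted with slightly *better* evidence integration
    w_mean = np.where(is_user, config.bade_impairment["users"], config.bade_impairment["non-users"])
    w = np.clip(w_mean + rng.normal(0, config.bade_impairment_sd, len(subjects)), 0, 1)
    ratings = synthetic.generate_bade_ratings(
        n_subjects=len(subjects), impairment_level=w, seed=config.seed + 4
    )
    ratings = {subjects[i]: v for i, v in enumerate(ratings.values())}
    eii = bade.subject_eii_table(ratings)
    eii["group"] = group_labels.reindex(eii["subject"]).to_numpy()
    _write(eii, out / "eii.csv", tables, "eii")
    eii_contrast = survey_models.group_contrast(eii["eii_z"], eii["group"], tail="less")
    _write(_contrast_frame(eii_contrast), out / "eii_contrast.csv", tables, "eii_contrast")
    eii_reg = bade.eii_exposure_model(
        eii.set_index("subject")["eii_z"],
        exposures[["exposure_psychedelics", "exposure_stimulants", "exposure_mdma"]],
        demographics=exposures[["age", "is_female"]],
    )
    _write(_report_frame(eii_reg), out / "eii_regression.csv", tables, "eii_regression")

    try:
        from .plotting import coefficient_plot, rho_group_plot

        rho_group_plot(fit.estimates["rho"], group_labels, out / "fig_rho_groups.png")
        coefficient_plot({"EII exposure model": eii_reg}, out / "fig_eii_coefficients.png")
    except Exception:
        pass


def run(config: RunConfig) -> ReportBundle:
    """Execute the configured arms; deterministic given the config seeds."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict = {}
    stages = []
    if config.arm in ("survey", "both"):
        stages.append(("survey", _run_survey_arm))
    if config.arm in ("experimental", "both"):
        stages.append(("experimental", _run_experimental_arm))
    for name, fn in stages:
        try:
            fn(config, out, tables)
        except Exception as exc:  # partial outputs are retained on disk
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    cfg_dict = config.to_dict()
    hashed = {k: v for k, v in cfg_dict.items() if k != "output_dir"}
    manifest = {
        "psyflex_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(hashed, sort_keys=True).encode()
        ).hexdigest(),
        "tables": {k: str(v.name) for k, v in tables.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(output_dir=out, tables=tables, manifest=manifest)
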