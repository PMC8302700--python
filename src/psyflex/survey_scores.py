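"""Questionnaire scoring, composite scores and inclusion filtering.

Instruments:

* **O-LIFE** — 43-item short-form Oxford-Liverpool Inventory of Feelings
  and Experiences; binary items counted into a total and four facets
  (unusual experiences UE, cognitive disorganisation CD, introvertive
  anhedonia IA, impulsive nonconformity IN) that partition the total. The
  facet key ships as an editable YAML data file.
* **PDI+** — 21-item Peters Delusion Inventory plus 5 unusual-experience
  items from CAPE-42; total = endorsement count, with a PDI-21 subtotal
  excluding the CAPE items. An optional "disturbance" score is the mean
  distress rating over endorsed items (secondary outcome).

Composites are z-score merges: each input is standardised against the
analysis sample (R ``scale()`` convention, ddof = 1), averaged, and the
average re-standardised. The schizotypy composite merges O-LIFE and PDI+
totals; the drug-exposure composite merges frequency and recency ratings,
with never-users set to the subsample minimum (switchable to exclusion).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateInputError, ValidationError

N_OLIFE = 43
N_PDI_PLUS = 26
N_PDI = 21
FACETS = ("UE", "CD", "IA", "IN")
DRUG_CLASSES = ("alcohol", "tobacco", "cannabis", "psychedelics", "mdma", "stimulants", "opiates")
EXCLUSION_FLAGS = ("diag_psychiatric", "diag_neurological", "diag_head_trauma", "diag_serious_medical")


def load_olife_key(path=None) -> dict:
    """Load the O-LIFE facet key (the packaged default, or a custom YAML)."""
    if path is None:
        ref = importlib.resources.files("psyflex") / "data" / "olife_key.yaml"
        key = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            key = yaml.safe_load(fh)
    items = sorted(i for f in key["facets"].values() for i in f)
    if items != list(range(1, N_OLIFE + 1)):
        raise ValidationError("O-LIFE key facets must partition items 1..43")
    return key


def _check_binary(items, n_expected: int, name: str) -> np.ndarray:
    arr = np.asarray(items, float)
    if arr.ndim != 1 or len(arr) != n_expected:
        raise ValidationError(f"{name} needs {n_expected} item responses, got shape {arr.shape}")
    if not np.all(np.isin(arr[np.isfinite(arr)], (0.0, 1.0))) or np.any(~np.isfinite(arr)):
        raise ValidationError(f"{name} responses must be binary (0/1) and complete")
    return arr.astype(int)


@dataclass(frozen=True)
class SchizotypyScores:
    olife_total: int
    facets: dict  # UE/CD/IA/IN counts; always sums to olife_total
    pdi_plus_total: int | None = None
    pdi21_subtotal: int | None = None


def score_olife(items, key: dict | None = None) -> SchizotypyScores:
    """Count schizotypy-keyed endorsements: total + the four facet scores."""
    arr = _check_binary(items, N_OLIFE, "O-LIFE")
    key = key or load_olife_key()
    for i in key.get("reverse", []):
        arr[i - 1] = 1 - arr[i - 1]
    facets = {f: int(arr[[i - 1 for i in idx]].sum()) for f, idx in key["facets"].items()}
    return SchizotypyScores(olife_total=int(arr.sum()), facets=facets)


def score_pdi_plus(items) -> tuple[int, int]:
    """PDI+ total (26 items) and PDI-21 subtotal (excluding the 5 CAPE items,
    which occupy positions 22–26 of the codebook vector)."""
    arr = _check_binary(items, N_PDI_PLUS, "PDI+")
    return int(arr.sum()), int(arr[:N_PDI].sum())


def pdi_disturbance(items, distress) -> float:
    """Mean distress rating over endorsed PDI+ items (secondary outcome).

    Returns NaN when nothing is endorsed.
    """
    arr = _check_binary(items, N_PDI_PLUS, "PDI+")
    distress = np.asarray(distress, float)
    if len(distress) != N_PDI_PLUS:
        raise ValidationError("distress ratings must align with the 26 PDI+ items")
    endorsed = arr == 1
    if not endorsed.any():
        return float("nan")
    return float(np.nanmean(distress[endorsed]))


def zscore(x, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, float)
    sd = np.nanstd(x, ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero variance: cannot standardise")
    return (x - np.nanmean(x)) / sd


def composite_schizotypy(olife_totals, pdi_totals, standardize_first: bool = True) -> np.ndarray:
    """Composite schizotypy z-score merging O-LIFE and PDI+ totals.

    Default: standardise each total against the analysis sample, average,
    re-standardise the average (mean 0, SD 1 under ddof = 1). With
    ``standardize_first=False`` the raw totals are averaged first and the
    average standardised once — both orders give identically *ranked*
    composites; they differ only in relative weighting.
    """
    olife = np.asarray(olife_totals, float)
    pdi = np.asarray(pdi_totals, float)
    if olife.shape != pdi.shape or olife.ndim != 1:
        raise ValidationError("olife and pdi totals must be equal-length 1-D vectors")
    if len(olife) < 2:
        raise DegenerateInputError("composite needs at least 2 respondents")
    if standardize_first:
        merged = (zscore(olife) + zscore(pdi)) / 2.0
    else:
        merged = (olife + pdi) / 2.0
    return zscore(merged)


def exposure_composite(
    frequency,
    recency,
    never_user=None,
    never_user_policy: str = "minimum",
) -> np.ndarray:
    """Drug-exposure composite: z-merge of frequency and recency ratings.

    Standardisation uses only ever-users with complete ratings (the
    subsample with extended drug data); missing ratings for a user yield
    NaN. Never-users get the subsample minimum composite
    (``never_user_policy="minimum"``, the default, so they can enter the
    experimental-arm regressions) or NaN (``"exclude"``).
    """
    freq = np.asarray(frequency, float)
    rec = np.asarray(recency, float)
    if freq.shape != rec.shape:
        raise ValidationError("frequency and recency must align")
    never = (
        np.zeros(freq.shape, bool) if never_user is None else np.asarray(never_user, bool)
    )
    users = ~never
    complete = users & np.isfinite(freq) & np.isfinite(rec)
    if complete.sum() < 2:
        raise DegenerateInputError("need >= 2 ever-users with complete ratings")
    out = np.full(freq.shape, np.nan)
    fz = np.full(freq.shape, np.nan)
    rz = np.full(freq.shape, np.nan)
    fz[complete] = zscore(freq[complete])
    rz[complete] = zscore(rec[complete])
    merged = (fz[complete] + rz[complete]) / 2.0
    out[complete] = zscore(merged)
    if never_user_policy == "minimum":
        out[never] = np.nanmin(out[complete])
    elif never_user_policy != "exclude":
        raise ValueError(f"unknown never_user_policy {never_user_policy!r}")
    return out


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    n_age_excluded: int
    n_flag_excluded: int
    n_missing_age: int


def young_healthy_filter(
    records: pd.DataFrame,
    age_range: tuple[float, float] = (18.0, 35.0),
    flag_cols: tuple[str, ...] = EXCLUSION_FLAGS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the young-healthy inclusion criteria.

    Retains records with ``age_range[0] <= age <= age_range[1]`` and every
    present exclusion flag false. Records with missing age are excluded and
    counted. Idempotent.
    """
    if "age" not in records.columns:
        raise ValidationError("records need an 'age' column")
    age = pd.to_numeric(records["age"], errors="coerce")
    missing_age = age.isna()
    age_ok = (age >= age_range[0]) & (age <= age_range[1]) & ~missing_age
    flags_present = [c for c in flag_cols if c in records.columns]
    flag_bad = pd.Series(False, index=records.index)
    for c in flags_present:
        flag_bad |= records[c].fillna(False).astype(bool)
    keep = age_ok & ~flag_bad
    report = FilterReport(
        n_input=len(records),
        n_retained=int(keep.sum()),
        n_age_excluded=int((~age_ok & ~missing_age).sum()),
        n_flag_excluded=int((flag_bad & age_ok).sum()),
        n_missing_age=int(missing_age.sum()),
    )
    return records.loc[keep].copy(), report


# -- table-level scoring -----------------------------------------------------


def score_survey_table(df: pd.DataFrame, key: dict | None = None) -> pd.DataFrame:
    """Score a whole survey table (generator layout or codebook-mapped).

    Expects item columns ``olife_item_1..43`` and ``pdi_item_1..26``; adds
    totals, facets and the schizotypy composite. Non-item columns pass
    through untouched.
    """
    key = key or load_olife_key()
    olife_cols = [f"olife_item_{i}" for i in range(1, N_OLIFE + 1)]
    pdi_cols = [f"pdi_item_{i}" for i in range(1, N_PDI_PLUS + 1)]
    for col in olife_cols + pdi_cols:
        if col not in df.columns:
            raise ValidationError(f"survey table missing item column {col}")
    out = df.copy()
    olife_mat = df[olife_cols].to_numpy(int)
    for i in key.get("reverse", []):
        olife_mat[:, i - 1] = 1 - olife_mat[:, i - 1]
    out["olife_total"] = olife_mat.sum(axis=1)
    for f, idx in key["facets"].items():
        out[f"olife_{f}"] = olife_mat[:, [i - 1 for i in idx]].sum(axis=1)
    pdi_mat = df[pdi_cols].to_numpy(int)
    out["pdi_plus_total"] = pdi_mat.sum(axis=1)
    out["pdi21_subtotal"] = pdi_mat[:, :N_PDI].sum(axis=1)
    out["schizotypy_composite"] = composite_schizotypy(out["olife_total"], out["pdi_plus_total"])
    return out


def read_survey(path, codebook: dict | None = None) -> pd.DataFrame:
    """Read a survey table from CSV or XLSX.

    ``codebook`` optionally maps source column names to the package's
    canonical names (e.g. ``{"OLIFE_01": "olife_item_1"}``).
    """
    path = str(path)
    df = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    if codebook:
        df = df.rename(columns=codebook)
    return df
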