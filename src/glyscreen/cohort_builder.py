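"""From raw EHR tables to analyzable cohort rows.

Cohort entry follows the incident-user design: a patient enters at the DM-2
diagnosis date (the index date) if an antidiabetic purchase occurs on or
after it and at least one HbA1c lab falls inside the closed outcome window
[window_start, window_end] days post-index. The outcome is success iff the
arithmetic mean of in-window HbA1c values is strictly below the threshold
(default 6.5%). Covariates (weight, BMI) are summarized over all pre-index
measurements by mean/median/max/min/sample-SD; age is a single value at the
index date; smoking is encoded ordinally (never=0, past=1, current=2).

The cohort is a pandas DataFrame indexed by patient_id; drug-class exposure
flags live in 0/1 columns prefixed ``rx_``.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingCovariateError, ValidationError
from .synthetic_ehr import EHRTables

__all__ = [
    "CohortCriteria",
    "FeatureSummary",
    "CohortRow",
    "extract_cohort",
    "label_outcome",
    "summarize_series",
    "eligible_drug_classes",
    "write_cohort",
    "DEFAULT_FEATURES",
    "EXPOSURE_PREFIX",
]

logger = logging.getLogger(__name__)

EXPOSURE_PREFIX = "rx_"

#: Covariate columns used for matching: the five summary statistics of
#: weight and BMI, plus age at index and the ordinal smoking code.
DEFAULT_FEATURES = (
    "weight_mean",
    "weight_median",
    "weight_max",
    "weight_min",
    "weight_sd",
    "bmi_mean",
    "bmi_median",
    "bmi_max",
    "bmi_min",
    "bmi_sd",
    "age",
    "smoking",
)

_SMOKING_CODES = {"never": 0, "past": 1, "current": 2}


@dataclass(frozen=True)
class CohortCriteria:
    """Cohort-entry, outcome and eligibility rules."""

    outcome_lab_code: str = "HGA1C"
    success_threshold: float = 6.5
    window_start: int = 90
    window_end: int = 365
    min_group_size: int = 200
    exposure_window: str = "any_time_before_window_end"
    diagnosis_code: str = "DM2"
    antidiabetic_prefix: str = "AD_"

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValidationError("window_start must be < window_end")
        if self.success_threshold <= 0:
            raise ValidationError("success_threshold must be positive")
        if self.min_group_size < 1:
            raise ValidationError("min_group_size must be >= 1")
        if self.exposure_window not in ("any_time_before_window_end", "post_diagnosis_only"):
            raise ValidationError(f"unknown exposure_window {self.exposure_window!r}")


@dataclass(frozen=True)
class FeatureSummary:
    """Five-statistic summary of one covariate series."""

    mean: float
    median: float
    maximum: float
    minimum: float
    sd: float
    n_observations: int


@dataclass
class CohortRow:
    """One analyzable patient, as a plain object view of a cohort frame row."""

    patient_id: str
    index_date: int
    first_treatment_date: int
    features: dict
    outcome: str  # "success" / "failure"
    exposures: dict
    antidiabetic_class: str


def summarize_series(values) -> FeatureSummary:
    """Mean/median/max/min/sample-SD of a covariate series.

    The SD uses the n-1 denominator and is 0 for a single observation; the
    median of an even-length series is the midpoint average. Raises
    :class:`MissingCovariateError` on an empty series.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise MissingCovariateError("cannot summarize an empty covariate series")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return FeatureSummary(
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        maximum=float(np.max(v)),
        minimum=float(np.min(v)),
        sd=sd,
        n_observations=int(v.size),
    )


def label_outcome(labs, index_date: int, criteria: CohortCriteria) -> str:
    """Label one patient from dated outcome-lab values.

    ``labs`` is an iterable of (day, value) pairs already filtered to the
    outcome lab code. Returns "success" iff the mean of values inside the
    closed window [index+window_start, index+window_end] is strictly below
    the threshold, "failure" if a window mean exists but is >= threshold,
    and "undefined" when no value falls in the window.
    """
    lo = index_date + criteria.window_start
    hi = index_date + criteria.window_end
    in_window = [v for d, v in labs if lo <= d <= hi]
    if not in_window:
        return "undefined"
    return "success" if math.fsum(in_window) / len(in_window) < criteria.success_threshold else "failure"


def _as_tables(bundles) -> EHRTables:
    if isinstance(bundles, EHRTables):
        return bundles
    return EHRTables.from_bundles(list(bundles))


def extract_cohort(bundles, criteria: CohortCriteria | None = None) -> pd.DataFrame:
    """Build the analyzable cohort from raw tables or patient bundles.

    Returns a DataFrame indexed by patient_id with columns: index_date,
    first_treatment_date, antidiabetic_class, the :data:`DEFAULT_FEATURES`
    covariates, ``outcome`` (1=success, 0=failure), and one 0/1 ``rx_<class>``
    column per concomitant drug class observed in the purchase stream.
    Patients without a qualifying diagnosis, treatment, outcome lab, or any
    pre-index weight/BMI measurement are excluded; exclusion counts are
    recorded in ``cohort.attrs`` and logged.
    """
    criteria = criteria or CohortCriteria()
    t = _as_tables(bundles)

    dx = t.diagnoses[t.diagnoses["code"] == criteria.diagnosis_code]
    index_date = dx.groupby("patient_id")["date_days"].min().rename("index_date")

    rx = t.purchases.merge(index_date, on="patient_id", how="inner")
    is_ad = rx["drug_class"].str.startswith(criteria.antidiabetic_prefix)
    ad = rx[is_ad & (rx["date_days"] >= rx["index_date"])]
    ad = ad.sort_values(["patient_id", "date_days", "drug_class"], kind="mergesort")
    first_ad = ad.groupby("patient_id").first()
    first_ad = first_ad.rename(
        columns={"date_days": "first_treatment_date", "drug_class": "antidiabetic_class"}
    )[["first_treatment_date", "antidiabetic_class"]]

    labs = t.labs[t.labs["test_code"] == criteria.outcome_lab_code].merge(
        index_date, on="patient_id", how="inner"
    )
    rel = labs["date_days"] - labs["index_date"]
    in_win = labs[(rel >= criteria.window_start) & (rel <= criteria.window_end)]
    window_mean = in_win.groupby("patient_id")["value"].mean()
    outcome = (window_mean < criteria.success_threshold).astype(int).rename("outcome")

    # pre-index weight/BMI summaries
    cov = t.labs[t.labs["test_code"].isin(["WEIGHT", "BMI"])].merge(
        index_date, on="patient_id", how="inner"
    )
    cov = cov[cov["date_days"] <= cov["index_date"]]
    agg = cov.groupby(["patient_id", "test_code"])["value"].agg(
        ["mean", "median", "max", "min", "std", "count"]
    )
    agg["std"] = agg["std"].where(agg["count"] > 1, 0.0)
    feat = agg.drop(columns="count").unstack("test_code")
    feat.columns = [
        f"{code.lower()}_{'sd' if stat == 'std' else stat}"
        for stat, code in feat.columns
    ]

    base = t.patients.set_index("patient_id")
    cohort = (
        index_date.to_frame()
        .join(first_ad, how="inner")
        .join(outcome, how="left")
        .join(feat, how="left")
        .join(base[["sex", "birth_offset_days", "smoking"]], how="left")
    )
    n_no_outcome = int(cohort["outcome"].isna().sum())
    needed = [f"{c}_{s}" for c in ("weight", "bmi") for s in ("mean", "median", "max", "min", "sd")]
    for col in needed:
        if col not in cohort.columns:
            cohort[col] = np.nan
    n_no_cov = int(cohort[needed].isna().any(axis=1).sum())
    cohort = cohort.dropna(subset=["outcome"] + needed)

    cohort["outcome"] = cohort["outcome"].astype(int)
    cohort["age"] = (cohort["birth_offset_days"] + cohort["index_date"]) / 365.25
    cohort["smoking"] = cohort["smoking"].map(_SMOKING_CODES).astype(float)
    cohort = cohort.drop(columns=["birth_offset_days"])

    # exposure flags for concomitant (non-antidiabetic) classes
    con = rx[~is_ad].copy()
    classes = sorted(con["drug_class"].unique())  # stable column set per class seen
    if criteria.exposure_window == "post_diagnosis_only":
        keep = (con["date_days"] >= con["index_date"]) & (
            con["date_days"] <= con["index_date"] + criteria.window_end
        )
    else:
        keep = con["date_days"] <= con["index_date"] + criteria.window_end
    con = con[keep]
    con = con[con["patient_id"].isin(cohort.index)]
    expo = (
        con.assign(flag=1)
        .pivot_table(index="patient_id", columns="drug_class", values="flag", aggfunc="max")
        .reindex(cohort.index)
        .fillna(0)
        .astype(int)
    )
    for cls in classes:
        cohort[EXPOSURE_PREFIX + cls] = expo[cls] if cls in expo.columns else 0

    n_total = len(index_date)
    cohort.attrs["drug_classes"] = classes
    cohort.attrs["n_diagnosed"] = n_total
    cohort.attrs["n_excluded_no_outcome_lab"] = n_no_outcome
    cohort.attrs["n_excluded_no_covariates"] = n_no_cov
    if cohort.empty:
        logger.warning("extract_cohort produced an empty cohort")
    else:
        logger.info(
            "cohort: %d/%d diagnosed patients analyzable (%d lacked an in-window "
            "outcome lab, %d lacked pre-index covariates)",
            len(cohort), n_total, n_no_outcome, n_no_cov,
        )
    return cohort


def cohort_row(cohort: pd.DataFrame, patient_id: str) -> CohortRow:
    """Materialize one cohort frame row as a :class:`CohortRow` object."""
    r = cohort.loc[patient_id]
    features = {c: float(r[c]) for c in DEFAULT_FEATURES}
    exposures = {
        c[len(EXPOSURE_PREFIX):]: bool(r[c])
        for c in cohort.columns
        if c.startswith(EXPOSURE_PREFIX)
    }
    return CohortRow(
        patient_id=patient_id,
        index_date=int(r["index_date"]),
        first_treatment_date=int(r["first_treatment_date"]),
        features=features,
        outcome="success" if int(r["outcome"]) == 1 else "failure",
        exposures=exposures,
        antidiabetic_class=str(r["antidiabetic_class"]),
    )


def eligible_drug_classes(cohort: pd.DataFrame, criteria: CohortCriteria | None = None) -> list:
    """Concomitant classes with at least ``min_group_size`` exposed patients.

    Antidiabetic classes never appear (they are not exposure columns).
    Sorted by descending exposed count, ties broken by class code.
    """
    criteria = criteria or CohortCriteria()
    if cohort.empty:
        raise ValidationError("eligible_drug_classes requires a non-empty cohort")
    counts = {
        c[len(EXPOSURE_PREFIX):]: int(cohort[c].sum())
        for c in cohort.columns
        if c.startswith(EXPOSURE_PREFIX)
    }
    keep = [(cls, n) for cls, n in counts.items() if n >= criteria.min_group_size]
    keep.sort(key=lambda t: (-t[1], t[0]))
    return [cls for cls, _ in keep]


def write_cohort(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the cohort as CSV: identifiers, outcome, features, exposure flags."""
    out = cohort.reset_index()
    if "index" in out.columns:
        out = out.rename(columns={"index": "patient_id"})
    out.to_csv(path, index=False, lineterminator="\n")
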