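"""Synthetic EHR generator with known ground truth.

Emulates the raw material of an incident type-2-diabetes pharmacoepidemiology
study: each simulated patient carries a DM-2 diagnosis, a first antidiabetic
purchase on or after it, dated weight/BMI measurements, HbA1c labs, and
purchases of concomitant drug classes. One "planted" class — an
alpha-1-adrenoceptor-antagonist stand-in taken almost exclusively by older
men (confounding by indication, as for benign prostatic hyperplasia) —
carries a configurable true log-odds benefit on glycemic-control success;
every other class is a true null. Because the generator records each
patient's intended success label and exposure, every downstream stage
(labeling, matching, balance diagnostics, the screen itself) can be checked
against truth.

Success is generated through a logistic model in age, BMI and smoking plus
the planted-class exposure; the realized label is then expressed as HbA1c
values in the 90–365-day outcome window drawn around 6.5% shifted down
(success) or up (failure), so that outcome labeling from the lab stream can
be validated against the generative truth.

All dates are integer days on a single study axis starting at day 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import SchemaError, ValidationError

__all__ = [
    "SimConfig",
    "PatientBundle",
    "EHRTables",
    "generate_population",
    "write_tables",
    "read_tables",
    "ALPHA_BLOCKER_CLASS",
    "ANTIDIABETIC_CLASSES",
    "ALPHA_BLOCKER_COMPONENTS",
]

#: Drug-class code of the planted alpha-1-antagonist-like class.
ALPHA_BLOCKER_CLASS = "ALPHA1"

#: Antidiabetic class codes (the exposure that defines cohort entry, never screened).
ANTIDIABETIC_CLASSES = ("AD_BIGUANIDE", "AD_SULFONYL", "AD_DPP4", "AD_INSULIN")
_ANTIDIABETIC_SHARES = (0.75, 0.15, 0.07, 0.03)

#: Components of the planted class, in the order of SimConfig.component_mix.
ALPHA_BLOCKER_COMPONENTS = ("alfuzosin", "doxazosin", "terazosin", "tamsulosin")

# Covariate effects (log-odds) in the success-generating model. Mild by
# design: in the source population glycemic control varies only gently with
# demographics, so the matched control arm of the planted class sits a little
# below the marginal success rate.
_SUCCESS_B_AGE = -0.10  # per SD of age
_SUCCESS_B_BMI = -0.06  # per SD of BMI
_SUCCESS_B_SMOKING = -0.05  # per smoking level (never=0, past=1, current=2)

# HbA1c window values are centred at threshold -/+ this shift for
# success/failure, so labeling from labs recovers the generative label.
_HBA1C_SHIFT = 0.8
_HBA1C_THRESHOLD = 6.5

_FEMALE_UPTAKE_PENALTY = -4.5  # log-odds; the planted class is a BPH drug


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults reproduce the screen's reference conditions: 73 concomitant
    drug classes, 54% marginal success, a planted class with prevalence
    ~7.5% of the cohort and a log-odds benefit of 0.327
    (= logit(0.61) - logit(0.53)), and purchaser counts for a handful of
    classes drawn to straddle the 200-patient eligibility cutoff.
    """

    n_patients: int
    seed: int = 0
    n_drug_classes: int = 73
    base_success_rate: float = 0.54
    planted_class_id: str | None = ALPHA_BLOCKER_CLASS
    planted_effect: float = 0.327
    planted_prevalence: float = 0.075
    confounding_strength: float = 0.6
    min_purchasers_target: int = 200
    component_mix: tuple = (0.27, 0.18, 0.06, 0.49)
    hba1c_noise_sd: float = 0.3
    visit_rate: float = 4.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError(f"n_patients must be positive, got {self.n_patients}")
        for name in ("base_success_rate", "planted_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if abs(sum(self.component_mix) - 1.0) > 1e-9:
            raise ValidationError(
                f"component_mix must sum to 1, got sum={sum(self.component_mix)!r}"
            )
        if any(p < 0 for p in self.component_mix):
            raise ValidationError("component_mix entries must be non-negative")
        if self.n_drug_classes < 1:
            raise ValidationError("n_drug_classes must be >= 1")
        if self.hba1c_noise_sd < 0 or self.visit_rate < 0:
            raise ValidationError("hba1c_noise_sd and visit_rate must be non-negative")


@dataclass
class PatientBundle:
    """One patient's demographics plus dated diagnosis/purchase/lab streams.

    Dated series are lists of tuples sorted by date: ``diagnoses`` as
    (day, code), ``purchases`` as (day, drug_class, component), ``labs`` as
    (day, test_code, value). ``weights`` and ``bmis`` are convenience views
    of the WEIGHT/BMI lab streams as (day, value).
    """

    patient_id: str
    sex: str
    birth_offset: int
    smoking: str
    diagnoses: list = field(default_factory=list)
    purchases: list = field(default_factory=list)
    labs: list = field(default_factory=list)

    @property
    def weights(self) -> list:
        return [(d, v) for d, code, v in self.labs if code == "WEIGHT"]

    @property
    def bmis(self) -> list:
        return [(d, v) for d, code, v in self.labs if code == "BMI"]


_PATIENT_COLS = ["patient_id", "sex", "birth_offset_days", "smoking"]
_DIAGNOSIS_COLS = ["patient_id", "code", "date_days"]
_PURCHASE_COLS = ["patient_id", "drug_class", "component", "date_days"]
_LAB_COLS = ["patient_id", "test_code", "value", "date_days"]


@dataclass
class EHRTables:
    """The four EHR tables of a population, plus generator truth when available.

    Iterating yields one :class:`PatientBundle` per patient, so an
    ``EHRTables`` can be used anywhere a bundle collection is expected.
    ``truth`` (generated populations only) has one row per patient with the
    success probability, realized success label, and planted-class exposure.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    purchases: pd.DataFrame
    labs: pd.DataFrame
    truth: pd.DataFrame | None = None
    config: SimConfig | None = None

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientBundle]:
        dx = {k: g for k, g in self.diagnoses.groupby("patient_id", sort=False)}
        rx = {k: g for k, g in self.purchases.groupby("patient_id", sort=False)}
        lb = {k: g for k, g in self.labs.groupby("patient_id", sort=False)}
        empty_dx = self.diagnoses.iloc[0:0]
        empty_rx = self.purchases.iloc[0:0]
        empty_lb = self.labs.iloc[0:0]
        for row in self.patients.itertuples(index=False):
            d = dx.get(row.patient_id, empty_dx).sort_values(["date_days", "code"])
            p = rx.get(row.patient_id, empty_rx).sort_values(["date_days", "drug_class"])
            l = lb.get(row.patient_id, empty_lb).sort_values(["date_days", "test_code"])
            yield PatientBundle(
                patient_id=row.patient_id,
                sex=row.sex,
                birth_offset=int(row.birth_offset_days),
                smoking=row.smoking,
                diagnoses=list(zip(d["date_days"].astype(int), d["code"])),
                purchases=list(
                    zip(p["date_days"].astype(int), p["drug_class"], p["component"])
                ),
                labs=list(zip(l["date_days"].astype(int), l["test_code"], l["value"])),
            )

    @classmethod
    def from_bundles(cls, bundles: Sequence[PatientBundle]) -> "EHRTables":
        pat, dx, rx, lb = [], [], [], []
        for b in bundles:
            pat.append((b.patient_id, b.sex, b.birth_offset, b.smoking))
            dx.extend((b.patient_id, code, day) for day, code in b.diagnoses)
            rx.extend((b.patient_id, cls_, comp, day) for day, cls_, comp in b.purchases)
            lb.extend((b.patient_id, code, val, day) for day, code, val in b.labs)
        return cls(
            patients=pd.DataFrame(pat, columns=_PATIENT_COLS),
            diagnoses=pd.DataFrame(dx, columns=_DIAGNOSIS_COLS),
            purchases=pd.DataFrame(rx, columns=_PURCHASE_COLS),
            labs=pd.DataFrame(lb, columns=_LAB_COLS),
        )


def _drug_class_codes(config: SimConfig) -> tuple[list, list, list]:
    """Concomitant class codes: (planted or [], common, straddlers)."""
    planted = [config.planted_class_id] if config.planted_class_id else []
    n_other = config.n_drug_classes - len(planted)
    n_straddle = min(5, max(0, n_other - 1))
    n_common = n_other - n_straddle
    common = [f"C{i:03d}" for i in range(1, n_common + 1)]
    straddle = [f"S{i:03d}" for i in range(1, n_straddle + 1)]
    return planted, common, straddle


def _calibrate_intercept(offsets: np.ndarray, target: float) -> float:
    """Intercept a such that mean(expit(a + offsets)) == target."""

    def gap(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + offsets))))) - target

    return brentq(gap, -30.0, 30.0, xtol=1e-12)


def generate_population(config: SimConfig) -> EHRTables:
    """Draw a full synthetic population under ``config``.

    Deterministic under a fixed seed. Uptake of the planted class follows a
    logistic model in age and BMI (scaled by ``confounding_strength``) with a
    strong male shift; every other concomitant class is purchased
    independently of covariates and outcome. The success-model intercept and
    the planted-uptake intercept are calibrated numerically on the realized
    covariates so the marginal success rate and planted prevalence hit their
    configured values.
    """
    cfg = config  # validated in __post_init__
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    patient_ids = np.array([f"P{i:07d}" for i in range(1, n + 1)])
    male = rng.random(n) < 0.48
    age = np.clip(rng.normal(62.0, 11.0, n), 25.0, 90.0)
    smoking_lvl = rng.choice(3, size=n, p=[0.55, 0.25, 0.20])
    dx_date = rng.integers(365, 1501, n)
    birth_offset = np.round(age * 365.25).astype(int)

    weight_base = np.where(
        male, rng.normal(84.0, 12.0, n), rng.normal(72.0, 13.0, n)
    ).clip(40.0, 160.0)
    bmi_base = np.clip(rng.normal(29.5, 4.5, n), 16.0, 55.0)

    z_age = (age - age.mean()) / age.std()
    z_bmi = (bmi_base - bmi_base.mean()) / bmi_base.std()

    # --- concomitant exposures -------------------------------------------
    planted, common, straddle = _drug_class_codes(cfg)
    class_codes: list[str] = planted + common + straddle
    prev = np.empty(len(class_codes))
    i = len(planted)
    prev[i : i + len(common)] = rng.uniform(0.06, 0.13, len(common))
    # straddlers: expected purchaser counts drawn around the eligibility
    # cutoff, scale-free in n (0.95 ~ fraction of patients reaching the cohort)
    cutoff = cfg.min_purchasers_target
    prev[i + len(common) :] = rng.uniform(0.7 * cutoff, 1.3 * cutoff, len(straddle)) / (
        0.95 * n
    )
    exposures = np.zeros((n, len(class_codes)), dtype=bool)
    if planted:
        uptake_offset = (
            cfg.confounding_strength * z_age
            + 0.5 * cfg.confounding_strength * z_bmi
            + np.where(male, 0.0, _FEMALE_UPTAKE_PENALTY)
        )
        g0 = _calibrate_intercept(uptake_offset, cfg.planted_prevalence)
        p_uptake = 1.0 / (1.0 + np.exp(-(g0 + uptake_offset)))
        exposures[:, 0] = rng.random(n) < p_uptake
    for j in range(len(planted), len(class_codes)):
        exposures[:, j] = rng.random(n) < prev[j]

    # --- success model ----------------------------------------------------
    offsets = (
        _SUCCESS_B_AGE * z_age
        + _SUCCESS_B_BMI * z_bmi
        + _SUCCESS_B_SMOKING * smoking_lvl
    )
    if planted:
        offsets = offsets + cfg.planted_effect * exposures[:, 0]
    alpha = _calibrate_intercept(offsets, cfg.base_success_rate)
    p_success = 1.0 / (1.0 + np.exp(-(alpha + offsets)))
    success = rng.random(n) < p_success

    # --- patients ---------------------------------------------------------
    smoking_str = np.array(["never", "past", "current"])[smoking_lvl]
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": np.where(male, "male", "female"),
            "birth_offset_days": birth_offset,
            "smoking": smoking_str,
        }
    )

    # --- diagnoses: DM2 for everyone, BPH per the uptake story -------------
    dx_frames = [
        pd.DataFrame(
            {"patient_id": patient_ids, "code": "DM2", "date_days": dx_date}
        )
    ]
    if planted:
        exposed = exposures[:, 0]
        bph = np.zeros(n, dtype=bool)
        bph[exposed] = rng.random(int(exposed.sum())) < 0.95
        candidates = (~exposed) & male & (age > 60.0)
        bph[candidates] = rng.random(int(candidates.sum())) < 0.20
        bph_days = (rng.random(int(bph.sum())) * (dx_date[bph] + 1)).astype(int)
        dx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[bph],
                    "code": "BPH",
                    "date_days": bph_days,
                }
            )
        )
    diagnoses = pd.concat(dx_frames, ignore_index=True)

    # --- purchases ---------------------------------------------------------
    ad_class = rng.choice(
        np.array(ANTIDIABETIC_CLASSES), size=n, p=_ANTIDIABETIC_SHARES
    )
    treat_date = dx_date + rng.integers(0, 61, n)
    rx_frames = [
        pd.DataFrame(
            {
                "patient_id": patient_ids,
                "drug_class": ad_class,
                "component": "",
                "date_days": treat_date,
            }
        )
    ]
    for j, code in enumerate(class_codes):
        idx = np.flatnonzero(exposures[:, j])
        if idx.size == 0:
            continue
        days = (rng.random(idx.size) * (dx_date[idx] + 301)).astype(int)
        if planted and j == 0:
            comp = rng.choice(
                np.array(ALPHA_BLOCKER_COMPONENTS),
                size=idx.size,
                p=np.asarray(cfg.component_mix, dtype=float)
                / sum(cfg.component_mix),
            )
        else:
            comp = np.full(idx.size, "")
        rx_frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids[idx],
                    "drug_class": code,
                    "component": comp,
                    "date_days": days,
                }
            )
        )
    purchases = pd.concat(rx_frames, ignore_index=True)

    # --- labs: weight/BMI history, baseline HbA1c, outcome-window HbA1c ----
    n_meas = np.minimum(1 + rng.poisson(2.0, n), 6)
    midx = np.repeat(np.arange(n), n_meas)
    meas_days = (rng.random(midx.size) * (dx_date[midx] + 1)).astype(int)
    weight_vals = np.round(weight_base[midx] + rng.normal(0.0, 1.5, midx.size), 1)
    bmi_vals = np.round(
        np.clip(bmi_base[midx] + rng.normal(0.0, 0.8, midx.size), 12.0, 60.0), 1
    )
    weight_labs = pd.DataFrame(
        {
            "patient_id": patient_ids[midx],
            "test_code": "WEIGHT",
            "value": weight_vals.clip(35.0, 200.0),
            "date_days": meas_days,
        }
    )
    bmi_labs = pd.DataFrame(
        {
            "patient_id": patient_ids[midx],
            "test_code": "BMI",
            "value": bmi_vals,
            "date_days": meas_days,
        }
    )
    baseline_hba1c = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "test_code": "HGA1C",
            "value": np.round(np.clip(rng.normal(7.8, 0.8, n), 5.6, 14.0), 2),
            "date_days": dx_date,
        }
    )
    window_days = 365 - 90
    k_labs = rng.poisson(cfg.visit_rate * window_days / 365.25, n)
    lidx = np.repeat(np.arange(n), k_labs)
    lab_days = dx_date[lidx] + rng.integers(90, 366, lidx.size)
    centre = np.where(
        success[lidx], _HBA1C_THRESHOLD - _HBA1C_SHIFT, _HBA1C_THRESHOLD + _HBA1C_SHIFT
    )
    lab_vals = np.round(
        np.clip(centre + rng.normal(0.0, cfg.hba1c_noise_sd, lidx.size), 3.5, 15.0), 2
    )
    window_hba1c = pd.DataFrame(
        {
            "patient_id": patient_ids[lidx],
            "test_code": "HGA1C",
            "value": lab_vals,
            "date_days": lab_days,
        }
    )
    labs = pd.concat(
        [weight_labs, bmi_labs, baseline_hba1c, window_hba1c], ignore_index=True
    )
    labs = labs.sort_values(
        ["patient_id", "date_days", "test_code"], kind="mergesort"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "p_success": p_success,
            "success": success.astype(int),
            "exposed_planted": exposures[:, 0].astype(int)
            if planted
            else np.zeros(n, dtype=int),
            "age": age,
            "male": male.astype(int),
            "bmi": bmi_base,
            "smoking": smoking_lvl,
            "n_window_labs": k_labs,
        }
    )
    return EHRTables(
        patients=patients,
        diagnoses=diagnoses,
        purchases=purchases,
        labs=labs,
        truth=truth,
        config=cfg,
    )


_TABLE_SPECS = {
    "patients.csv": ("patients", _PATIENT_COLS),
    "diagnoses.csv": ("diagnoses", _DIAGNOSIS_COLS),
    "purchases.csv": ("purchases", _PURCHASE_COLS),
    "labs.csv": ("labs", _LAB_COLS),
}


def write_tables(tables, directory: str | os.PathLike) -> list:
    """Write the four EHR CSVs (patients, diagnoses, purchases, labs).

    Accepts an :class:`EHRTables` or any iterable of :class:`PatientBundle`.
    Returns the written paths. Output is byte-stable for a given population:
    all floats are already rounded at generation and written with shortest
    repr.
    """
    if not isinstance(tables, EHRTables):
        tables = EHRTables.from_bundles(list(tables))
    os.makedirs(directory, exist_ok=True)
    paths = []
    for fname, (attr, cols) in _TABLE_SPECS.items():
        df = getattr(tables, attr)
        path = os.path.join(directory, fname)
        df.to_csv(path, index=False, columns=cols, lineterminator="\n")
        paths.append(path)
    return paths


def _check_numeric(df: pd.DataFrame, col: str, fname: str, integer: bool) -> pd.Series:
    raw = df[col]
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{fname}: cannot parse column '{col}' at data row {row + 1} "
            f"(value {raw.iloc[row]!r})"
        )
    if num.isna().any():
        row = int(np.flatnonzero(num.isna().to_numpy())[0])
        raise SchemaError(f"{fname}: missing value in column '{col}' at data row {row + 1}")
    if integer:
        frac = num != np.floor(num)
        if frac.any():
            row = int(np.flatnonzero(frac.to_numpy())[0])
            raise SchemaError(
                f"{fname}: non-integer date in column '{col}' at data row {row + 1} "
                f"(value {raw.iloc[row]!r})"
            )
        return num.astype(int)
    return num.astype(float)


def read_tables(directory: str | os.PathLike) -> EHRTables:
    """Read the four EHR CSVs back into an :class:`EHRTables`.

    Validates the schema: a missing required column raises
    :class:`~glyscreen.errors.SchemaError` naming the file and column; an
    unparsable or non-integer date (or non-numeric lab value) raises one
    naming the row. Round-trips :func:`write_tables` exactly.
    """
    frames = {}
    for fname, (attr, cols) in _TABLE_SPECS.items():
        path = os.path.join(directory, fname)
        if not os.path.exists(path):
            raise SchemaError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for col in cols:
            if col not in df.columns:
                raise SchemaError(f"{fname}: missing required column '{col}'")
        df = df[cols].copy()
        for col in cols:
            if col.endswith("_days"):
                df[col] = _check_numeric(df, col, fname, integer=True)
            elif col == "value":
                df[col] = _check_numeric(df, col, fname, integer=False)
        frames[attr] = df
    tables = EHRTables(**frames)
    if (tables.labs["value"] <= 0).any():
        row = int(np.flatnonzero((tables.labs["value"] <= 0).to_numpy())[0])
        raise SchemaError(f"labs.csv: non-positive lab value at data row {row + 1}")
    return tables


def null_config(config: SimConfig) -> SimConfig:
    """The same study conditions with the planted effect switched off."""
    return replace(config, planted_effect=0.0)
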