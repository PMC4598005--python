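"""Synthetic patient encounter histories with a known 30-day readmission hazard.

The generator emulates the statistical structure a readmission risk model is
built on: index inpatient discharges, a 12-month look-back encounter history
per discharge, and a discrete-time readmission hazard driven by chronic-disease
burden, prior inpatient utilization, age and planted continuous risk factors.
A configurable number of high-risk "phenotype" archetypes is planted so the
downstream clustering stage has a recoverable cluster count: archetypes are
laid out on a ring in clinical space (chronic-condition profile, lab /
prescription / radiology utilization, age), which makes the between-archetype
variation essentially two-dimensional and hence visible to a rank-2 PCA.

Each patient contributes exactly one index inpatient discharge.  The
time-to-readmission for patient ``l`` is geometric with a constant per-day
probability ``h_l = logistic(logit(h0) + sum_k beta_k z_kl)``; the latent
``h_l`` is recorded alongside the observed outcome so that recovery tests can
compare fitted risk against the generating truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

AGE_GROUPS = ["0", "1-5", "6-12", "13-18", "19-34", "35-49", "50-65", "65+"]
GENDERS = ["F", "M"]
PAYERS = ["commercial", "medicaid", "medicare", "self_pay"]
ENCOUNTER_TYPES = ["E", "O", "I", "P", "R"]

N_CHRONIC_CONDITIONS = 19
N_LAB_CODES = 24
N_RX_CODES = 40
N_RAD_CODES = 6
N_DX_CODES = 12

CHRONIC_CATALOGUE = [f"cond_{j:02d}" for j in range(1, N_CHRONIC_CONDITIONS + 1)]
LAB_CODES = [f"L{j:02d}" for j in range(1, N_LAB_CODES + 1)]
RX_CODES = [f"R{j:02d}" for j in range(1, N_RX_CODES + 1)]
RAD_CODES = [f"X{j:02d}" for j in range(1, N_RAD_CODES + 1)]
DX_CODES = [f"DX{j:02d}" for j in range(1, N_DX_CODES + 1)]

PATIENT_COLUMNS = [
    "patient_id", "facility_id", "age_group", "gender", "payer",
    "income_band", "education_band", "phenotype",
]
ENCOUNTER_COLUMNS = [
    "patient_id", "encounter_id", "encounter_type", "admit_date",
    "discharge_date", "chronic_flags", "n_labs", "n_meds", "n_radiology",
    "lab_codes", "rx_codes", "rad_codes", "primary_dx", "secondary_dx",
]
INDEX_COLUMNS = [
    "index_id", "patient_id", "discharge_date", "true_time_to_readmission",
    "event_within_30d", "observed_time", "event_observed",
    "true_daily_hazard", "true_prob_30d", "phenotype",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def default_effect_log_hr(n_signal_features: int = 10) -> dict[str, float]:
    """Default log hazard ratios for the generating model.

    ``chronic_count``, ``prior_inpatient_count`` and ``age_group`` act on the
    patient's true counts / age-bin index; ``phenotype`` is the indicator of
    membership in any planted high-risk archetype; ``signal_*`` are standard
    normal continuous covariates with a direct effect.  Noise features carry no
    key and therefore a log-HR of zero.
    """
    eff = {
        "chronic_count": 0.22,
        "prior_inpatient_count": 0.35,
        "age_group": 0.07,
        "phenotype": 2.4,
    }
    for j in range(1, n_signal_features + 1):
        eff[f"signal_{j:02d}"] = 0.28
    return eff


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic cohort.

    The defaults define the desk-scale conditions used throughout the test
    suite: 10,000 index discharges over a 24-month calendar, a 0.10% baseline
    daily readmission hazard, six planted high-risk archetypes covering ~10%
    of patients, and 10 signal + 40 pure-noise continuous features; together
    these give an overall 30-day readmission rate near 19% (background ~11%,
    archetype members ~80%).
    """

    n_patients: int = 10_000
    n_facilities: int = 8
    seed: int = 0
    baseline_daily_hazard: float = 0.0010
    effect_log_hr: Optional[dict[str, float]] = None
    n_signal_features: int = 10
    n_noise_features: int = 40
    n_highrisk_phenotypes: int = 6
    phenotype_fraction: float = 0.10
    horizon_days: int = 30
    start_date: str = "2012-01-01"
    n_months: int = 24
    lookback_months: int = 12
    censoring_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_daily_hazard < 1.0):
            raise ConfigurationError(
                f"baseline_daily_hazard must be in (0, 1), got "
                f"{self.baseline_daily_hazard}")
        for name in ("n_patients", "n_facilities", "n_signal_features",
                     "n_noise_features", "horizon_days", "n_months"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_highrisk_phenotypes < 1:
            raise ConfigurationError("n_highrisk_phenotypes must be >= 1")
        if not (0.0 <= self.phenotype_fraction < 1.0):
            raise ConfigurationError("phenotype_fraction must be in [0, 1)")
        if not (0.0 <= self.censoring_fraction <= 1.0):
            raise ConfigurationError("censoring_fraction must be in [0, 1]")
        if self.n_facilities < 1 and self.n_patients > 0:
            raise ConfigurationError("need at least one facility")

    def resolved_effects(self) -> dict[str, float]:
        if self.effect_log_hr is None:
            return default_effect_log_hr(self.n_signal_features)
        return dict(self.effect_log_hr)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _ring_weights(n_items: int, theta: np.ndarray, kappa: float) -> np.ndarray:
    """Von-Mises-style sampling weights over items laid out on a ring.

    Rows index patients (by their archetype angle ``theta``), columns the
    catalogue items; each row sums to 1.
    """
    phi = 2.0 * np.pi * np.arange(n_items) / n_items
    w = np.exp(kappa * np.cos(phi[None, :] - theta[:, None]))
    return w / w.sum(axis=1, keepdims=True)


def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    encounters = pd.DataFrame(columns=ENCOUNTER_COLUMNS)
    index = pd.DataFrame(columns=INDEX_COLUMNS)
    return patients, encounters, index


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, encounters, index_discharges) tables.

    Index discharges are drawn from month ``lookback_months + 1`` onward so
    every index has a full look-back window.  Patients are alive and not
    transferred at the index discharge by construction.  Post-index encounters
    (the readmission itself, occasional outpatient follow-ups) ARE emitted, so
    look-back aggregation code can be checked for temporal leakage.

    Returns byte-identical tables for identical ``config`` (including seed).
    """
    if not isinstance(config, GeneratorConfig):
        raise ConfigurationError("config must be a GeneratorConfig")
    n = config.n_patients
    if n == 0:
        return _empty_tables()

    rng_pat = np.random.default_rng([config.seed, 101])
    rng_enc = np.random.default_rng([config.seed, 202])
    rng_out = np.random.default_rng([config.seed, 303])

    start = pd.Timestamp(config.start_date)
    end = start + pd.DateOffset(months=config.n_months)
    lookback_days = 365
    first_index_day = lookback_days
    last_index_day = (end - start).days - 1
    if last_index_day < first_index_day:
        raise ConfigurationError(
            "calendar too short: need more months than the look-back window")

    # ------------------------------------------------------------- patients
    patient_id = np.array([f"P{j:06d}" for j in range(1, n + 1)])
    fac_weights = np.arange(1, config.n_facilities + 1, dtype=float)
    fac_weights /= fac_weights.sum()
    facility = rng_pat.choice(config.n_facilities, size=n, p=fac_weights)
    facility_id = np.array([f"F{j + 1:02d}" for j in facility])

    k_phen = config.n_highrisk_phenotypes
    is_member = rng_pat.random(n) < config.phenotype_fraction
    phen = np.where(is_member, rng_pat.integers(0, k_phen, size=n), -1)
    theta = 2.0 * np.pi * np.clip(phen, 0, None) / k_phen  # junk for phen=-1

    age_w = np.array([0.02, 0.03, 0.03, 0.04, 0.18, 0.20, 0.25, 0.25])
    age_idx = rng_pat.choice(8, size=n, p=age_w)
    member_age = np.clip(
        np.round(5.0 + 1.2 * np.sin(theta) + rng_pat.normal(0, 1, n)),
        0, 7).astype(int)
    age_idx = np.where(is_member, member_age, age_idx)

    gender = rng_pat.choice(GENDERS, size=n)
    payer = rng_pat.choice(PAYERS, size=n, p=[0.45, 0.15, 0.3, 0.1])
    income_band = rng_pat.integers(1, 6, size=n)
    education_band = rng_pat.integers(1, 6, size=n)

    # chronic-condition burden and profile
    # archetype members carry a fixed chronic burden and tightly regulated
    # utilization; their clinical signature varies in WHICH conditions and
    # codes (a von-Mises window around the archetype's ring position), not in
    # how much care they consume, which keeps the planted clusters compact.
    lam_chronic = 0.5 + 0.3 * age_idx
    n_chronic = rng_pat.poisson(np.clip(lam_chronic, 0.05, None))
    n_chronic = np.where(is_member, 5, n_chronic)
    n_chronic = np.minimum(n_chronic, N_CHRONIC_CONDITIONS)

    base_cond_w = 1.0 / (np.arange(N_CHRONIC_CONDITIONS) + 2.0)
    base_cond_w /= base_cond_w.sum()
    member_cond_w = _ring_weights(N_CHRONIC_CONDITIONS, theta, kappa=3.0)
    cond_sets: list[np.ndarray] = []
    for i in range(n):
        k = n_chronic[i]
        if k == 0:
            cond_sets.append(np.empty(0, dtype=int))
            continue
        w = member_cond_w[i] if is_member[i] else base_cond_w
        cond_sets.append(np.sort(rng_pat.choice(
            N_CHRONIC_CONDITIONS, size=k, replace=False, p=w)))

    prior_ip = np.where(
        is_member, 2, rng_pat.poisson(0.35 + 0.12 * n_chronic))

    # planted continuous risk factors
    ns, nn = config.n_signal_features, config.n_noise_features
    signal = rng_pat.standard_normal((n, ns)) if ns else np.empty((n, 0))
    noise = rng_pat.standard_normal((n, nn)) if nn else np.empty((n, 0))

    patients = pd.DataFrame({
        "patient_id": patient_id,
        "facility_id": facility_id,
        "age_group": np.array(AGE_GROUPS)[age_idx],
        "gender": gender,
        "payer": payer,
        "income_band": income_band,
        "education_band": education_band,
        "phenotype": phen,
    })
    for j in range(ns):
        patients[f"signal_{j + 1:02d}"] = signal[:, j]
    for j in range(nn):
        patients[f"noise_{j + 1:02d}"] = noise[:, j]

    # ------------------------------------------------------------- outcomes
    eff = config.resolved_effects()
    lp = np.full(n, _logit(config.baseline_daily_hazard))
    lp += eff.get("chronic_count", 0.0) * n_chronic
    lp += eff.get("prior_inpatient_count", 0.0) * prior_ip
    lp += eff.get("age_group", 0.0) * age_idx
    lp += eff.get("phenotype", 0.0) * is_member.astype(float)
    for j in range(ns):
        lp += eff.get(f"signal_{j + 1:02d}", 0.0) * signal[:, j]
    for j in range(nn):
        lp += eff.get(f"noise_{j + 1:02d}", 0.0) * noise[:, j]
    daily_hazard = 1.0 / (1.0 + np.exp(-lp))
    # cap the background so its extreme tail stays out of the high-risk
    # stratum; the planted archetypes remain the only 30-day-risk >= 0.7 group
    daily_hazard = np.where(is_member, daily_hazard,
                            np.minimum(daily_hazard, 0.03))

    index_day = rng_out.integers(first_index_day, last_index_day + 1, size=n)
    index_date = start + pd.to_timedelta(index_day, unit="D")
    t_true = rng_out.geometric(daily_hazard)  # support {1, 2, ...}
    event_30 = t_true <= 30
    observed = np.minimum(t_true, config.horizon_days)
    event_obs = t_true <= config.horizon_days
    if config.censoring_fraction > 0.0:
        censored = rng_out.random(n) < config.censoring_fraction
        c_time = rng_out.integers(1, config.horizon_days + 1, size=n)
        cut = np.where(censored, c_time, config.horizon_days)
        event_obs = event_obs & (t_true <= cut)
        observed = np.minimum(observed, cut)
    prob30 = 1.0 - (1.0 - daily_hazard) ** 30

    # ----------------------------------------------------------- encounters
    member = is_member.astype(float)
    memb_i = is_member.astype(int)
    lam_E = (0.7 + 0.12 * n_chronic) * (1.0 - member)
    lam_O = (2.5 + 0.40 * n_chronic) * (1.0 - member)
    lam_P = np.full(n, 0.25)
    lam_R = 0.15 * (1.0 - member)
    cnt = {
        "E": rng_enc.poisson(np.clip(lam_E, 0.0, None)) + memb_i * 4,
        "O": rng_enc.poisson(np.clip(lam_O, 0.0, None)) + memb_i * 9,
        "I": prior_ip,
        "P": rng_enc.poisson(lam_P),
        "R": rng_enc.poisson(np.clip(lam_R, 0.0, None)) + memb_i,
    }

    lab_mult = 1.0 + member * 2.0
    rx_mult = 1.0 + member * 2.0
    rad_mult = 1.0 + member * 1.2
    lab_w_member = _ring_weights(N_LAB_CODES, theta, kappa=3.0)
    rx_w_member = _ring_weights(N_RX_CODES, theta, kappa=3.0)
    rad_w_member = _ring_weights(N_RAD_CODES, theta, kappa=2.0)
    lab_w_base = np.full(N_LAB_CODES, 1.0 / N_LAB_CODES)
    rx_w_base = np.full(N_RX_CODES, 1.0 / N_RX_CODES)
    rad_w_base = np.full(N_RAD_CODES, 1.0 / N_RAD_CODES)

    lab_rate = {"E": 4.0, "O": 1.5, "I": 8.0, "P": 2.0, "R": 1.0}
    rx_rate = {"E": 1.0, "O": 2.0, "I": 3.0, "P": 0.3, "R": 1.5}
    rad_rate = {"E": 0.8, "O": 0.3, "I": 1.5, "P": 0.5, "R": 0.2}

    rows: dict[str, list] = {c: [] for c in ENCOUNTER_COLUMNS}
    index_rows: list[int] = []

    def _codes(rng, pool, weights, lam, fixed=False) -> tuple[int, str]:
        k = int(round(lam)) if fixed else int(rng.poisson(lam))
        if k == 0:
            return 0, ""
        picks = rng.choice(len(pool), size=k, p=weights)
        return k, ";".join(pool[j] for j in picks)

    def _flags(rng, conds: np.ndarray) -> str:
        if conds.size == 0:
            return ""
        keep = conds[rng.random(conds.size) < 0.6]
        return ";".join(CHRONIC_CATALOGUE[j] for j in keep)

    def _emit(i: int, etype: str, admit_day: int, los: int) -> None:
        lw = lab_w_member[i] if is_member[i] else lab_w_base
        rw = rx_w_member[i] if is_member[i] else rx_w_base
        xw = rad_w_member[i] if is_member[i] else rad_w_base
        fx = bool(is_member[i])  # members: fixed counts, random composition
        n_lab, lab_s = _codes(rng_enc, LAB_CODES, lw,
                              lab_rate[etype] * lab_mult[i], fixed=fx)
        n_rx, rx_s = _codes(rng_enc, RX_CODES, rw,
                            rx_rate[etype] * rx_mult[i], fixed=fx)
        n_rad, rad_s = _codes(rng_enc, RAD_CODES, xw,
                              rad_rate[etype] * rad_mult[i], fixed=fx)
        dx = rng_enc.integers(0, N_DX_CODES, size=2)
        rows["patient_id"].append(patient_id[i])
        rows["encounter_id"].append(None)  # filled after sorting
        rows["encounter_type"].append(etype)
        rows["admit_date"].append(admit_day)
        rows["discharge_date"].append(admit_day + los)
        rows["chronic_flags"].append(_flags(rng_enc, cond_sets[i]))
        rows["n_labs"].append(n_lab)
        rows["n_meds"].append(n_rx)
        rows["n_radiology"].append(n_rad)
        rows["lab_codes"].append(lab_s)
        rows["rx_codes"].append(rx_s)
        rows["rad_codes"].append(rad_s)
        rows["primary_dx"].append(DX_CODES[dx[0]])
        rows["secondary_dx"].append(DX_CODES[dx[1]])

    horizon_end_day = last_index_day + 1
    for i in range(n):
        idx_day = int(index_day[i])
        lo = idx_day - lookback_days + 1
        # look-back history (discharge dates within (index-365, index])
        for etype in ENCOUNTER_TYPES:
            k = int(cnt[etype][i])
            for _ in range(k):
                if etype == "I":
                    los = 4 if is_member[i] else 1 + int(rng_enc.poisson(2.0))
                else:
                    los = 0
                dis = int(rng_enc.integers(lo, idx_day))  # strictly pre-index
                _emit(i, etype, dis - los, los)
        # the index inpatient stay itself
        idx_los = 1 + int(rng_enc.poisson(2.0 + 1.0 * member[i]))
        _emit(i, "I", idx_day - idx_los, idx_los)
        idx_row = len(rows["patient_id"]) - 1
        # post-index encounters: the readmission, occasional follow-ups
        t = int(t_true[i])
        if idx_day + t <= horizon_end_day:
            re_los = 1 + int(rng_enc.poisson(2.0))
            _emit(i, "I", idx_day + t, re_los)
        if rng_enc.random() < 0.3:
            fu = idx_day + 5 + int(rng_enc.integers(0, 55))
            if fu <= horizon_end_day:
                _emit(i, "O", fu, 0)
        index_rows.append(idx_row)

    index_enc_row = np.array(index_rows)
    encounters = pd.DataFrame({c: rows[c] for c in ENCOUNTER_COLUMNS})
    encounters["encounter_id"] = [
        f"ENC{j:07d}" for j in range(1, len(encounters) + 1)]
    encounters["admit_date"] = start + pd.to_timedelta(
        encounters["admit_date"], unit="D")
    encounters["discharge_date"] = start + pd.to_timedelta(
        encounters["discharge_date"], unit="D")

    index = pd.DataFrame({
        "index_id": encounters["encounter_id"].to_numpy()[index_enc_row],
        "patient_id": patient_id,
        "discharge_date": index_date,
        "true_time_to_readmission": t_true.astype(int),
        "event_within_30d": event_30,
        "observed_time": observed.astype(int),
        "event_observed": event_obs,
        "true_daily_hazard": daily_hazard,
        "true_prob_30d": prob30,
        "phenotype": phen,
    })
    return patients, encounters, index


# --------------------------------------------------------------------- I/O

class CohortParseError(ValueError):
    """A cohort CSV violates a table invariant; names the row and column."""


_DATE_COLS = {"encounters": ["admit_date", "discharge_date"],
              "index_discharges": ["discharge_date"]}
_BOOL_COLS = {"index_discharges": ["event_within_30d", "event_observed"]}


def write_cohort(tables, path) -> dict[str, str]:
    """Write (patients, encounters, index) to patients.csv / encounters.csv /
    index_discharges.csv under ``path`` with ISO-8601 dates.  Returns the file
    map."""
    import os
    patients, encounters, index = tables
    os.makedirs(path, exist_ok=True)
    out = {}
    for name, df in [("patients", patients), ("encounters", encounters),
                     ("index_discharges", index)]:
        f = os.path.join(path, f"{name}.csv")
        df.to_csv(f, index=False, date_format="%Y-%m-%d")
        out[name] = f
    return out


def read_cohort(path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read cohort tables written by :func:`write_cohort`, validating row
    invariants (date ordering, non-negative counts)."""
    import os
    dfs = {}
    for name in ("patients", "encounters", "index_discharges"):
        f = os.path.join(path, f"{name}.csv")
        df = pd.read_csv(f, keep_default_na=False, na_values=[])
        for col in _DATE_COLS.get(name, []):
            try:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
            except ValueError as exc:
                raise CohortParseError(
                    f"{name}.csv: column {col!r}: {exc}") from exc
        for col in _BOOL_COLS.get(name, []):
            if len(df) and df[col].dtype == object:
                bad = ~df[col].isin(["True", "False"])
                if bad.any():
                    row = int(np.argmax(bad.to_numpy()))
                    raise CohortParseError(
                        f"{name}.csv row {row}, column {col!r}: "
                        f"not a boolean: {df[col].iloc[row]!r}")
                df[col] = df[col] == "True"
            else:
                df[col] = df[col].astype(bool)
        dfs[name] = df
    enc = dfs["encounters"]
    if len(enc):
        bad = enc["discharge_date"] < enc["admit_date"]
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise CohortParseError(
                f"encounters.csv row {row}, column 'discharge_date': "
                "discharge_date earlier than admit_date")
        for col in ("n_labs", "n_meds", "n_radiology"):
            neg = enc[col] < 0
            if neg.any():
                row = int(np.argmax(neg.to_numpy()))
                raise CohortParseError(
                    f"encounters.csv row {row}, column {col!r}: negative count")
        bad_type = ~enc["encounter_type"].isin(ENCOUNTER_TYPES)
        if bad_type.any():
            row = int(np.argmax(bad_type.to_numpy()))
            raise CohortParseError(
                f"encounters.csv row {row}, column 'encounter_type': "
                f"unknown type {enc['encounter_type'].iloc[row]!r}")
    idx = dfs["index_discharges"]
    if len(idx):
        bad = idx["observed_time"] < 0
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise CohortParseError(
                f"index_discharges.csv row {row}, column 'observed_time': "
                "negative time")
    return dfs["patients"], dfs["encounters"], dfs["index_discharges"]
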