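"""Look-back feature aggregation, feature filtering, sub-cohorts and splits.

Features for an index discharge are computed strictly from encounters whose
discharge date falls in the half-open look-back window
``(index_date - lookback_days, index_date]``, excluding the index stay itself;
nothing post-index is ever read.  The cohort is partitioned into four
sub-cohorts by (any chronic-disease diagnosis in look-back) x (any prior
inpatient admission in look-back), and into facility-disjoint
train/calibration vs blind-test subgroups plus a temporally later prospective
phase.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_ehr import (
    AGE_GROUPS,
    CHRONIC_CATALOGUE,
    LAB_CODES,
    PAYERS,
    RAD_CODES,
    RX_CODES,
)

SUBCOHORT_LABELS = ["CD+IP", "CD-only", "IP-only", "neither"]
SPLIT_LABELS = ["train", "calibration", "blind_test", "prospective"]


@dataclass
class CohortSplit:
    """Assignment of index discharges to pipeline roles.

    ``assignment`` maps index_id -> one of train / calibration / blind_test /
    prospective; ``facility_partition`` maps facility_id -> subgroup 1
    (train + calibration) or 2 (blind test).  The split is a function of
    facility membership and calendar period only.
    """

    assignment: pd.Series
    facility_partition: dict = field(default_factory=dict)

    def ids(self, role: str) -> pd.Index:
        return self.assignment.index[self.assignment == role]


def _count_codes(s: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Total and distinct code counts from ';'-joined code strings."""
    split = s.str.split(";")
    total = split.map(lambda v: 0 if v == [""] or v is np.nan else len(v))
    distinct = split.map(
        lambda v: 0 if v == [""] or v is np.nan else len(set(v)))
    return total, distinct


def aggregate_features(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    index: pd.DataFrame,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """One numeric feature row per index discharge from its look-back window.

    Emitted feature groups mirror a hospital-encounter feature dictionary:
    per-type visit counts (E/O/I/P/R), accumulated inpatient length of stay,
    chronic-disease count and per-condition indicators, total and
    non-redundant (distinct-code) lab / prescription / radiology counts,
    per-code utilization counts, distinct primary/secondary diagnosis counts,
    demographics, payer one-hots, and the generator's planted continuous
    covariates when present.
    """
    if len(index) == 0:
        return pd.DataFrame()
    missing = set(index["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise ValueError(
            f"index discharges reference unknown patients: {sorted(missing)[:5]}")

    idx = index[["index_id", "patient_id", "discharge_date"]].rename(
        columns={"discharge_date": "index_date"})
    enc = encounters.merge(idx, on="patient_id", how="inner")
    window = (
        (enc["discharge_date"] > enc["index_date"]
         - pd.to_timedelta(lookback_days, unit="D"))
        & (enc["discharge_date"] <= enc["index_date"])
        & (enc["encounter_id"] != enc["index_id"])  # the index stay itself
    )
    enc = enc.loc[window].copy()

    row_index = pd.Index(index["index_id"], name="index_id")
    cols: dict[str, pd.Series] = {}

    def as_count(series) -> pd.Series:
        s = pd.Series(series, dtype=float).reindex(row_index).fillna(0.0)
        return s.astype(int)

    # visit counts per encounter type
    type_counts = (enc.groupby(["index_id", "encounter_type"]).size()
                   .unstack(fill_value=0))
    for t in "EOIPR":
        col = type_counts[t] if t in type_counts else pd.Series(dtype=float)
        cols[f"count_{t}"] = as_count(col)

    # accumulated inpatient length of stay
    ip = enc[enc["encounter_type"] == "I"]
    los = ((ip["discharge_date"] - ip["admit_date"]).dt.days
           .groupby(ip["index_id"].values).sum())
    cols["total_los"] = as_count(los)

    # chronic-disease burden: distinct conditions flagged in look-back
    flagged = enc.loc[enc["chronic_flags"] != "",
                      ["index_id", "chronic_flags"]].copy()
    if len(flagged):
        flagged["chronic_flags"] = flagged["chronic_flags"].str.split(";")
        exploded = flagged.explode("chronic_flags")
        seen = exploded.groupby("index_id")["chronic_flags"].agg(set)
    else:
        seen = pd.Series(dtype=object)
    seen = seen.reindex(row_index)
    cols["chronic_count"] = seen.map(
        lambda v: len(v) if isinstance(v, set) else 0).astype(int)
    for cond in CHRONIC_CATALOGUE:
        cols[f"chronic_{cond}"] = seen.map(
            lambda v, c=cond: int(isinstance(v, set) and c in v)).astype(int)

    # lab / prescription / radiology utilization
    for prefix, col, pool in [("labs", "lab_codes", LAB_CODES),
                              ("meds", "rx_codes", RX_CODES),
                              ("rad", "rad_codes", RAD_CODES)]:
        total, distinct = _count_codes(enc[col].fillna(""))
        cols[f"{prefix}_total"] = as_count(
            total.groupby(enc["index_id"].values).sum())
        nonred = enc.loc[enc[col].fillna("") != "", ["index_id", col]].copy()
        if len(nonred):
            nonred[col] = nonred[col].str.split(";")
            expl = nonred.explode(col)
            cols[f"{prefix}_distinct"] = as_count(
                expl.groupby("index_id")[col].nunique())
            per_code = (expl.groupby(["index_id", col]).size()
                        .unstack(fill_value=0))
        else:
            cols[f"{prefix}_distinct"] = as_count(pd.Series(dtype=float))
            per_code = pd.DataFrame(index=row_index)
        for code in pool:
            cols[f"{prefix}_{code}"] = as_count(
                per_code[code] if code in per_code else pd.Series(dtype=float))

    # diagnosis variety
    for dx_col in ("primary_dx", "secondary_dx"):
        grp = enc.groupby("index_id")[dx_col]
        cols[f"{dx_col}_distinct"] = as_count(grp.nunique())
        cols[f"{dx_col}_total"] = as_count(grp.size())

    # demographics and planted covariates (time-invariant patient attributes)
    pat = patients.set_index("patient_id").loc[index["patient_id"]]
    pat.index = row_index
    cols["age_group_idx"] = pat["age_group"].map(
        {g: i for i, g in enumerate(AGE_GROUPS)}).astype(int)
    cols["is_female"] = (pat["gender"] == "F").astype(int)
    cols["income_band"] = pat["income_band"].astype(int)
    cols["education_band"] = pat["education_band"].astype(int)
    for p in PAYERS:
        cols[f"payer_{p}"] = (pat["payer"] == p).astype(int)
    planted = [c for c in patients.columns
               if c.startswith(("signal_", "noise_"))]
    for c in planted:
        cols[c] = pat[c].astype(float)
    return pd.DataFrame(cols, index=row_index)


def variance_filter(features: pd.DataFrame, n_keep: int) -> list[str]:
    """Rank features by variance after min-max scaling; keep the top n_keep.

    Constant (zero-variance) features are always removed first.  Ties in
    scaled variance are broken by feature name, so the returned ranking is
    deterministic.  Returns feature names in rank order.
    """
    if n_keep <= 0:
        raise ValueError(f"n_keep must be positive, got {n_keep}")
    if n_keep > features.shape[1]:
        raise ValueError(
            f"n_keep={n_keep} exceeds available features ({features.shape[1]})")
    x = features.to_numpy(dtype=float)
    lo, hi = x.min(axis=0), x.max(axis=0)
    nonconst = hi > lo
    scaled = np.zeros_like(x)
    scaled[:, nonconst] = ((x - lo) / np.where(nonconst, hi - lo, 1.0))[:, nonconst]
    var = scaled.var(axis=0, ddof=1)
    names = np.asarray(features.columns)
    order = sorted(
        (i for i in range(len(names)) if nonconst[i]),
        key=lambda i: (-var[i], names[i]))
    kept = [str(names[i]) for i in order[:n_keep]]
    return kept


def assign_subcohort(features: pd.DataFrame) -> pd.Series:
    """Four-way partition by chronic-disease and prior-inpatient history.

    CD+IP / CD-only / IP-only / neither from (chronic_count >= 1) x
    (count_I >= 1) over the look-back window.
    """
    for col in ("chronic_count", "count_I"):
        if col not in features:
            raise ValueError(f"required feature {col!r} missing")
    cd = features["chronic_count"] >= 1
    ip = features["count_I"] >= 1
    label = np.select(
        [cd & ip, cd & ~ip, ~cd & ip],
        ["CD+IP", "CD-only", "IP-only"],
        default="neither")
    return pd.Series(label, index=features.index, name="subcohort")


def _monthly_tables(index: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = index.copy()
    df["month"] = df["discharge_date"].dt.to_period("M")
    vol = (df.groupby(["facility_id", "month"]).size()
           .unstack(fill_value=0))
    ev = (df.groupby(["facility_id", "month"])["event_within_30d"].sum()
          .unstack(fill_value=0).reindex(vol.index).fillna(0))
    return vol, ev


def _split_objective(vol: pd.DataFrame, ev: pd.DataFrame,
                     side1: list, side2: list) -> tuple[float, float]:
    v1, v2 = vol.loc[side1].sum(axis=0), vol.loc[side2].sum(axis=0)
    e1, e2 = ev.loc[side1].sum(axis=0), ev.loc[side2].sum(axis=0)
    vol_diff = float((v1 - v2).abs().max())
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(v1 > 0, e1 / v1, np.nan)
        r2 = np.where(v2 > 0, e2 / v2, np.nan)
    both = ~(np.isnan(r1) | np.isnan(r2))
    rate_diff = float(np.abs(r1[both] - r2[both]).max()) if both.any() else 0.0
    return vol_diff, rate_diff


def facility_balanced_split(
    index: pd.DataFrame,
    seed: int = 0,
    train_fraction: float = 0.7,
    prospective_start=None,
    max_exhaustive: int = 12,
) -> CohortSplit:
    """Facility-disjoint retrospective split plus temporal prospective phase.

    Whole facilities are assigned to two subgroups minimizing, lexicographically,
    the maximum monthly absolute inpatient-volume difference and then the
    maximum monthly readmission-rate difference (exhaustive search up to
    ``max_exhaustive`` facilities, greedy beyond).  Subgroup-1 rows are further
    split into train and calibration by a patient-level random draw under
    ``seed``; subgroup-2 rows become the blind test set.  Rows discharged on or
    after ``prospective_start`` form the prospective phase regardless of
    facility.

    ``index`` must carry index_id, patient_id, facility_id, discharge_date and
    event_within_30d columns.
    """
    need = {"index_id", "patient_id", "facility_id", "discharge_date",
            "event_within_30d"}
    missing = need - set(index.columns)
    if missing:
        raise ValueError(f"index table missing columns: {sorted(missing)}")

    df = index.copy()
    if prospective_start is not None:
        prospective_start = pd.Timestamp(prospective_start)
        prosp_mask = df["discharge_date"] >= prospective_start
    else:
        prosp_mask = pd.Series(False, index=df.index)
    retro = df.loc[~prosp_mask]

    facilities = sorted(retro["facility_id"].unique())
    if len(facilities) < 2:
        raise ValueError(
            "need >= 2 facilities with retrospective rows to form two "
            "facility-disjoint subgroups")

    vol, ev = _monthly_tables(retro)
    if len(facilities) <= max_exhaustive:
        best = None
        for bits in itertools.product([0, 1], repeat=len(facilities) - 1):
            # facility 0 pinned to side 1: halves the search, kills mirror ties
            side = (1,) + bits
            s1 = [f for f, b in zip(facilities, side) if b == 1]
            s2 = [f for f, b in zip(facilities, side) if b == 0]
            if not s2:
                continue
            obj = _split_objective(vol, ev, s1, s2)
            if best is None or obj < best[0]:
                best = (obj, s1, s2)
        _, side1, side2 = best
    else:
        totals = vol.sum(axis=1).sort_values(ascending=False)
        side1, side2 = [], []
        for f in totals.index:
            cands = []
            for s1, s2 in ((side1 + [f], side2), (side1, side2 + [f])):
                if s1 and s2:
                    cands.append((_split_objective(vol, ev, s1, s2), s1, s2))
                else:
                    cands.append(((np.inf, np.inf), s1, s2))
            if not side1:
                side1 = side1 + [f]
            elif not side2:
                side2 = side2 + [f]
            else:
                (obj_a, s1a, s2a), (obj_b, s1b, s2b) = cands
                if obj_a <= obj_b:
                    side1, side2 = s1a, s2a
                else:
                    side1, side2 = s1b, s2b

    partition = {f: 1 for f in side1}
    partition.update({f: 2 for f in side2})
    # prospective-only facilities (no retrospective rows) stay unpartitioned
    assignment = pd.Series("prospective", index=df["index_id"].to_numpy(),
                           name="split", dtype=object)

    retro_rows = retro.set_index("index_id")
    sub1 = retro_rows[retro_rows["facility_id"].isin(side1)]
    sub2_ids = retro_rows.index[retro_rows["facility_id"].isin(side2)]
    assignment.loc[sub2_ids] = "blind_test"

    rng = np.random.default_rng([seed, 404])
    pats = np.sort(sub1["patient_id"].unique())
    rng.shuffle(pats)
    n_train = int(round(train_fraction * len(pats)))
    train_pats = set(pats[:n_train])
    is_train = sub1["patient_id"].isin(train_pats)
    assignment.loc[sub1.index[is_train]] = "train"
    assignment.loc[sub1.index[~is_train]] = "calibration"
    assignment.index.name = "index_id"
    return CohortSplit(assignment=assignment, facility_partition=partition)
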