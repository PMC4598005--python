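"""PPV-based 0-100 risk score calibration and tier assignment.

Each sub-cohort model produces ensemble cumulative-hazard estimates on its own
scale; to unify them, the calibration set's hazards are ranked and each
observed hazard value h gets the positive predictive value of the threshold
rule "H >= h" (the readmission fraction among calibration samples at or above
h).  The risk score is 100 x that PPV, regularized to be monotone
non-decreasing in h, so a score of 70 reads as "patients this high or higher
readmitted 70% of the time on the calibration set".

Tiers partition the score: Low < 30 <= Intermediate < 70 <= High.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TIER_LOW, TIER_INTERMEDIATE, TIER_HIGH = "Low", "Intermediate", "High"


@dataclass
class CalibrationMap:
    """Monotone step mapping from ensemble hazard to 0-100 risk score.

    ``knots`` are the distinct calibration-set hazard values (ascending);
    ``ppv`` the regularized PPV at each knot.  Scoring uses the left-step
    convention (value of the largest knot not exceeding h) and clamps outside
    the knot range.
    """

    subcohort: str
    knots: np.ndarray
    ppv: np.ndarray

    def score(self, h):
        h = np.asarray(h, dtype=float)
        idx = np.clip(np.searchsorted(self.knots, h, side="right") - 1,
                      0, len(self.knots) - 1)
        out = 100.0 * self.ppv[idx]
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"subcohort": self.subcohort,
                "knots": self.knots.tolist(),
                "ppv": self.ppv.tolist()}

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibrationMap":
        return cls(subcohort=doc["subcohort"],
                   knots=np.asarray(doc["knots"], dtype=float),
                   ppv=np.asarray(doc["ppv"], dtype=float))


def fit_calibration(h, labels, subcohort: str = "all") -> CalibrationMap:
    """Fit the PPV step map on a calibration set of (hazard, 30-day label).

    The raw curve PPV(h) = #{label = 1 and H >= h} / #{H >= h} is computed at
    every distinct observed hazard ("higher than" read inclusively so the
    largest hazard keeps a defined PPV).  Finite-sample PPV curves are not
    monotone, so a one-sided isotonic regularization is applied: the score at
    h is the running maximum of the raw PPV over knots <= h, which is the
    smallest monotone non-decreasing majorant pinned to the full-set PPV
    (the prevalence) at the lowest knot.
    """
    h = np.asarray(h, dtype=float)
    y = np.asarray(labels, dtype=float)
    if h.size == 0:
        raise ValueError("empty calibration set")
    if h.shape != y.shape:
        raise ValueError("h and labels must have equal length")
    if y.min() == y.max():
        warnings.warn(
            f"calibration labels for sub-cohort {subcohort!r} are all "
            f"{int(y[0])}; the score map is degenerate", stacklevel=2)
    order = np.argsort(h, kind="stable")
    hs, ys = h[order], y[order]
    # suffix counts: for each position, events and samples at-or-above
    suffix_pos = np.cumsum(ys[::-1])[::-1]
    n = len(hs)
    knots, first = np.unique(hs, return_index=True)
    raw = suffix_pos[first] / (n - first)
    reg = np.maximum.accumulate(raw)
    return CalibrationMap(subcohort=subcohort, knots=knots, ppv=reg)


def assign_tier(score, low: float = 30.0, high: float = 70.0) -> str:
    """Risk tier for a 0-100 score: Low < low <= Intermediate < high <= High."""
    s = float(score)
    if not (0.0 <= s <= 100.0):
        raise ValueError(f"score must be in [0, 100], got {s}")
    if s < low:
        return TIER_LOW
    if s >= high:
        return TIER_HIGH
    return TIER_INTERMEDIATE


def assign_tiers(scores, low: float = 30.0, high: float = 70.0) -> np.ndarray:
    """Vectorized :func:`assign_tier`."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 100)):
        bad = s[(s < 0) | (s > 100)][0]
        raise ValueError(f"score must be in [0, 100], got {bad}")
    return np.select([s < low, s >= high], [TIER_LOW, TIER_HIGH],
                     default=TIER_INTERMEDIATE)


def unified_scores(results_by_subcohort: dict,
                   maps_by_subcohort: dict,
                   features: pd.DataFrame,
                   subcohorts: pd.Series,
                   low: float = 30.0, high: float = 70.0) -> pd.DataFrame:
    """Score a cohort on the unified 0-100 scale.

    Each sample is scored by its own sub-cohort's fitted forest and
    calibration map; the resulting table (index_id, subcohort, H30, score,
    tier) is comparable across sub-cohorts because the score is a PPV, not a
    hazard.
    """
    rows = []
    for label in pd.unique(subcohorts):
        if label not in results_by_subcohort or label not in maps_by_subcohort:
            raise ValueError(
                f"no fitted model/calibration for sub-cohort {label!r}")
        mask = subcohorts == label
        sub = features.loc[mask]
        res = results_by_subcohort[label]
        h30 = res.predict_risk(sub)
        score = maps_by_subcohort[label].score(h30)
        rows.append(pd.DataFrame({
            "index_id": sub.index,
            "subcohort": label,
            "H30": h30,
            "score": score,
            "tier": assign_tiers(score, low=low, high=high),
        }))
    out = pd.concat(rows, ignore_index=True).set_index("index_id")
    order = features.index[features.index.isin(out.index)]
    out = out.loc[order]
    out.index.name = "index_id"
    return out.reset_index()
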