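"""Evaluation surfaces: risk-bin readmission rates, readmission-free curves,
and the binary c-statistic.

The c-statistic here is the probability that a randomly chosen readmitted
patient outranks a randomly chosen non-readmitted one on the risk score
(Mann-Whitney form, ties counted half) -- the binary 30-day AUC, not a
time-dependent concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import rankdata

BIN_EDGES = np.arange(0.0, 101.0, 10.0)  # [0,10), ..., [90,100]


@dataclass
class BinSummary:
    """One 10-point risk bin: occupancy and observed 30-day readmission rate.

    ``rate`` is None for an empty bin -- an absent rate, never a fabricated
    zero.
    """

    bin: str
    lo: float
    hi: float
    n: int
    readmission_rate: Optional[float]


@dataclass
class ReadmissionFreeCurve:
    """Kaplan-Meier readmission-free probability at integer days 0..30."""

    tier: Optional[str]
    days: np.ndarray
    survival: np.ndarray


@dataclass
class ConcordanceResult:
    auc: float
    n_pos: int
    n_neg: int


def bin_rates(scores, labels) -> tuple[list[BinSummary], dict]:
    """Readmission rate per 10-point score bin plus tier-level aggregates.

    The top bin is closed ([90, 100]) so a score of exactly 100 is counted.
    Tier aggregates use the standard 30/70 cuts.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    bins = []
    for i in range(10):
        lo, hi = BIN_EDGES[i], BIN_EDGES[i + 1]
        mask = (s >= lo) & ((s < hi) if i < 9 else (s <= hi))
        n = int(mask.sum())
        rate = float(y[mask].mean()) if n else None
        label = f"[{lo:.0f},{hi:.0f}" + (")" if i < 9 else "]")
        bins.append(BinSummary(bin=label, lo=lo, hi=hi, n=n,
                               readmission_rate=rate))
    tiers = {}
    for name, mask in [("Low", s < 30), ("Intermediate", (s >= 30) & (s < 70)),
                       ("High", s >= 70)]:
        n = int(mask.sum())
        tiers[name] = {"n": n,
                       "rate": float(y[mask].mean()) if n else None}
    return bins, tiers


def km_curve(times, events, tier: Optional[str] = None,
             horizon: int = 30) -> ReadmissionFreeCurve:
    """Product-limit readmission-free curve evaluated at days 0..horizon."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    days = np.arange(horizon + 1)
    if t.size == 0:
        return ReadmissionFreeCurve(tier=tier, days=days,
                                    survival=np.ones(horizon + 1))
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_at_times(days).to_numpy()
    return ReadmissionFreeCurve(tier=tier, days=days, survival=surv)


def c_statistic(scores, labels) -> ConcordanceResult:
    """Binary AUC in the Mann-Whitney formulation.

    P(score_pos > score_neg) + 0.5 P(tie) over all positive-negative pairs,
    computed from midranks.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("c-statistic needs both classes present")
    ranks = rankdata(s)  # midranks handle ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return ConcordanceResult(auc=float(auc), n_pos=n_pos, n_neg=n_neg)


def median_time_to_event(curve: ReadmissionFreeCurve) -> Optional[int]:
    """Median day of readmission among patients readmitted by day 30.

    First day d at which the conditional CDF
    (1 - S(d)) / (1 - S(30)) reaches one half; None when no events occur.
    """
    S = np.asarray(curve.survival, dtype=float)
    total = 1.0 - S[-1]
    if total <= 0.0:
        return None
    cond = (1.0 - S) / total
    day = int(np.argmax(cond >= 0.5))
    return day
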