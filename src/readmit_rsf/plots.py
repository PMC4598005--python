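"""Optional matplotlib views of the evaluation surfaces."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .evaluation import BinSummary, ReadmissionFreeCurve


def plot_bin_rates(bins: list[BinSummary], ax=None, **bar_kw):
    """Bar chart of 30-day readmission rate per 10-point risk bin."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    mids = [b.lo + 5 for b in bins if b.readmission_rate is not None]
    rates = [b.readmission_rate for b in bins if b.readmission_rate is not None]
    ax.bar(mids, rates, width=8, **bar_kw)
    ax.set_xlabel("risk score bin")
    ax.set_ylabel("30-day readmission rate")
    ax.set_xlim(0, 100)
    return ax


def plot_readmission_free_curves(curves: list[ReadmissionFreeCurve], ax=None):
    """Kaplan-Meier readmission-free curves, one line per risk tier."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        ax.step(curve.days, curve.survival, where="post",
                label=curve.tier or "all")
    ax.set_xlabel("days since discharge")
    ax.set_ylabel("readmission-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
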