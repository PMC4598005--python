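"""Compiled inner loops for survival-tree growth and prediction.

The log-rank split search maintains the daughter-node risk-set counts
incrementally while sweeping samples in feature order, so evaluating every
cut point of one feature costs O(n * m) for m distinct event times in the
node.  Terms of the variance sum with a single subject at risk (Y_i == 1)
contribute zero, and candidate cuts are midpoints between consecutive
distinct feature values; ties in |F| keep the earliest candidate (features
are visited in name order, cuts in ascending order).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def best_split_kernel(Xn, events, cand, d, Y, ub, ei, min_daughter):
    """Best log-rank split over candidate feature columns of one node.

    Parameters
    ----------
    Xn : (n, p) float64 node feature matrix
    events : (n,) int64 event indicators
    cand : (k,) int64 candidate column indices, pre-sorted by feature name
    d, Y : (m,) int64 events / at-risk counts at the node's distinct event times
    ub : (n,) int64, per sample the number of distinct event times <= its time
    ei : (n,) int64, event-time index per sample (junk where events == 0)
    min_daughter : smallest admissible daughter size

    Returns (column, cut, F, |F|); column is -1 when no valid split exists.
    """
    n = Xn.shape[0]
    m = d.shape[0]
    best_j = -1
    best_cut = 0.0
    best_F = 0.0
    best_absF = -1.0
    Y1 = np.zeros(m, dtype=np.int64)
    d1 = np.zeros(m, dtype=np.int64)
    for jj in range(cand.shape[0]):
        j = cand[jj]
        col = Xn[:, j]
        order = np.argsort(col)
        for i in range(m):
            Y1[i] = 0
            d1[i] = 0
        for k in range(n - 1):
            s = order[k]
            for i in range(ub[s]):
                Y1[i] += 1
            if events[s] == 1:
                d1[ei[s]] += 1
            left_n = k + 1
            if left_n < min_daughter or n - left_n < min_daughter:
                continue
            xk = col[order[k]]
            xk1 = col[order[k + 1]]
            if xk1 > xk:
                num = 0.0
                den = 0.0
                for i in range(m):
                    num += d1[i] - Y1[i] * d[i] / Y[i]
                    if Y[i] > 1:
                        p1 = Y1[i] / Y[i]
                        den += (p1 * (1.0 - p1)
                                * ((Y[i] - d[i]) / (Y[i] - 1.0)) * d[i])
                if den > 0.0:
                    F = num / np.sqrt(den)
                    aF = abs(F)
                    if aF > best_absF:
                        best_absF = aF
                        best_j = j
                        best_cut = 0.5 * (xk + xk1)
                        best_F = F
    return best_j, best_cut, best_F, best_absF


@njit(cache=True)
def node_risk_sets(times, events):
    """Distinct event times and per-time (d_i, Y_i, ub, ei) for one node.

    ``times`` need not be sorted.  Returns (ts, d, Y, ub, ei).
    """
    n = times.shape[0]
    ts = np.unique(times[events == 1])
    m = ts.shape[0]
    d = np.zeros(m, dtype=np.int64)
    Y = np.zeros(m, dtype=np.int64)
    ub = np.searchsorted(ts, times, side="right")
    ei = np.searchsorted(ts, times)
    for s in range(n):
        if events[s] == 1:
            d[ei[s]] += 1
        for i in range(ub[s]):
            Y[i] += 1
        if events[s] == 0:
            ei[s] = 0
    return ts, d, Y, ub, ei


@njit(cache=True)
def tree_chf_at(feature, threshold, left, right,
                chf_off, chf_len, chf_times, chf_H, X, t):
    """H(t) at the leaf reached by each row of X in one array-encoded tree."""
    n = X.shape[0]
    out = np.zeros(n)
    for s in range(n):
        node = 0
        while feature[node] >= 0:
            if X[s, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        off = chf_off[node]
        ln = chf_len[node]
        # step function: last jump time <= t
        k = 0
        while k < ln and chf_times[off + k] <= t:
            k += 1
        if k > 0:
            out[s] = chf_H[off + k - 1]
    return out


@njit(cache=True)
def predict_leaf(feature, threshold, left, right, X):
    """Leaf index reached by each row of X in one array-encoded tree."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.int64)
    for s in range(n):
        node = 0
        while feature[node] >= 0:
            if X[s, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[s] = node
    return out
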