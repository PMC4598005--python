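"""Random survival forest with log-rank splitting and Nelson-Aalen leaves.

The model follows the classical random-survival-forest recipe: each of
``ntree`` trees is grown on a bootstrap resample of the training data; at
every node a fresh random subset of ``mtry`` predictors is searched for the
cut maximizing the absolute standardized log-rank statistic

    F(x, c) = sum_i (d_i1 - Y_i1 d_i / Y_i)
              / sqrt(sum_i (Y_i1/Y_i)(1 - Y_i1/Y_i)((Y_i - d_i)/(Y_i - 1)) d_i)

over the node's distinct event times t_i, where daughter 1 collects samples
with x <= c.  Terminal nodes carry the Nelson-Aalen cumulative-hazard step
function of their samples, H(t) = sum_{t_i <= t} d_i / Y_i, and the ensemble
prediction is the plain average of the per-tree leaf hazards.

Organised in the model/results style: construct a :class:`SurvivalForest`
from data, call :meth:`~SurvivalForest.fit`, and work with the returned
:class:`SurvivalForestResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._forest_kernels import (
    best_split_kernel,
    node_risk_sets,
    predict_leaf,
    tree_chf_at,
)


@dataclass(frozen=True)
class SplitCandidate:
    """A candidate node split: predictor name, cut value, signed statistic."""

    feature: str
    c: float
    F: float


@dataclass
class CHFStepFunction:
    """Right-continuous non-decreasing cumulative-hazard step function.

    ``times`` are the sorted event times at which the hazard jumps; ``H`` the
    cumulative values after each jump.  H(t) = 0 for t below the first jump.
    """

    times: np.ndarray
    H: np.ndarray

    def __call__(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float),
                              side="right")
        padded = np.concatenate([[0.0], self.H])
        return padded[idx]


@dataclass
class SurvivalTreeNode:
    """Nested view of a survival tree: either a split or a terminal CHF."""

    split: Optional[SplitCandidate] = None
    left: Optional["SurvivalTreeNode"] = None
    right: Optional["SurvivalTreeNode"] = None
    terminal: Optional[CHFStepFunction] = None

    @property
    def is_leaf(self) -> bool:
        return self.terminal is not None


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    ntree=300 mirrors the reference modelling protocol; mtry defaults to
    ceil(sqrt(p)); nodesize_min is the smallest node that will still be
    searched for a split (1 grows trees to single-sample purity, the default
    of 3 trades a little purity for stability at desk scale); horizon_days is
    the scoring time t* for 30-day risk.  ``bootstrap=False`` is a test hook
    that fits every tree on the full sample.
    """

    ntree: int = 300
    mtry: Optional[int] = None
    nodesize_min: int = 3
    seed: int = 0
    horizon_days: int = 30
    bootstrap: bool = True
    chf_estimator: str = "nelson-aalen"  # or "neg-log-km"

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.nodesize_min < 1:
            raise ValueError("nodesize_min must be >= 1")
        if self.chf_estimator not in ("nelson-aalen", "neg-log-km"):
            raise ValueError(f"unknown chf_estimator {self.chf_estimator!r}")


# ------------------------------------------------------------ primitives


def _as_arrays(times, events, x=None):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=np.int64)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if x is not None:
        xv = np.asarray(x, dtype=float)
        if xv.shape[0] != t.shape[0]:
            raise ValueError("feature vector length mismatch")
        return t, e, xv
    return t, e


def logrank_statistic(times, events, x, c,
                      feature: str = "x") -> Optional[SplitCandidate]:
    """Signed log-rank split statistic F for the cut ``x <= c``.

    Returns None (an invalid-split signal) when a daughter is empty or the
    variance sum vanishes.  Terms with a single subject at risk contribute
    zero to the denominator.
    """
    t, e, xv = _as_arrays(times, events, x)
    in1 = xv <= c
    if not in1.any() or in1.all():
        return None
    ts = np.unique(t[e == 1])
    if ts.size == 0:
        return None
    num = 0.0
    den = 0.0
    for ti in ts:
        at_risk = t >= ti
        Yi = int(at_risk.sum())
        di = int(((t == ti) & (e == 1)).sum())
        Yi1 = int((at_risk & in1).sum())
        di1 = int(((t == ti) & (e == 1) & in1).sum())
        num += di1 - Yi1 * di / Yi
        if Yi > 1:
            p1 = Yi1 / Yi
            den += p1 * (1.0 - p1) * ((Yi - di) / (Yi - 1.0)) * di
    if den <= 0.0:
        return None
    return SplitCandidate(feature=feature, c=float(c), F=num / np.sqrt(den))


def best_split(times, events, X, feature_names: Sequence[str],
               candidates: Optional[Sequence[int]] = None,
               ) -> Optional[SplitCandidate]:
    """Exhaustive best log-rank split over features and midpoint cuts.

    Cut points are midpoints between consecutive distinct observed values.
    Ties in |F| are broken by (lower feature name, lower cut).  Reference
    implementation in plain numpy; the tree grower uses the compiled kernel,
    which is checked against this function in the test suite.
    """
    t, e = _as_arrays(times, events)
    X = np.asarray(X, dtype=float)
    names = list(feature_names)
    if candidates is None:
        candidates = range(X.shape[1])
    best: Optional[SplitCandidate] = None
    for j in sorted(candidates, key=lambda j: names[j]):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            c = 0.5 * (lo + hi)
            cand = logrank_statistic(t, e, X[:, j], c, feature=names[j])
            if cand is None:
                continue
            if best is None or abs(cand.F) > abs(best.F):
                best = cand
    return best


def terminal_chf(times, events,
                 estimator: str = "nelson-aalen") -> CHFStepFunction:
    """Cumulative-hazard step function of a terminal node's samples.

    Default is the Nelson-Aalen estimator H(t) = sum_{t_i <= t} d_i / Y_i.
    ``estimator="neg-log-km"`` instead returns -log of the Kaplan-Meier
    survival, with S floored at 0.5/n so fully-eventful nodes stay finite.
    """
    t, e = _as_arrays(times, events)
    if t.size == 0:
        raise ValueError("cannot estimate a CHF from zero samples")
    ts = np.unique(t[e == 1])
    if ts.size == 0:
        return CHFStepFunction(times=np.empty(0), H=np.empty(0))
    d = np.array([((t == ti) & (e == 1)).sum() for ti in ts], dtype=float)
    Y = np.array([(t >= ti).sum() for ti in ts], dtype=float)
    if estimator == "nelson-aalen":
        H = np.cumsum(d / Y)
    elif estimator == "neg-log-km":
        S = np.cumprod(1.0 - d / Y)
        H = -np.log(np.maximum(S, 0.5 / t.size))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return CHFStepFunction(times=ts.astype(float), H=H)


# ------------------------------------------------------------------ trees


class SurvivalTree:
    """Array-encoded log-rank survival tree (one member of the forest)."""

    __slots__ = ("feature", "threshold", "left", "right",
                 "chf_off", "chf_len", "chf_times", "chf_H", "n_node",
                 "_names")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.chf_off: list[int] = []
        self.chf_len: list[int] = []
        self.chf_times: list[float] = []
        self.chf_H: list[float] = []
        self.n_node: list[int] = []

    def _finalize(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.chf_off = np.asarray(self.chf_off, dtype=np.int64)
        self.chf_len = np.asarray(self.chf_len, dtype=np.int64)
        self.chf_times = np.asarray(self.chf_times, dtype=float)
        self.chf_H = np.asarray(self.chf_H, dtype=float)
        self.n_node = np.asarray(self.n_node, dtype=np.int64)

    def predict_leaf(self, X: np.ndarray) -> np.ndarray:
        return predict_leaf(self.feature, self.threshold, self.left,
                            self.right, np.ascontiguousarray(X, dtype=float))

    def chf_at(self, X: np.ndarray, t: float) -> np.ndarray:
        return tree_chf_at(self.feature, self.threshold, self.left,
                           self.right, self.chf_off, self.chf_len,
                           self.chf_times, self.chf_H,
                           np.ascontiguousarray(X, dtype=float), float(t))

    def leaf_chf(self, node: int) -> CHFStepFunction:
        off, ln = self.chf_off[node], self.chf_len[node]
        return CHFStepFunction(times=self.chf_times[off:off + ln].copy(),
                               H=self.chf_H[off:off + ln].copy())

    def root_node(self) -> SurvivalTreeNode:
        """Nested-node view of the tree (for inspection and serialization)."""
        def build(i: int, names) -> SurvivalTreeNode:
            if self.feature[i] < 0:
                return SurvivalTreeNode(terminal=self.leaf_chf(i))
            return SurvivalTreeNode(
                split=SplitCandidate(feature=names[self.feature[i]],
                                     c=float(self.threshold[i]), F=np.nan),
                left=build(self.left[i], names),
                right=build(self.right[i], names))
        names = getattr(self, "_names", None)
        if names is None:
            names = [f"x{j}" for j in range(int(self.feature.max()) + 1 or 1)]
        return build(0, names)


def _grow_tree_arrays(times: np.ndarray, events: np.ndarray, X: np.ndarray,
                      name_rank: np.ndarray, config: ForestConfig,
                      rng: np.random.Generator) -> SurvivalTree:
    p = X.shape[1]
    mtry = config.mtry or int(np.ceil(np.sqrt(p)))
    mtry = min(max(1, mtry), p)
    tree = SurvivalTree()

    def new_node() -> int:
        i = len(tree.feature)
        tree.feature.append(-1)
        tree.threshold.append(np.nan)
        tree.left.append(-1)
        tree.right.append(-1)
        tree.chf_off.append(0)
        tree.chf_len.append(0)
        tree.n_node.append(0)
        return i

    def make_leaf(node: int, idx: np.ndarray) -> None:
        chf = terminal_chf(times[idx], events[idx],
                           estimator=config.chf_estimator)
        tree.chf_off[node] = len(tree.chf_times)
        tree.chf_len[node] = len(chf.times)
        tree.chf_times.extend(chf.times.tolist())
        tree.chf_H.extend(chf.H.tolist())

    stack = [(new_node(), np.arange(len(times)))]
    while stack:
        node, idx = stack.pop()
        tree.n_node[node] = len(idx)
        t, e = times[idx], events[idx]
        if len(idx) < config.nodesize_min or e.sum() == 0:
            make_leaf(node, idx)
            continue
        cand = rng.choice(p, size=mtry, replace=False)
        cand = cand[np.argsort(name_rank[cand])].astype(np.int64)
        ts, d, Y, ub, ei = node_risk_sets(t.astype(float), e)
        j, cut, F, absF = best_split_kernel(
            np.ascontiguousarray(X[idx]), e, cand, d, Y, ub, ei, 1)
        if j < 0:
            make_leaf(node, idx)
            continue
        tree.feature[node] = int(j)
        tree.threshold[node] = float(cut)
        mask = X[idx, j] <= cut
        l, r = new_node(), new_node()
        tree.left[node], tree.right[node] = l, r
        # push right first so the left child is processed (and numbered) next
        stack.append((r, idx[~mask]))
        stack.append((l, idx[mask]))
    tree._finalize()
    return tree


def grow_tree(times, events, X, feature_names: Sequence[str],
              config: Optional[ForestConfig] = None,
              rng: Optional[np.random.Generator] = None) -> SurvivalTree:
    """Grow a single survival tree on the given samples (no bootstrap)."""
    config = config or ForestConfig(ntree=1)
    rng = rng or np.random.default_rng(config.seed)
    t, e = _as_arrays(times, events)
    X = np.asarray(X, dtype=float)
    if t.size == 0:
        raise ValueError("cannot grow a tree on zero samples")
    names = np.asarray(list(feature_names))
    name_rank = np.empty(len(names), dtype=np.int64)
    name_rank[np.argsort(names)] = np.arange(len(names))
    tree = _grow_tree_arrays(t, e, X, name_rank, config, rng)
    tree._names = list(feature_names)  # type: ignore[attr-defined]
    return tree


# ------------------------------------------------------------------ model


class SurvivalForest:
    """Random survival forest model for time-to-readmission data.

    Parameters
    ----------
    times, events : observed days to readmission (or censoring) and event
        indicators, one entry per index discharge.
    X : (n, p) predictor matrix or DataFrame.
    feature_names : required when X is a bare array.
    config : :class:`ForestConfig`.

    Call :meth:`fit` to obtain a :class:`SurvivalForestResults`.
    """

    def __init__(self, times, events, X,
                 feature_names: Optional[Sequence[str]] = None,
                 config: Optional[ForestConfig] = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        elif feature_names is None:
            X = np.asarray(X, dtype=float)
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        self.times, self.events = _as_arrays(times, events)
        self.X = np.ascontiguousarray(X, dtype=float)
        if self.X.shape[0] != self.times.shape[0]:
            raise ValueError("X and times must have equal length")
        self.feature_names = list(feature_names)
        self.config = config or ForestConfig()
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       duration_col: str = "observed_time",
                       event_col: str = "event_observed",
                       feature_cols: Optional[Sequence[str]] = None,
                       config: Optional[ForestConfig] = None,
                       ) -> "SurvivalForest":
        if feature_cols is None:
            feature_cols = [c for c in df.columns
                            if c not in (duration_col, event_col)]
        return cls(df[duration_col], df[event_col], df[list(feature_cols)],
                   config=config)

    def fit(self) -> "SurvivalForestResults":
        """Grow the forest: one tree per seeded bootstrap resample."""
        if self.events.sum() == 0:
            raise ValueError("no events in the training data")
        cfg = self.config
        names = np.asarray(self.feature_names)
        name_rank = np.empty(len(names), dtype=np.int64)
        name_rank[np.argsort(names)] = np.arange(len(names))
        ss = np.random.SeedSequence([cfg.seed, 555])
        children = ss.spawn(cfg.ntree)
        n = len(self.times)
        trees = []
        for b in range(cfg.ntree):
            rng = np.random.default_rng(children[b])
            idx = rng.integers(0, n, size=n) if cfg.bootstrap else np.arange(n)
            trees.append(_grow_tree_arrays(
                self.times[idx], self.events[idx], self.X[idx],
                name_rank, cfg, rng))
        return SurvivalForestResults(self, trees)


class SurvivalForestResults:
    """Fitted forest: ensemble hazard predictions, importances, persistence."""

    def __init__(self, model: SurvivalForest, trees: list[SurvivalTree]):
        self.model = model
        self.trees = trees
        self.feature_names = model.feature_names
        self.config = model.config

    # ------------------------------------------------------- predictions

    def _check_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"missing features: {sorted(missing)[:5]}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, "
                f"got {X.shape[1]}")
        return X

    def predict_chf(self, X, t: Optional[float] = None) -> np.ndarray:
        """Ensemble cumulative hazard H^e(t | x) for each row of X."""
        if t is None:
            t = float(self.config.horizon_days)
        X = self._check_X(X)
        acc = np.zeros(X.shape[0])
        for tree in self.trees:
            acc += tree.chf_at(X, float(t))
        return acc / len(self.trees)

    def predict_risk(self, X) -> np.ndarray:
        """Ensemble cumulative hazard at the scoring horizon (t* = 30)."""
        return self.predict_chf(X, float(self.config.horizon_days))

    def ensemble_chf(self, x, t: float) -> float:
        """Scalar H^e(t | x) for a single feature vector."""
        return float(self.predict_chf(np.asarray(x, dtype=float), t)[0])

    # ------------------------------------------------------- diagnostics

    def permutation_importance(self, X, labels,
                               transform: Optional[Callable] = None,
                               seed: Optional[int] = None) -> pd.Series:
        """Permutation importance against the binary 30-day outcome.

        For each feature the evaluation column is permuted (seeded) and the
        increase in mean-square error of the monotonely rescaled ensemble
        score against ``labels`` is reported.  ``transform`` maps the raw
        ensemble hazard to the evaluation scale (default: min-max rescale
        fitted on the unpermuted predictions; the pipeline passes the
        calibrated score / 100).
        """
        X = self._check_X(X)
        y = np.asarray(labels, dtype=float)
        base_h = self.predict_risk(X)
        if transform is None:
            lo, hi = base_h.min(), base_h.max()
            span = hi - lo if hi > lo else 1.0
            transform = lambda h: np.clip((h - lo) / span, 0.0, 1.0)
        base_mse = float(np.mean((transform(base_h) - y) ** 2))
        rng = np.random.default_rng(
            [self.config.seed if seed is None else seed, 666])
        imp = {}
        for j, name in enumerate(self.feature_names):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            mse = float(np.mean((transform(self.predict_risk(Xp)) - y) ** 2))
            imp[name] = mse - base_mse
        return pd.Series(imp, name="importance")

    def summary(self) -> str:
        cfg = self.config
        n = len(self.model.times)
        d = int(self.model.events.sum())
        mtry = cfg.mtry or int(np.ceil(np.sqrt(len(self.feature_names))))
        leaves = np.mean([(t.feature < 0).sum() for t in self.trees])
        lines = [
            "Random Survival Forest Results",
            "=" * 46,
            f"{'No. samples:':<28}{n}",
            f"{'No. events:':<28}{d}",
            f"{'No. features:':<28}{len(self.feature_names)}",
            f"{'Trees:':<28}{cfg.ntree}",
            f"{'mtry:':<28}{mtry}",
            f"{'Min node size to split:':<28}{cfg.nodesize_min}",
            f"{'Scoring horizon (days):':<28}{cfg.horizon_days}",
            f"{'Leaf CHF estimator:':<28}{cfg.chf_estimator}",
            f"{'Avg. leaves per tree:':<28}{leaves:.1f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # ------------------------------------------------------- persistence

    def to_dict(self) -> dict:
        trees = []
        for t in self.trees:
            trees.append({
                "feature": t.feature.tolist(),
                "threshold": [None if np.isnan(v) else v
                              for v in t.threshold],
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "chf_off": t.chf_off.tolist(),
                "chf_len": t.chf_len.tolist(),
                "chf_times": t.chf_times.tolist(),
                "chf_H": t.chf_H.tolist(),
                "n_node": t.n_node.tolist(),
            })
        cfg = self.config
        return {
            "feature_names": self.feature_names,
            "config": {
                "ntree": cfg.ntree, "mtry": cfg.mtry,
                "nodesize_min": cfg.nodesize_min, "seed": cfg.seed,
                "horizon_days": cfg.horizon_days, "bootstrap": cfg.bootstrap,
                "chf_estimator": cfg.chf_estimator,
            },
            "trees": trees,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "SurvivalForestResults":
        cfg = ForestConfig(**doc["config"])
        names = doc["feature_names"]
        model = SurvivalForest(np.zeros(0), np.zeros(0, dtype=int),
                               np.zeros((0, len(names))),
                               feature_names=names, config=cfg)
        trees = []
        for td in doc["trees"]:
            t = SurvivalTree()
            t.feature = td["feature"]
            t.threshold = [np.nan if v is None else v for v in td["threshold"]]
            t.left, t.right = td["left"], td["right"]
            t.chf_off, t.chf_len = td["chf_off"], td["chf_len"]
            t.chf_times, t.chf_H = td["chf_times"], td["chf_H"]
            t.n_node = td["n_node"]
            t._finalize()
            trees.append(t)
        return cls(model, trees)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "SurvivalForestResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ensemble_chf(results: SurvivalForestResults, x, t: float) -> float:
    """Module-level convenience for H^e(t | x) of a fitted forest."""
    return results.ensemble_chf(x, t)


# ------------------------------------------------- forward feature selection


def forward_feature_selection(
    importance: pd.Series,
    eval_fn: Callable[[list[str]], float],
    batch_size: int = 5,
    tol: float = 1e-3,
    patience: int = 2,
    n_start: int = 10,
) -> list[str]:
    """Iterative forward selection over an importance ranking.

    Starts from the ``n_start`` most important features, then adds features in
    descending importance in batches of ``batch_size``; after each step
    ``eval_fn`` scores the candidate set on held-out data (the pipeline uses
    sensitivity + specificity - 1 at the high-tier threshold).  Stops when the
    score has not improved by more than ``tol`` for ``patience`` consecutive
    steps, and returns the best-scoring set seen.
    """
    ranked = list(importance.sort_values(ascending=False,
                                         kind="stable").index)
    if len(ranked) <= n_start:
        return ranked
    current = ranked[:n_start]
    best_set, best_score = list(current), eval_fn(list(current))
    stale = 0
    pos = n_start
    while pos < len(ranked) and stale < patience:
        current = current + ranked[pos:pos + batch_size]
        pos += batch_size
        score = eval_fn(list(current))
        if score > best_score + tol:
            best_set, best_score = list(current), score
            stale = 0
        else:
            stale += 1
    return best_set
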