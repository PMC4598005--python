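"""High-risk phenotype discovery: PCA projection, K-means, elbow selection.

High-risk encounters are projected onto the first two principal components of
their standardized feature matrix and clustered with K-means.  The cluster
count is chosen from the total within-cluster sum of squares (TWSS) trace via
its reduction rate

    R_k = (TWSS_{k-1} - TWSS_k) / TWSS_{k-1},

keeping K = max{k : R_k > threshold} with threshold 0.2 by default; the argmax
of R_k is reported alongside for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class PCAProjection:
    """Rank-2 PCA of standardized features: loadings, variances, coords."""

    loadings: pd.DataFrame          # feature x (pc1, pc2)
    explained_variance: np.ndarray  # top-2 eigenvalues
    coords: pd.DataFrame            # sample x (pc1, pc2)
    mean: np.ndarray
    scale: np.ndarray


@dataclass
class ClusterSelection:
    """TWSS / R_k trace over a k grid and the chosen cluster count."""

    k_grid: np.ndarray
    twss: np.ndarray
    r_k: np.ndarray          # aligned with k_grid; R_1 is NaN
    k_selected: int
    k_peak: int              # argmax of R_k, reported for comparison
    threshold: float

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_grid, "twss": self.twss,
                             "r_k": self.r_k})


def pca_project(features: pd.DataFrame) -> PCAProjection:
    """Project samples onto the top-2 PCs of the z-scored feature matrix.

    Constant features are dropped before standardization.  Component signs are
    fixed so each component's largest-magnitude loading is positive, making
    the projection deterministic.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 samples for a PCA projection")
    X = features.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-degenerate feature dimensions")
    cols = features.columns[keep]
    mean = X[:, keep].mean(axis=0)
    scale = sd[keep]
    Z = (X[:, keep] - mean) / scale
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(Z)
    loadings = pca.components_.copy()
    for c in range(2):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
            coords[:, c] = -coords[:, c]
    return PCAProjection(
        loadings=pd.DataFrame(loadings.T, index=cols, columns=["pc1", "pc2"]),
        explained_variance=pca.explained_variance_.copy(),
        coords=pd.DataFrame(coords, index=features.index,
                            columns=["pc1", "pc2"]),
        mean=mean, scale=scale)


def _twss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def kmeans_twss(coords, k: int, n_restarts: int = 10, seed: int = 0,
                init_centers: Optional[np.ndarray] = None,
                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Best-of-restarts Lloyd K-means; returns (labels, TWSS, centers).

    TWSS is the sum over clusters of squared distances to the cluster
    centroid.  k = 1 is computed in closed form (total sum of squares about
    the grand mean); an optional warm start from ``init_centers`` is run in
    addition to the seeded k-means++ restarts.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    if k == 1:
        center = X.mean(axis=0, keepdims=True)
        return np.zeros(n, dtype=int), float(((X - center) ** 2).sum()), center
    best = None
    seeds = np.random.SeedSequence([seed, 808, k]).generate_state(n_restarts)
    inits: list = [int(s) % (2 ** 31) for s in seeds]
    runs = [("++", s) for s in inits]
    if init_centers is not None and len(init_centers) == k:
        runs.append(("warm", None))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence noise
        for kind, s in runs:
            if kind == "++":
                km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                            max_iter=300, tol=1e-6, algorithm="lloyd",
                            random_state=s)
            else:
                km = KMeans(n_clusters=k, init=np.asarray(init_centers),
                            n_init=1, max_iter=300, tol=1e-6,
                            algorithm="lloyd")
            labels = km.fit_predict(X)
            twss = _twss(X, labels)
            if best is None or twss < best[1] - 1e-12:
                best = (labels, twss, km.cluster_centers_.copy())
    return best


def select_k(coords, k_max: int = 15, threshold: float = 0.2,
             n_restarts: int = 10, seed: int = 0) -> ClusterSelection:
    """Choose the cluster count from the TWSS reduction-rate trace.

    K = max{k in 2..k_max : R_k > threshold}; if no k qualifies, K = 1 with a
    warning.  Each k >= 3 warm-starts one run from the previous best centers
    (plus the point farthest from its centroid) so the TWSS trace is
    non-increasing.  Degenerate input (all points identical) yields TWSS = 0
    for every k and K = 1.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(coords, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    k_max = min(k_max, n)
    k_grid = np.arange(1, k_max + 1)
    twss = np.empty(len(k_grid))
    prev_labels = prev_centers = None
    for i, k in enumerate(k_grid):
        init = None
        if prev_centers is not None and n > len(prev_centers):
            dists = np.linalg.norm(
                X - prev_centers[prev_labels], axis=1)
            far = X[int(np.argmax(dists))]
            init = np.vstack([prev_centers, far])
        labels, w, centers = kmeans_twss(
            X, int(k), n_restarts=n_restarts, seed=seed, init_centers=init)
        twss[i] = w
        prev_labels, prev_centers = labels, centers
    r_k = np.full(len(k_grid), np.nan)
    for i in range(1, len(k_grid)):
        r_k[i] = ((twss[i - 1] - twss[i]) / twss[i - 1]
                  if twss[i - 1] > 0 else 0.0)
    qualifying = [int(k) for i, k in enumerate(k_grid)
                  if i >= 1 and r_k[i] > threshold]
    if qualifying:
        k_sel = max(qualifying)
    else:
        warnings.warn("no k exceeded the R_k threshold; selecting K=1",
                      stacklevel=2)
        k_sel = 1
    finite = np.nan_to_num(r_k, nan=-np.inf)
    k_peak = int(k_grid[int(np.argmax(finite))]) if len(k_grid) > 1 else 1
    return ClusterSelection(k_grid=k_grid, twss=twss, r_k=r_k,
                            k_selected=k_sel, k_peak=k_peak,
                            threshold=threshold)


def profile_clusters(assignment, features: pd.DataFrame,
                     coords=None) -> list[dict]:
    """Per-cluster clinical profiles.

    For each cluster: size, mean lab / radiology / prescription utilization,
    mean chronic-disease count, chronic-condition prevalences, age-group
    percentage breakdown, and (when coords are given) the within-cluster sum
    of squares.  Empty clusters are omitted with a warning.
    """
    labels = np.asarray(assignment)
    if len(labels) != len(features):
        raise ValueError("assignment must cover all rows")
    profiles = []
    for c in np.unique(labels):
        mask = labels == c
        if not mask.any():
            warnings.warn(f"cluster {c} is empty; omitted", stacklevel=2)
            continue
        sub = features.loc[mask]
        prof: dict = {"cluster_id": int(c), "n": int(mask.sum())}
        for col, key in [("labs_total", "mean_labs"),
                         ("rad_total", "mean_radiology"),
                         ("meds_total", "mean_medications"),
                         ("chronic_count", "mean_chronic_count")]:
            if col in sub:
                prof[key] = float(sub[col].mean())
        chronic_cols = [c2 for c2 in sub.columns if c2.startswith("chronic_cond")
                        or (c2.startswith("chronic_") and c2 != "chronic_count")]
        if chronic_cols:
            prof["chronic_prevalence_pct"] = {
                c2: float(100.0 * sub[c2].mean()) for c2 in chronic_cols}
        if "age_group_idx" in sub:
            counts = sub["age_group_idx"].value_counts()
            prof["age_group_pct"] = {
                int(g): float(100.0 * v / len(sub))
                for g, v in counts.sort_index().items()}
        if coords is not None:
            pts = np.asarray(coords, dtype=float)[mask]
            prof["within_ss"] = float(((pts - pts.mean(axis=0)) ** 2).sum())
        profiles.append(prof)
    return profiles
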