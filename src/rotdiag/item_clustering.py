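"""Exploratory Q-matrix validation by k-prototypes clustering of items.

Items within a module are clustered on mixed features built from the
response data: a numeric block (log response times) and a categorical
block (binary responses).  The k-prototypes cost combines squared
Euclidean distance on the numeric block with a weighted simple-matching
mismatch count on the categorical block.  The number of clusters is chosen
by the Global Silhouette (the mean per-item silhouette under the same
mixed dissimilarity).  The resulting grouping is compared with the
single-skill / two-skill split implied by the Q-matrix, flagging items
whose empirical behavior disagrees with their declared complexity.

Two feature modes are offered: ``summary`` (default; per-item proportion
correct overall and per covariate stratum, plus mean and SD of log RT) and
``raw`` (person-indexed response and log-RT vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import QMatrix, ResponseDataset

__all__ = [
    "ItemFeatureMatrix",
    "ClusteringResult",
    "build_item_features",
    "mixed_dissimilarity",
    "kprototype",
    "global_silhouette",
    "choose_num_clusters",
    "compare_to_q",
]


@dataclass
class ItemFeatureMatrix:
    """Aligned numeric and categorical feature blocks for a set of items.

    numeric: (J, p) standardized columns; categorical: (J, q) integer codes
    (q may be 0, in which case k-prototypes reduces to k-means).
    """

    numeric: np.ndarray
    categorical: np.ndarray
    item_ids: np.ndarray = None

    def __post_init__(self):
        self.numeric = np.atleast_2d(np.asarray(self.numeric, dtype=float))
        self.categorical = np.asarray(self.categorical)
        if self.categorical.size == 0:
            self.categorical = np.zeros((self.numeric.shape[0], 0), dtype=int)
        if self.categorical.shape[0] != self.numeric.shape[0]:
            raise ValueError("numeric and categorical blocks must align on items")
        if self.item_ids is None:
            self.item_ids = np.arange(self.numeric.shape[0])

    @property
    def n_items(self) -> int:
        return self.numeric.shape[0]


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def build_item_features(ds: ResponseDataset, module: int, covariates=None,
                        mode: str = "summary") -> ItemFeatureMatrix:
    """Per-item features for one module from responses and response times."""
    idx = np.flatnonzero(ds.module_of_item == module)
    y = ds.Y[:, idx].astype(float)
    logl = np.log(ds.L[:, idx])
    if mode == "raw":
        return ItemFeatureMatrix(numeric=_standardize(logl.T),
                                 categorical=y.T.astype(int),
                                 item_ids=ds.item_ids[idx])
    if mode != "summary":
        raise ValueError(f"unknown feature mode {mode!r}")
    cols = [y.mean(axis=0), logl.mean(axis=0), logl.std(axis=0)]
    if covariates is not None:
        from .data_model import encode_covariates

        cov5 = covariates if isinstance(covariates, np.ndarray) else encode_covariates(covariates)
        for c in range(2):  # accuracy by gender and country strata
            for level in (0, 1):
                sel = cov5[:, c] == level
                if sel.any():
                    cols.append(y[sel].mean(axis=0))
    numeric = _standardize(np.column_stack(cols))
    return ItemFeatureMatrix(numeric=numeric,
                             categorical=np.zeros((idx.size, 0), dtype=int),
                             item_ids=ds.item_ids[idx])


@dataclass
class ClusteringResult:
    """K-prototypes output for one feature matrix."""

    assignments: np.ndarray
    prototypes_numeric: np.ndarray
    prototypes_categorical: np.ndarray
    cost: float
    n_clusters: int
    gamma_w: float
    silhouette: np.ndarray = field(default=None)
    global_silhouette: float = field(default=None)


def default_gamma(features: ItemFeatureMatrix) -> float:
    """Half the mean numeric-feature standard deviation (Huang's guidance)."""
    return 0.5 * float(features.numeric.std(axis=0).mean())


def mixed_dissimilarity(features: ItemFeatureMatrix, gamma_w: float) -> np.ndarray:
    """(J, J) pairwise mixed dissimilarity: squared Euclidean + gamma * mismatch."""
    x = features.numeric
    d_num = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    if features.categorical.shape[1]:
        c = features.categorical
        d_cat = (c[:, None, :] != c[None, :, :]).sum(axis=2)
    else:
        d_cat = 0.0
    return d_num + gamma_w * d_cat


def _assign_cost(features, centers_num, centers_cat, gamma_w):
    x = features.numeric
    d = ((x[:, None, :] - centers_num[None, :, :]) ** 2).sum(axis=2)
    if features.categorical.shape[1]:
        d = d + gamma_w * (features.categorical[:, None, :]
                           != centers_cat[None, :, :]).sum(axis=2)
    assign = d.argmin(axis=1)
    return assign, float(d[np.arange(x.shape[0]), assign].sum())


def _mode(col: np.ndarray) -> int:
    vals, counts = np.unique(col, return_counts=True)
    return int(vals[counts.argmax()])


def kprototype(features: ItemFeatureMatrix, n_clusters: int, gamma_w: float = None,
               seed: int = 0, n_init: int = 10, max_iter: int = 100) -> ClusteringResult:
    """K-prototypes clustering; best of ``n_init`` seeded restarts.

    The cost (sum of within-cluster mixed dissimilarities to the prototype)
    is non-increasing across Lloyd iterations; empty clusters are reseeded
    with the point farthest from its prototype.
    """
    j = features.n_items
    if not 2 <= n_clusters <= j - 1:
        raise ValueError(f"cluster count {n_clusters} invalid for {j} items")
    if gamma_w is None:
        gamma_w = default_gamma(features)
    if gamma_w < 0:
        raise ValueError("categorical weight must be non-negative")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        order = rng.permutation(j)[:n_clusters]
        cen_num = features.numeric[order].copy()
        cen_cat = features.categorical[order].copy()
        prev_cost = np.inf
        for _ in range(max_iter):
            assign, cost = _assign_cost(features, cen_num, cen_cat, gamma_w)
            # reseed empty clusters deterministically
            for m in range(n_clusters):
                if not (assign == m).any():
                    d_own = ((features.numeric - cen_num[assign]) ** 2).sum(axis=1)
                    far = int(np.argmax(d_own))
                    assign[far] = m
            for m in range(n_clusters):
                members = assign == m
                cen_num[m] = features.numeric[members].mean(axis=0)
                if features.categorical.shape[1]:
                    cen_cat[m] = [
                        _mode(features.categorical[members][:, c])
                        for c in range(features.categorical.shape[1])
                    ]
            if cost >= prev_cost - 1e-12:
                break
            prev_cost = cost
        assign, cost = _assign_cost(features, cen_num, cen_cat, gamma_w)
        if best is None or cost < best.cost - 1e-12:
            best = ClusteringResult(assignments=assign, prototypes_numeric=cen_num,
                                    prototypes_categorical=cen_cat, cost=cost,
                                    n_clusters=n_clusters, gamma_w=gamma_w)
    s, gs = global_silhouette(features, best.assignments, gamma_w)
    best.silhouette = s
    best.global_silhouette = gs
    return best


def global_silhouette(features: ItemFeatureMatrix, assignments, gamma_w: float = None):
    """Per-item silhouettes s(i) = (b - a) / max(a, b) and their mean (GS).

    Uses the mixed dissimilarity.  Items in singleton clusters get s = 0.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if labels.size < 2:
        raise ValueError("silhouette requires at least 2 non-empty clusters")
    if gamma_w is None:
        gamma_w = default_gamma(features)
    d = mixed_dissimilarity(features, gamma_w)
    j = features.n_items
    s = np.zeros(j)
    for i in range(j):
        own = assignments == assignments[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, assignments == lab].mean()
                for lab in labels if lab != assignments[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def choose_num_clusters(features: ItemFeatureMatrix, m_range=(2, 3, 4, 5),
                        gamma_w: float = None, seed: int = 0) -> int:
    """Cluster count maximizing the Global Silhouette; ties take the smallest M."""
    best_m, best_gs = None, -np.inf
    for m in sorted(m_range):
        res = kprototype(features, m, gamma_w=gamma_w, seed=seed)
        if res.global_silhouette > best_gs + 1e-12:
            best_m, best_gs = m, res.global_silhouette
    return best_m


def compare_to_q(result: ClusteringResult, q_module: np.ndarray,
                 ds: ResponseDataset = None, module: int = None) -> pd.DataFrame:
    """Cross-tabulate clusters against single/two-skill item classes.

    The cluster holding the majority of single-skill items is labeled the
    'simple' cluster; items whose Q-class disagrees with their cluster are
    flagged, with mean accuracy and mean RT attached when data are given.
    """
    q_module = np.asarray(q_module)
    n_skills = q_module.sum(axis=1)
    simple = n_skills == 1
    assign = result.assignments
    # majority cluster of the simple items
    labs, counts = np.unique(assign[simple], return_counts=True)
    simple_cluster = int(labs[counts.argmax()]) if labs.size else -1
    rows = []
    for i in range(len(assign)):
        in_simple_cluster = assign[i] == simple_cluster
        mismatch = bool(simple[i] != in_simple_cluster)
        row = {
            "item": i,
            "n_skills": int(n_skills[i]),
            "cluster": int(assign[i]),
            "mismatch": mismatch,
        }
        if ds is not None and module is not None:
            idx = np.flatnonzero(ds.module_of_item == module)
            row["mean_accuracy"] = float(ds.Y[:, idx[i]].mean())
            row["mean_rt"] = float(ds.L[:, idx[i]].mean())
        rows.append(row)
    return pd.DataFrame(rows)
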