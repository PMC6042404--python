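"""K-means grouping of TSS binding profiles (G1..Gk) and of differentially
expressed genes' condition trajectories (C1..Ck), with deterministic label
conventions so that reruns and center permutations yield identical labels.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans


def _row_align(matrices: Sequence[pd.DataFrame]) -> pd.Index:
    idx = matrices[0].index
    for m in matrices[1:]:
        if not m.index.equals(idx):
            raise ValueError("TSS matrices are not row-aligned on the same genes")
    return idx


class TssKMeans(BaseEstimator):
    """Group genes by their binding profiles around the TSS.

    ``fit`` takes a list of row-aligned TSS matrices (one per track); the
    feature vector per gene is the concatenation of its binned profiles.
    Genes are sorted by id before clustering, so input order never changes
    the result. Group labels G1..Gk are assigned in descending order of the
    cluster-center mean of the first track's central bins; empty clusters
    are flagged and skipped in the numbering.

    Fitted attributes: ``labels_`` (pd.Series gene -> group), ``centers_``,
    ``inertia_``, ``empty_groups_``.
    """

    def __init__(self, k: int = 5, seed: int = 0, n_init: int = 10,
                 central_frac: float = 0.2):
        self.k = k
        self.seed = seed
        self.n_init = n_init
        self.central_frac = central_frac

    def fit(self, X: Sequence[pd.DataFrame], y=None) -> "TssKMeans":
        idx = _row_align(X)
        order = np.argsort(idx.to_numpy())
        genes = idx.to_numpy()[order]
        mat = np.hstack([m.to_numpy()[order] for m in X])
        if self.k > len(genes):
            raise ValueError(f"k={self.k} exceeds number of genes ({len(genes)})")
        col_mean = np.nanmean(mat, axis=0)
        mat = np.where(np.isnan(mat), np.where(np.isnan(col_mean), 0.0,
                                               col_mean)[None, :], mat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=self.k, n_init=self.n_init,
                        random_state=self.seed, max_iter=300, tol=1e-6).fit(mat)
        raw = km.labels_
        nb = X[0].shape[1]
        c0, c1 = int(nb * (0.5 - self.central_frac / 2)), \
            int(np.ceil(nb * (0.5 + self.central_frac / 2)))
        center_signal = km.cluster_centers_[:, c0:c1].mean(axis=1)
        sizes = np.bincount(raw, minlength=self.k)
        occupied = np.flatnonzero(sizes > 0)
        ranked = occupied[np.argsort(-center_signal[occupied], kind="mergesort")]
        mapping = {int(c): f"G{i + 1}" for i, c in enumerate(ranked)}
        self.empty_groups_ = [f"G{i + 1}" for i in range(len(ranked), self.k)]
        self.labels_ = pd.Series([mapping[int(l)] for l in raw], index=genes,
                                 name="group")
        self.centers_ = {mapping[int(c)]: km.cluster_centers_[c] for c in ranked}
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, X: Sequence[pd.DataFrame], y=None) -> pd.Series:
        return self.fit(X).labels_


class ExpressionPatternKMeans(BaseEstimator):
    """Cluster differentially expressed genes by their scaled log-expression
    trajectory across conditions.

    Expression is log-transformed (log2(FPKM + 1)) and standardized per gene
    (zero mean, unit variance across conditions); constant-expression genes
    are excluded with a warning. Cluster labels C1..Ck are ordered by the
    condition pattern of cluster means: descending shift relative to the
    first (reference) condition, comparing the last condition first — so a
    cluster up in both single knockouts and most in the double knockout
    comes first.

    Fitted attributes: ``labels_``, ``centers_`` (standardized trajectories),
    ``excluded_`` (zero-variance gene ids).
    """

    def __init__(self, k: int = 7, seed: int = 0, n_init: int = 10,
                 log_transform: bool = True):
        self.k = k
        self.seed = seed
        self.n_init = n_init
        self.log_transform = log_transform

    def fit(self, X: pd.DataFrame, y=None) -> "ExpressionPatternKMeans":
        X = X.sort_index()
        vals = X.to_numpy(dtype=float)
        if self.log_transform:
            vals = np.log2(vals + 1.0)
        mu = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)
        keep = sd[:, 0] > 0
        self.excluded_ = list(X.index[~keep])
        if self.excluded_:
            warnings.warn(f"{len(self.excluded_)} constant-expression genes excluded")
        z = (vals[keep] - mu[keep]) / sd[keep]
        if self.k > z.shape[0]:
            raise ValueError(f"k={self.k} exceeds number of usable genes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=self.k, n_init=self.n_init,
                        random_state=self.seed, max_iter=300, tol=1e-6).fit(z)
        centers = km.cluster_centers_
        # shift pattern relative to the reference (first) condition,
        # compared from the last condition backwards
        shifts = centers - centers[:, [0]]
        key = np.round(shifts[:, ::-1], 6)
        ranked = sorted(range(self.k), key=lambda c: tuple(-key[c]))
        mapping = {c: f"C{i + 1}" for i, c in enumerate(ranked)}
        self.labels_ = pd.Series([mapping[int(l)] for l in km.labels_],
                                 index=X.index[keep], name="cluster")
        self.centers_ = {mapping[c]: centers[c] for c in range(self.k)}
        self.inertia_ = float(km.inertia_)
        self.conditions_ = list(X.columns)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_


def kmeans_tss_groups(matrices: Sequence[pd.DataFrame], k: int = 5,
                      seed: int = 0) -> pd.Series:
    """Gene -> G1..Gk assignment from concatenated TSS binding profiles."""
    return TssKMeans(k=k, seed=seed).fit_predict(matrices)


def deg_clusters(expression: pd.DataFrame, k: int = 7, seed: int = 0) -> pd.Series:
    """Gene -> C1..Ck assignment from cross-condition expression patterns.

    ``expression`` has one row per differentially expressed gene (gene ids
    as index) and one FPKM column per condition, reference condition first.
    """
    return ExpressionPatternKMeans(k=k, seed=seed).fit_predict(expression)


def group_summaries(assignment: pd.Series,
                    matrices: Optional[Dict[str, pd.DataFrame]] = None,
                    expression: Optional[pd.Series] = None,
                    promoter_density: Optional[pd.Series] = None) -> dict:
    """Per-group mean profiles, expression quartiles, promoter CpG density
    quartiles, and member counts. Empty groups appear with n = 0."""
    groups = sorted(assignment.unique())
    out = {}
    for g in groups:
        members = assignment.index[assignment == g]
        entry: dict = {"n": int(len(members))}
        if len(members) == 0:
            out[g] = entry
            continue
        if matrices:
            entry["mean_profiles"] = {
                name: m.loc[m.index.intersection(members)].mean(axis=0).to_numpy()
                for name, m in matrices.items()}
        if expression is not None:
            e = expression.loc[expression.index.intersection(members)]
            entry["expression_quartiles"] = tuple(
                float(q) for q in np.percentile(e, [25, 50, 75]))
        if promoter_density is not None:
            d = promoter_density.loc[promoter_density.index.intersection(members)]
            entry["density_quartiles"] = tuple(
                float(q) for q in np.percentile(d.dropna(), [25, 50, 75]))
        out[g] = entry
    return out
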