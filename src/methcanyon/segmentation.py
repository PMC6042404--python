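"""Under-methylated region (UMR) and canyon calling.

A two-state binomial HMM is decoded over the per-CpG count sequence
(posterior decoding, low-state threshold 0.5 with ties resolved to the high
state); maximal runs of low-state CpGs become candidate segments, broken
where consecutive CpGs are farther apart than ``max_cpg_gap``. Candidates
whose count-weighted mean methylation exceeds ``max_region_meth`` are
discarded. Length classes: >= ``min_umr_len`` and < ``canyon_len`` is a UMR,
>= ``canyon_len`` a canyon; shorter segments are dropped. A canyon edge is
the 2-kb interval abutting each region boundary.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import SegmentationParams
from .hmm import fit_binomial_hmm
from .tracks import MethylomeTrack

REGION_COLUMNS = ["chrom", "start", "end", "mean_ratio", "n_cpgs", "klass"]


class CanyonSegmenter(BaseEstimator):
    """Sklearn-style estimator: fit the HMM on a methylome, expose regions.

    Parameters mirror :class:`~methcanyon.config.SegmentationParams`.
    Fitted attributes: ``emission_means_`` (low/high state methylation
    probabilities), ``transmat_``, ``candidates_`` (pre-length-filter
    segments) and ``regions_`` (classified UMRs/canyons).
    """

    def __init__(self, max_region_meth: float = 0.10, min_umr_len: int = 1000,
                 canyon_len: int = 3500, edge_flank: int = 2000,
                 max_cpg_gap: int = 2000, init_low_meth: float = 0.05,
                 init_high_meth: float = 0.75, init_stay_prob: float = 0.99,
                 max_iter: int = 50, tol: float = 1e-4,
                 low_posterior_cutoff: float = 0.5):
        self.max_region_meth = max_region_meth
        self.min_umr_len = min_umr_len
        self.canyon_len = canyon_len
        self.edge_flank = edge_flank
        self.max_cpg_gap = max_cpg_gap
        self.init_low_meth = init_low_meth
        self.init_high_meth = init_high_meth
        self.init_stay_prob = init_stay_prob
        self.max_iter = max_iter
        self.tol = tol
        self.low_posterior_cutoff = low_posterior_cutoff

    def _params(self) -> SegmentationParams:
        return SegmentationParams(**{f.name: getattr(self, f.name)
                                     for f in dataclasses.fields(SegmentationParams)})

    def fit(self, X: MethylomeTrack, y=None) -> "CanyonSegmenter":
        params = self._params()  # validates
        chrom_arrays = []
        chrom_names = []
        for chrom in X.chroms:
            sub = X.chrom_data(chrom)
            chrom_names.append(chrom)
            chrom_arrays.append((sub["pos"].to_numpy(),
                                 sub["meth"].to_numpy(),
                                 sub["total"].to_numpy()))
        if sum(len(a[0]) for a in chrom_arrays) < 2:
            warnings.warn("fewer than 2 CpGs: no segmentation performed")
            self.candidates_ = pd.DataFrame(columns=REGION_COLUMNS[:-1])
            self.regions_ = pd.DataFrame(columns=REGION_COLUMNS)
            self.emission_means_ = np.array([np.nan, np.nan])
            return self
        fit = fit_binomial_hmm(
            [(m, t) for _, m, t in chrom_arrays],
            init_means=(params.init_low_meth, params.init_high_meth),
            init_stay=params.init_stay_prob,
            max_iter=params.max_iter, tol=params.tol)
        self.emission_means_ = fit.emission_means
        self.transmat_ = fit.transmat
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.n_iter
        rows = []
        for chrom, (pos, meth, total), gamma in zip(chrom_names, chrom_arrays,
                                                    fit.posteriors):
            low = gamma[:, 0] > params.low_posterior_cutoff  # tie -> high state
            rows.extend(_runs_to_segments(chrom, pos, meth, total, low, params))
        cand = pd.DataFrame(rows, columns=REGION_COLUMNS[:-1])
        cand = cand[cand["mean_ratio"] <= params.max_region_meth]
        self.candidates_ = cand.reset_index(drop=True)
        self.regions_ = classify_regions(self.candidates_, params)
        return self

    def predict(self, X: MethylomeTrack) -> pd.DataFrame:
        """Regions for the methylome the estimator was fitted on (or refit)."""
        if not hasattr(self, "regions_"):
            self.fit(X)
        return self.regions_


def _runs_to_segments(chrom, pos, meth, total, low, params):
    rows = []
    n = len(pos)
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and low[j + 1]
               and pos[j + 1] - pos[j] <= params.max_cpg_gap):
            j += 1
        t_sum = total[i:j + 1].sum()
        mean_ratio = meth[i:j + 1].sum() / t_sum if t_sum > 0 else np.nan
        rows.append((chrom, int(pos[i]), int(pos[j]) + 2,
                     float(mean_ratio), int(j - i + 1)))
        i = j + 1
    return rows


def segment_methylome(track: MethylomeTrack,
                      params: Optional[SegmentationParams] = None) -> pd.DataFrame:
    """Candidate under-methylated segments (before length classification)."""
    params = params or SegmentationParams()
    seg = CanyonSegmenter(**dataclasses.asdict(params)).fit(track)
    return seg.candidates_


def classify_regions(segments: pd.DataFrame,
                     params: Optional[SegmentationParams] = None) -> pd.DataFrame:
    """Apply the length classes: drop < min_umr_len, UMR below canyon_len,
    canyon at or above it."""
    params = params or SegmentationParams()
    df = segments.copy()
    length = df["end"] - df["start"]
    df = df[length >= params.min_umr_len].copy()
    df["klass"] = np.where((df["end"] - df["start"]) >= params.canyon_len,
                           "CANYON", "UMR")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def canyon_edges(region, flank: int = 2000,
                 chrom_size: Optional[int] = None) -> pd.DataFrame:
    """The two edge intervals flanking a region: [start-flank, start) and
    [end, end+flank), truncated at chromosome bounds."""
    start, end = int(region["start"]), int(region["end"])
    chrom = region["chrom"]
    left = (max(0, start - flank), start)
    right = (end, end + flank if chrom_size is None else min(end + flank, chrom_size))
    rows = [(chrom, left[0], left[1], "left"), (chrom, right[0], right[1], "right")]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "side"])
    return df[df["end"] > df["start"]].reset_index(drop=True) if flank > 0 else \
        pd.DataFrame(columns=["chrom", "start", "end", "side"])


def all_canyon_edges(regions: pd.DataFrame, flank: int = 2000,
                     chrom_sizes: Optional[Dict[str, int]] = None) -> pd.DataFrame:
    frames = []
    for idx, r in regions.iterrows():
        size = chrom_sizes.get(r["chrom"]) if chrom_sizes else None
        e = canyon_edges(r, flank=flank, chrom_size=size)
        e["parent"] = idx
        frames.append(e)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "side", "parent"])
    return pd.concat(frames, ignore_index=True)


def regions_to_bed(regions: pd.DataFrame, path) -> None:
    """BED6 with name=klass and score=round(1000*(1-mean_ratio))."""
    out = regions.copy()
    out["score"] = (1000 * (1 - out["mean_ratio"])).round().astype(int)
    from .tracks import write_bed
    write_bed(out, path, name_col="klass", score_col="score")
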