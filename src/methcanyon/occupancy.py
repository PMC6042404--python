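"""ChIP occupancy processing: depth normalization with input subtraction,
spike-in scaling, 1-kb genomic-window statistics with the standard
exclusions (satellite windows, windows without bisulfite or input coverage),
feature-class enrichment, and a signed Poisson differential-occupancy score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import special

from .config import DataIntegrityError
from .tracks import MethylomeTrack, OccupancyTrack

LOG10P_CAP = 300.0
WINDOW = 1000  # bp


@dataclass
class SpikeInCounts:
    """Exogenous (spike-in) chromatin tag counts for one sample."""

    sample: str
    spike_count: int
    reference_count: int

    def __post_init__(self):
        if self.spike_count <= 0 or self.reference_count <= 0:
            raise DataIntegrityError("spike-in tag counts must be positive")


def spike_in_factor(spike: SpikeInCounts) -> float:
    """Scale factor equalizing exogenous tag counts: reference / sample."""
    return spike.reference_count / spike.spike_count


def apply_spike(track: OccupancyTrack, factor: float) -> OccupancyTrack:
    if factor <= 0:
        raise ValueError("spike-in factor must be positive")
    values = {c: v * factor for c, v in track.values.items()}
    out = track.copy_with(values)
    out.total_tags = track.total_tags
    return out


def scale_to_depth(track: OccupancyTrack, target_depth: float) -> OccupancyTrack:
    total = track.total()
    if total <= 0:
        raise ValueError("cannot depth-normalize an empty track")
    f = target_depth / total
    return track.copy_with({c: v * f for c, v in track.values.items()})


def normalize_track(raw: OccupancyTrack, input_track: Optional[OccupancyTrack],
                    target_depth: float = 1e6) -> OccupancyTrack:
    """Depth-normalize ChIP and input to a common tag count, subtract input
    bin-wise, and floor negative values at zero."""
    scaled = scale_to_depth(raw, target_depth)
    if input_track is None:
        return scaled
    if not raw.same_grid(input_track):
        raise DataIntegrityError("ChIP and input tracks are on different bin grids")
    inp = scale_to_depth(input_track, target_depth)
    values = {c: np.maximum(scaled.values[c] - inp.values[c], 0.0)
              for c in scaled.values}
    return scaled.copy_with(values)


# --- 1-kb window statistics -------------------------------------------------

def _interval_tree(df: pd.DataFrame, chrom: str) -> IntervalTree:
    sub = df[df["chrom"] == chrom]
    tree = IntervalTree()
    for s, e in zip(sub["start"], sub["end"]):
        if e > s:
            tree.addi(int(s), int(e))
    return tree


def build_windows(chrom_sizes: Dict[str, int],
                  tracks: Dict[str, OccupancyTrack],
                  satellites: Optional[pd.DataFrame] = None,
                  methylome: Optional[MethylomeTrack] = None,
                  input_track: Optional[OccupancyTrack] = None,
                  cpg_positions: Optional[Dict[str, np.ndarray]] = None,
                  ) -> pd.DataFrame:
    """Tile the genome into 1-kb windows with exclusion flags and statistics.

    Exclusions: any overlap (>= 1 bp) with a satellite interval; no
    bisulfite-covered CpG in the window; zero input signal. Per-window CpG
    density is CpGs per 100 bp; per-track mean signal columns are named
    ``signal_<name>``. ``included`` is True where no exclusion applies.
    """
    frames = []
    for chrom, size in chrom_sizes.items():
        n_win = size // WINDOW
        starts = np.arange(n_win) * WINDOW
        df = pd.DataFrame({"chrom": chrom, "start": starts,
                           "end": starts + WINDOW})
        sat = np.zeros(n_win, dtype=bool)
        if satellites is not None and len(satellites):
            tree = _interval_tree(satellites, chrom)
            sat = np.array([bool(tree.overlap(s, s + WINDOW)) for s in starts])
        df["satellite"] = sat
        no_wgbs = np.zeros(n_win, dtype=bool)
        if methylome is not None:
            sub = methylome.chrom_data(chrom)
            covered = sub.loc[sub["total"] > 0, "pos"].to_numpy()
            counts = (np.searchsorted(covered, starts + WINDOW)
                      - np.searchsorted(covered, starts))
            no_wgbs = counts == 0
        df["no_wgbs"] = no_wgbs
        no_input = np.zeros(n_win, dtype=bool)
        if input_track is not None:
            means = _window_means(input_track, chrom, n_win)
            no_input = ~(means > 0)
        df["no_input"] = no_input
        if cpg_positions is not None and chrom in cpg_positions:
            pos = cpg_positions[chrom]
            counts = (np.searchsorted(pos, starts + WINDOW)
                      - np.searchsorted(pos, starts))
            df["cpg_density"] = counts / (WINDOW / 100.0)
        for name, track in tracks.items():
            df[f"signal_{name}"] = _window_means(track, chrom, n_win)
        frames.append(df)
    windows = pd.concat(frames, ignore_index=True)
    windows["included"] = ~(windows["satellite"] | windows["no_wgbs"]
                            | windows["no_input"])
    return windows


def _window_means(track: OccupancyTrack, chrom: str, n_win: int) -> np.ndarray:
    arr = track.values.get(chrom)
    if arr is None:
        return np.zeros(n_win)
    per = WINDOW // track.bin_width
    if per < 1 or WINDOW % track.bin_width:
        raise DataIntegrityError("bin width must divide the 1-kb window")
    need = n_win * per
    padded = np.pad(arr[:need], (0, max(0, need - len(arr))))
    return padded.reshape(n_win, per).mean(axis=1)


def feature_enrichment(windows: pd.DataFrame, signal_col: str,
                       features: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Relative binding enrichment per feature class.

    A window belongs to a class when its midpoint falls inside one of the
    class intervals (classes may overlap). Enrichment is the mean included-
    window signal in the class over the mean across all included windows;
    also reported on log2 scale. Empty classes are flagged and omitted from
    the ratio columns.
    """
    inc = windows[windows["included"]]
    if len(inc) == 0:
        raise DataIntegrityError("no included windows")
    genome_mean = inc[signal_col].mean()
    mid = ((inc["start"] + inc["end"]) // 2).to_numpy()
    rows = []
    for name, intervals in features.items():
        mask = np.zeros(len(inc), dtype=bool)
        for chrom, sub in intervals.groupby("chrom"):
            cmask = (inc["chrom"] == chrom).to_numpy()
            if not cmask.any():
                continue
            tree = _interval_tree(sub, chrom)
            hits = np.array([bool(tree.overlap(m, m + 1)) for m in mid[cmask]])
            mask[np.flatnonzero(cmask)[hits]] = True
        if mask.sum() == 0:
            rows.append((name, 0, np.nan, np.nan))
            continue
        enr = inc.loc[mask, signal_col].mean() / genome_mean
        rows.append((name, int(mask.sum()), float(enr), float(np.log2(enr))))
    return pd.DataFrame(rows, columns=["feature", "n_windows",
                                       "enrichment", "log2_enrichment"])


def promoter_features(genes: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Strand-aware proximal (TSS +/- 500 bp) and distal (500-3000 bp
    upstream of the TSS) promoter interval classes."""
    plus = genes["strand"] == "+"
    tss = genes["tss"].to_numpy()
    prox = pd.DataFrame({"chrom": genes["chrom"],
                         "start": np.maximum(tss - 500, 0), "end": tss + 500})
    d_start = np.where(plus, tss - 3000, tss + 500)
    d_end = np.where(plus, tss - 500, tss + 3000)
    dist = pd.DataFrame({"chrom": genes["chrom"],
                         "start": np.maximum(d_start, 0), "end": d_end})
    return {"proximal_promoter": prox, "distal_promoter": dist}


# --- differential occupancy -------------------------------------------------

def _poisson_upper_tail_log10(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """|log10 P(X >= x)| for Poisson(lam), continuous in x via the
    regularized incomplete gamma (exact at integer x)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = special.gammainc(np.maximum(x, 1e-300), lam)
        logp = np.log10(p)
    return np.minimum(np.abs(logp), LOG10P_CAP)


def differential_occupancy(track_a: OccupancyTrack,
                           track_ref: OccupancyTrack) -> OccupancyTrack:
    """Signed per-bin differential score sign(A - ref) * |log10 P|.

    P is the upper-tail Poisson probability of the larger bin value given
    the smaller as the mean (a symmetric treatment, so swapping the
    arguments negates every score); equal bins score 0. Both tracks must
    already be normalized to a common depth on the same grid.
    """
    if not track_a.same_grid(track_ref):
        raise DataIntegrityError("differential tracks are on different bin grids")
    values = {}
    for chrom in track_a.values:
        a = track_a.values[chrom]
        r = track_ref.values[chrom]
        hi = np.maximum(a, r)
        lo = np.minimum(a, r)
        score = np.zeros_like(a)
        ne = hi != lo
        mag = np.where(lo[ne] <= 0, LOG10P_CAP,
                       _poisson_upper_tail_log10(hi[ne], lo[ne]))
        score[ne] = np.sign(a[ne] - r[ne]) * mag
        values[chrom] = score
    out = track_a.copy_with(values)
    out.sample = f"{track_a.sample}_vs_{track_ref.sample}"
    return out
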