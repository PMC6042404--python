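"""Meta-profiles and density-stratified binding landscapes.

Covers: scaled-region profiles (region bodies resampled to a fixed number of
bins so every region contributes equal weight regardless of length, plus
fixed-width flanks), strand-oriented TSS matrices, CpG-density-ranked window
profiles with crossing-point estimation, normalized peak coordinates (0 at
the peak centre, +/-1 at the edges), DMR positioning around peaks, and
promoter CpG density over the strand-oriented -1 kb ~ +0.5 kb window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DataIntegrityError
from .tracks import OccupancyTrack


@dataclass
class MetaProfile:
    """Mean signal on a scaled-region axis: flank | body (scaled) | flank."""

    body_bins: int
    flank: int
    flank_bin: int
    values: np.ndarray          # length 2*(flank//flank_bin) + body_bins
    n_regions: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    def segment(self, which: str) -> np.ndarray:
        nf = self.n_flank_bins
        if which == "left_flank":
            return self.values[:nf]
        if which == "body":
            return self.values[nf:nf + self.body_bins]
        if which == "right_flank":
            return self.values[nf + self.body_bins:]
        raise ValueError(which)


def scaled_region_profile(track: OccupancyTrack, regions: pd.DataFrame,
                          body_bins: int = 100, flank: int = 5000,
                          flank_bin: int = 50) -> MetaProfile:
    """Average signal across regions normalized to the same length.

    Region bodies are resampled to ``body_bins`` by linear interpolation of
    the binned signal; flanks are sampled at ``flank_bin`` resolution.
    Positions outside chromosome bounds are missing and excluded from means.
    Regions shorter than one track bin are skipped with a warning count.
    """
    if len(regions) == 0:
        raise DataIntegrityError("no regions to profile")
    nf = flank // flank_bin
    width = 2 * nf + body_bins
    acc = np.zeros(width)
    cnt = np.zeros(width)
    n_used = 0
    for r in regions.itertuples():
        if r.end - r.start < track.bin_width:
            continue
        left = r.start - flank + (np.arange(nf) + 0.5) * flank_bin
        right = r.end + (np.arange(nf) + 0.5) * flank_bin
        body = r.start + (np.arange(body_bins) + 0.5) / body_bins * (r.end - r.start)
        pos = np.concatenate([left, body, right]).astype(np.int64)
        vals = track.value_at(r.chrom, pos)
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        cnt[ok] += 1
        n_used += 1
    if n_used == 0:
        raise DataIntegrityError("all regions shorter than one track bin")
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return MetaProfile(body_bins=body_bins, flank=flank, flank_bin=flank_bin,
                       values=mean, n_regions=n_used)


def tss_matrix(track: OccupancyTrack, genes: pd.DataFrame, flank: int = 5000,
               bin: int = 50) -> pd.DataFrame:
    """Per-gene signal over TSS +/- flank, strand-oriented.

    Rows are indexed by gene id; minus-strand rows are reversed so the
    transcribed direction is rightward. Off-chromosome positions are NaN.
    """
    n_bins = 2 * (flank // bin)
    rows = []
    for g in genes.itertuples():
        if g.strand not in ("+", "-"):
            raise DataIntegrityError(f"{g.gene_id}: unknown strand {g.strand!r}")
        pos = (g.tss - flank + (np.arange(n_bins) + 0.5) * bin).astype(np.int64)
        vals = track.value_at(g.chrom, pos)
        if g.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    return pd.DataFrame(np.vstack(rows), index=list(genes["gene_id"]),
                        columns=[f"bin{i}" for i in range(n_bins)])


@dataclass
class DensityProfile:
    bin_centers: np.ndarray                 # mean CpG density per rank bin
    means: Dict[str, np.ndarray]            # per-track mean signal per bin
    n_per_bin: np.ndarray


def density_profile(windows: pd.DataFrame, signal_cols: Sequence[str],
                    n_bins: int = 20) -> DensityProfile:
    """Included 1-kb windows ranked by CpG density and grouped into
    equal-count bins; per-bin mean signal per track."""
    inc = windows[windows["included"]].sort_values("cpg_density",
                                                   kind="mergesort")
    if len(inc) < n_bins:
        raise DataIntegrityError(f"only {len(inc)} included windows for "
                                 f"{n_bins} density bins")
    idx = np.array_split(np.arange(len(inc)), n_bins)
    centers = np.array([inc["cpg_density"].to_numpy()[i].mean() for i in idx])
    means = {c: np.array([inc[c].to_numpy()[i].mean() for i in idx])
             for c in signal_cols}
    return DensityProfile(bin_centers=centers, means=means,
                          n_per_bin=np.array([len(i) for i in idx]))


def crossing_point(profile: DensityProfile, track_a: str,
                   track_b: str) -> Optional[float]:
    """CpG density at which track A minus track B changes sign, by linear
    interpolation between adjacent bin centres; None when there is no
    sign change."""
    diff = profile.means[track_a] - profile.means[track_b]
    for i in range(len(diff) - 1):
        if diff[i] == 0:
            return float(profile.bin_centers[i])
        if diff[i] * diff[i + 1] < 0:
            x0, x1 = profile.bin_centers[i], profile.bin_centers[i + 1]
            return float(x0 + (x1 - x0) * (-diff[i]) / (diff[i + 1] - diff[i]))
    if diff[-1] == 0:
        return float(profile.bin_centers[-1])
    return None


def to_peak_coordinate(position: float, peak_start: int, peak_end: int) -> float:
    """Signed normalized coordinate: 0 at the peak centre, +/-1 at the peak
    edges, linear beyond (in half-width units)."""
    if peak_end <= peak_start:
        raise DataIntegrityError("peak length must be positive")
    center = (peak_start + peak_end) / 2.0
    half = (peak_end - peak_start) / 2.0
    return (position - center) / half


def from_peak_coordinate(u: float, peak_start: int, peak_end: int) -> float:
    center = (peak_start + peak_end) / 2.0
    half = (peak_end - peak_start) / 2.0
    return center + u * half


def dmr_peak_histogram(dmrs: pd.DataFrame, peaks: pd.DataFrame,
                       u_range: Tuple[float, float] = (-3.0, 3.0),
                       n_bins: int = 60) -> pd.DataFrame:
    """Density histogram of DMR midpoints in normalized peak coordinates.

    Each DMR midpoint maps to the peak with the nearest centre (ties to the
    lower-coordinate peak).
    """
    if len(peaks) == 0:
        raise DataIntegrityError("empty peak set")
    us = []
    for chrom, sub in dmrs.groupby("chrom", sort=False):
        p = peaks[peaks["chrom"] == chrom].sort_values("start")
        if len(p) == 0:
            continue
        centers = ((p["start"] + p["end"]) / 2.0).to_numpy()
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        mids = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        # nearest centre; searchsorted then compare the two neighbours,
        # strict < keeps ties on the lower-coordinate peak
        j = np.searchsorted(centers, mids)
        j = np.clip(j, 1, len(centers) - 1) if len(centers) > 1 else np.zeros(len(mids), int)
        left = np.clip(j - 1, 0, len(centers) - 1)
        pick = np.where(np.abs(mids - centers[left])
                        <= np.abs(centers[np.clip(j, 0, len(centers) - 1)] - mids),
                        left, j)
        for m, k in zip(mids, pick):
            us.append(to_peak_coordinate(m, starts[k], ends[k]))
    edges = np.linspace(u_range[0], u_range[1], n_bins + 1)
    counts, _ = np.histogram(us, bins=edges)
    width = edges[1] - edges[0]
    dens = counts / max(1, len(us)) / width
    return pd.DataFrame({"u_left": edges[:-1], "u_right": edges[1:],
                         "count": counts, "density": dens})


def tss_associated_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                         max_dist: int = 1000) -> pd.DataFrame:
    """Peaks whose centre lies within ``max_dist`` of any TSS."""
    keep = []
    for chrom, sub in peaks.groupby("chrom", sort=False):
        tss = np.sort(genes.loc[genes["chrom"] == chrom, "tss"].to_numpy())
        if len(tss) == 0:
            continue
        centers = ((sub["start"] + sub["end"]) / 2.0).to_numpy()
        j = np.clip(np.searchsorted(tss, centers), 1, len(tss) - 1) \
            if len(tss) > 1 else np.zeros(len(centers), int)
        near = np.minimum(np.abs(centers - tss[j - 1 if len(tss) > 1 else 0]),
                          np.abs(tss[j] - centers))
        keep.append(sub[near <= max_dist])
    if not keep:
        return peaks.iloc[0:0]
    return pd.concat(keep).sort_values(["chrom", "start"]).reset_index(drop=True)


def promoter_cpg_density(genes: pd.DataFrame,
                         cpg_positions: Dict[str, np.ndarray],
                         chrom_sizes: Optional[Dict[str, int]] = None,
                         upstream: int = 1000, downstream: int = 500
                         ) -> pd.Series:
    """CpG density (per 100 bp) in the strand-oriented promoter window
    [TSS - upstream, TSS + downstream); windows off the chromosome are
    truncated and the density uses the truncated length."""
    out = {}
    for g in genes.itertuples():
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        elif g.strand == "-":
            lo, hi = g.tss - downstream, g.tss + upstream
        else:
            raise DataIntegrityError(f"{g.gene_id}: unknown strand {g.strand!r}")
        lo = max(0, lo)
        if chrom_sizes is not None:
            hi = min(hi, chrom_sizes[g.chrom])
        pos = cpg_positions[g.chrom]
        n = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
        out[g.gene_id] = 100.0 * n / (hi - lo) if hi > lo else np.nan
    return pd.Series(out, name="promoter_cpg_density")
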