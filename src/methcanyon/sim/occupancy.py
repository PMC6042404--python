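"""Chromatin occupancy simulation.

The generating model encodes the binding relationships the package is built
to measure: TET1 signal is a saturating (Hill) function of local CpG
density, DNMT3A1 carries the complementary density response plus Gaussian
bumps centred ``edge_peak_offset`` bp outside planted canyon boundaries, and
per-gene TSS bumps follow five binding archetypes (G1-G5). With equal
baselines and amplitudes the two density responses cross exactly at
``crossing_density``. Knockout conditions: a protein is flat baseline in its
own knockout; Tet1KO multiplies the DNMT3A1 bumps over former TET1 peaks in
height and width; Dnmt3aKO modestly raises TET1 peak height.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from ..config import SimulationConfig, ConfigurationError, CONDITIONS, PROTEINS
from ..occupancy import SpikeInCounts
from ..tracks import OccupancyTrack
from .genome import Genome

_HILL = 4.0
_DNMT3AKO_TET1_GAIN = 1.2   # modest TET1 height gain after Dnmt3a loss
_PEAK_RESIDUAL_AMP = 1.0    # WT DNMT3A1 residual bump at TET1 peaks

# TSS bump amplitude per binding archetype; offsets: DNMT3A1/3A2 "distal"
# bumps sit 1.5 kb upstream of the TSS, others are centred on it.
_TSS_BUMPS: Dict[str, Dict[str, float]] = {
    "DNMT3A1": {"G1": 8.0, "G4": 3.0},
    "DNMT3A2": {"G1": 5.0, "G3": 7.0, "G4": 2.5},
    "TET1": {"G2": 8.0, "G3": 2.5, "G4": 0.8},
    "H3K4me3": {"G2": 8.0, "G3": 2.5, "G4": 0.8},
    "H3K27me3": {"G1": 5.0, "G3": 4.0, "G4": 1.2},
}
_DISTAL = {"DNMT3A1": True, "DNMT3A2": True}
_BODY_PLATEAU: Dict[str, Dict[str, float]] = {
    "DNMT3B1": {"G2": 8.0, "G4": 2.0},
    "DNMT3A2": {"G2": 4.0},
}
_DENSITY_WEIGHT = {"DNMT3A1": 1.0, "DNMT3A2": 0.7, "DNMT3B1": 0.5}


def _local_density(genome: Genome, chrom: str, n_bins: int, bin_width: int) -> np.ndarray:
    """CpGs per 100 bp in the tiled 1-kb window containing each bin — the
    same local-density definition the window-level analysis measures."""
    pos = genome.cpg_positions[chrom]
    centers = (np.arange(n_bins) + 0.5) * bin_width
    win = (centers // 1000).astype(np.int64)
    lo = np.searchsorted(pos, win * 1000)
    hi = np.searchsorted(pos, (win + 1) * 1000)
    return (hi - lo) / 10.0


def _hill(d: np.ndarray, d0: float, activation: float) -> np.ndarray:
    f = d ** _HILL / (d ** _HILL + d0 ** _HILL)
    return np.where(d < activation, 0.0, f)


def _add_gauss(arr: np.ndarray, bin_width: int, center: float, amp: float,
               sigma: float) -> None:
    lo = max(0, int((center - 4 * sigma) // bin_width))
    hi = min(len(arr), int((center + 4 * sigma) // bin_width) + 1)
    if hi <= lo:
        return
    x = (np.arange(lo, hi) + 0.5) * bin_width
    arr[lo:hi] += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _add_plateau(arr: np.ndarray, bin_width: int, start: float, end: float,
                 amp: float) -> None:
    lo = max(0, int(start // bin_width))
    hi = min(len(arr), int(end // bin_width) + 1)
    arr[lo:hi] += amp


def tet1_peaks(genome: Genome) -> pd.DataFrame:
    """Wild-type TET1 peak intervals: planted baseline regions (TET1 binds
    throughout canyons) plus promoters of TET1-bound gene archetypes."""
    base = genome.regions[~genome.regions["ko_only"]]
    rows = [(r.chrom, int(r.start), int(r.end), "region_peak")
            for r in base.itertuples()]
    amp = _TSS_BUMPS["TET1"]
    for g in genome.genes.itertuples():
        if amp.get(g.group, 0.0) >= 1.0:
            rows.append((g.chrom, max(0, g.tss - 1000),
                         min(genome.chrom_sizes[g.chrom], g.tss + 1000), "tss_peak"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_occupancy(genome: Genome, protein: str, config: SimulationConfig,
                       depth_factor: float = 1.0,
                       ) -> Tuple[OccupancyTrack, pd.DataFrame, SpikeInCounts]:
    """Simulate a binned occupancy track for one protein or mark.

    Returns ``(track, peaks, spike_counts)``. ``depth_factor`` emulates
    sequencing-depth differences: both the track and the spike-in tag count
    scale with it, so spike-in normalization can undo it exactly.
    """
    if protein not in PROTEINS:
        raise ConfigurationError(
            f"protein: unknown label {protein!r}; allowed: {PROTEINS}")
    cond = config.condition
    bw = config.bin_width
    b, A = config.occ_baseline, config.occ_amplitude
    peaks = tet1_peaks(genome)
    absent = ((protein == "TET1" and cond in ("Tet1KO", "DKO"))
              or (protein in ("DNMT3A1", "DNMT3A2") and cond in ("Dnmt3aKO", "DKO")))
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.seed, 202, PROTEINS.index(protein), CONDITIONS.index(cond)]))

    values: Dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        n_bins = (size + bw - 1) // bw
        sig = np.full(n_bins, b, dtype=float)
        if protein != "input" and not absent:
            d = _local_density(genome, chrom, n_bins, bw)
            f = _hill(d, config.crossing_density, config.tet1_activation_density)
            genes = genome.genes[genome.genes["chrom"] == chrom]
            regs = genome.regions[(genome.regions["chrom"] == chrom)
                                  & (~genome.regions["ko_only"])]
            if protein == "TET1":
                sig = sig + A * f
                if cond in ("Dnmt3aKO",):
                    # height-only gain inside former peaks
                    for p in peaks[peaks["chrom"] == chrom].itertuples():
                        lo, hi = int(p.start // bw), int(p.end // bw)
                        sig[lo:hi] = b + (sig[lo:hi] - b) * _DNMT3AKO_TET1_GAIN
            else:
                w = _DENSITY_WEIGHT.get(protein, 0.0)
                sig = sig + w * A * (1.0 - f)
                if protein in ("DNMT3A1", "DNMT3A2"):
                    edge_amp = (config.edge_peak_amplitude
                                if protein == "DNMT3A1"
                                else 0.4 * config.edge_peak_amplitude)
                    for r in regs[regs["klass"] == "CANYON"].itertuples():
                        _add_gauss(sig, bw, r.start - config.edge_peak_offset,
                                   edge_amp, config.edge_peak_sigma)
                        _add_gauss(sig, bw, r.end + config.edge_peak_offset,
                                   edge_amp, config.edge_peak_sigma)
                if protein == "DNMT3A1":
                    h_mult, w_mult = 1.0, 1.0
                    if cond in ("Tet1KO", "DKO"):
                        h_mult = config.tet1ko_height_multiplier
                        w_mult = config.tet1ko_width_multiplier
                    for p in peaks[peaks["chrom"] == chrom].itertuples():
                        center = (p.start + p.end) / 2.0
                        half = (p.end - p.start) / 2.0
                        _add_gauss(sig, bw, center, _PEAK_RESIDUAL_AMP * h_mult,
                                   (half / 2.0) * w_mult)
            # archetype bumps around TSSs
            bump = _TSS_BUMPS.get(protein, {})
            plateau = _BODY_PLATEAU.get(protein, {})
            for g in genes.itertuples():
                jitter = float(np.exp(rng.normal(0.0, 0.15))) if config.occ_noise > 0 else 1.0
                amp = bump.get(g.group, 0.0)
                if amp > 0:
                    if _DISTAL.get(protein, False):
                        center = g.tss - 1500 if g.strand == "+" else g.tss + 1500
                        _add_gauss(sig, bw, center, amp * jitter, 700.0)
                    else:
                        _add_gauss(sig, bw, g.tss, amp * jitter, 500.0)
                pamp = plateau.get(g.group, 0.0)
                if pamp > 0:
                    body = ((g.tss + 500, g.end) if g.strand == "+"
                            else (g.start, g.tss - 500))
                    _add_plateau(sig, bw, body[0], body[1], pamp * jitter)
            if protein in ("DNMT3A1", "DNMT3A2", "DNMT3B1") and cond not in ("Tet1KO", "DKO"):
                # DNMTs are depleted inside under-methylated region bodies
                for r in regs.itertuples():
                    lo, hi = int(r.start // bw), int(r.end // bw)
                    sig[lo:hi] = b + (sig[lo:hi] - b) * 0.1
        if config.occ_noise > 0:
            sig = sig * rng.lognormal(0.0, config.occ_noise, size=len(sig))
        values[chrom] = np.maximum(sig * depth_factor, 0.0)

    track = OccupancyTrack(values=values, bin_width=bw,
                           sample=f"{protein}_{cond}", condition=cond)
    spike = SpikeInCounts(sample=track.sample,
                          spike_count=int(round(config.spike_base * depth_factor)),
                          reference_count=config.spike_base)
    return track, peaks, spike


def sample_read_starts(track: OccupancyTrack, n_reads: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw read-start coordinates proportional to the binned signal —
    the read-level entry point matching a generated track."""
    chroms, weights = [], []
    for chrom, arr in track.values.items():
        chroms.append(chrom)
        weights.append(arr.sum())
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    frames = []
    for chrom, k in zip(chroms, counts):
        arr = track.values[chrom]
        p = arr / arr.sum()
        bins = rng.choice(len(arr), size=k, p=p)
        offs = rng.integers(0, track.bin_width, size=k)
        starts = np.sort(bins * track.bin_width + offs)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts}))
    return pd.concat(frames, ignore_index=True)
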