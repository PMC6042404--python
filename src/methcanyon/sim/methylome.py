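"""Methylome simulation: per-CpG counts from a beta-binomial emission model
over a piecewise mean-methylation field.

Wild type: high background methylation with planted low-methylation regions.
Dnmt3aKO / DKO: background lowered by ``ko_global_meth_shift``, planted
regions extended by ``ko_region_extension`` on each side, and KO-only planted
regions become under-methylated. Tet1KO / DKO: 2-kb flanks of planted regions
gain ``tet1ko_flank_meth_gain`` methylation (hypermethylation where TET1
formerly bounded the region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from ..config import SimulationConfig, ConfigurationError
from ..tracks import MethylomeTrack
from .genome import Genome

_FLANK = 2000  # bp; width of the hypermethylation-prone flank in Tet1KO


@dataclass
class MethylomeGroundTruth:
    """Planted truth for one simulated methylome."""

    regions: pd.DataFrame            # active regions, post-extension coords + klass
    mu: Dict[str, np.ndarray]        # true per-CpG methylation mean, aligned to CpGs
    background_mean: float
    condition: str


def active_regions(genome: Genome, config: SimulationConfig) -> pd.DataFrame:
    """Planted regions under-methylated in this condition, with KO extension
    applied and the length class recomputed from the final extent."""
    hypo_ko = config.condition in ("Dnmt3aKO", "DKO")
    reg = genome.regions
    reg = reg[(~reg["ko_only"]) | hypo_ko].copy()
    if hypo_ko and config.ko_region_extension:
        ext = int(config.ko_region_extension)
        reg["start"] = reg["start"] - ext
        reg["end"] = reg["end"] + ext
    reg["start"] = reg["start"].clip(lower=0)
    for chrom, size in genome.chrom_sizes.items():
        m = reg["chrom"] == chrom
        reg.loc[m, "end"] = reg.loc[m, "end"].clip(upper=size)
    length = reg["end"] - reg["start"]
    reg["klass"] = np.where(length >= 3500, "CANYON", "UMR")
    return reg.reset_index(drop=True)


def _mean_field(genome: Genome, config: SimulationConfig,
                regions: pd.DataFrame) -> Dict[str, np.ndarray]:
    bg = config.background_meth_mean
    if config.condition in ("Dnmt3aKO", "DKO"):
        bg = float(np.clip(bg + config.ko_global_meth_shift, 0.0, 1.0))
    mu: Dict[str, np.ndarray] = {}
    for chrom, pos in genome.cpg_positions.items():
        m = np.full(len(pos), bg)
        sub = regions[regions["chrom"] == chrom]
        if config.condition in ("Tet1KO", "DKO") and config.tet1ko_flank_meth_gain:
            hyper = float(np.clip(bg + config.tet1ko_flank_meth_gain, 0.0, 0.98))
            for _, r in sub.iterrows():
                lo = np.searchsorted(pos, r.start - _FLANK)
                hi = np.searchsorted(pos, r.start)
                m[lo:hi] = hyper
                lo = np.searchsorted(pos, r.end)
                hi = np.searchsorted(pos, r.end + _FLANK)
                m[lo:hi] = hyper
        for _, r in sub.iterrows():
            lo = np.searchsorted(pos, r.start)
            hi = np.searchsorted(pos, r.end)
            m[lo:hi] = config.umr_meth_mean
        mu[chrom] = m
    return mu


def _beta_binomial(rng: np.random.Generator, total: np.ndarray, mu: np.ndarray,
                   dispersion: float) -> np.ndarray:
    """Methylated counts; dispersion 0 is the plain binomial limit."""
    if dispersion <= 0:
        return rng.binomial(total, mu)
    conc = (1.0 - dispersion) / dispersion
    a = np.clip(mu * conc, 1e-9, None)
    b = np.clip((1.0 - mu) * conc, 1e-9, None)
    p = rng.beta(a, b)
    # degenerate means stay degenerate
    p = np.where(mu <= 0.0, 0.0, np.where(mu >= 1.0, 1.0, p))
    return rng.binomial(total, p)


def simulate_methylome(genome: Genome, config: SimulationConfig):
    """Simulate per-CpG methylation calls.

    Returns ``(MethylomeTrack, MethylomeGroundTruth)``. Coverage is Poisson
    around ``coverage_mean``; methylated counts are beta-binomial around the
    condition-dependent mean field.
    """
    if config.coverage_mean <= 0:
        raise ConfigurationError("coverage_mean: must be positive")
    regions = active_regions(genome, config)
    mu = _mean_field(genome, config, regions)
    root = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    streams = root.spawn(len(genome.chroms))
    frames = []
    for rng, chrom in zip(streams, genome.chroms):
        pos = genome.cpg_positions[chrom]
        total = rng.poisson(config.coverage_mean, size=len(pos))
        meth = _beta_binomial(rng, total, mu[chrom], config.meth_dispersion)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "meth": meth, "total": total}))
    track = MethylomeTrack(pd.concat(frames, ignore_index=True),
                           sample=f"{config.condition}_methylome",
                           condition=config.condition)
    truth = MethylomeGroundTruth(regions=regions, mu=mu,
                                 background_mean=(config.background_meth_mean
                                                  + (config.ko_global_meth_shift
                                                     if config.condition in ("Dnmt3aKO", "DKO")
                                                     else 0.0)),
                                 condition=config.condition)
    return track, truth
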