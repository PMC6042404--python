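"""Genome-level ground truth: chromosome sizes, a CpG density field, planted
under-methylated regions, gene annotations and satellite windows.

CpG placement is an inhomogeneous Bernoulli-per-bp process with a piecewise
density field: each 1-kb block draws a background rate from a lognormal
around ``background_cpg_rate`` (giving a continuous density gradient across
windows), and island intervals — planted regions plus a fraction of gene
promoters — override the block rate with ``island_cpg_rate``. All
randomness flows from one seeded generator with sub-streams per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..config import SimulationConfig, ConfigurationError

GROUPS = ("G1", "G2", "G3", "G4", "G5")
DEG_CLUSTERS = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

_BLOCK = 1000  # bp; resolution of the background density field


@dataclass
class Genome:
    """Simulated genome with planted annotations (all coordinates 0-based)."""

    chrom_sizes: Dict[str, int]
    cpg_positions: Dict[str, np.ndarray]
    regions: pd.DataFrame       # chrom, start, end, klass, ko_only
    genes: pd.DataFrame         # gene_id, chrom, start, end, tss, strand, group, deg_cluster
    satellites: pd.DataFrame    # chrom, start, end
    enhancers: pd.DataFrame     # chrom, start, end
    density_rate: Dict[str, np.ndarray] = field(default_factory=dict)  # per-kb CpG/100bp

    @property
    def chroms(self) -> List[str]:
        return list(self.chrom_sizes)

    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))


def _stratified_positions(rng: np.random.Generator, length: int, n: int,
                          margin: int) -> np.ndarray:
    """n positions, one per equal slot of [0, length), jittered within the slot."""
    if n == 0:
        return np.array([], dtype=np.int64)
    slot = length // n
    if slot <= 2 * margin:
        raise ConfigurationError(
            f"genome_length: too short to place {n} objects with margin {margin}")
    offs = rng.integers(margin, slot - margin, size=n)
    return (np.arange(n) * slot + offs).astype(np.int64)


def _plant_regions(rng: np.random.Generator, chrom: str, length: int,
                   cfg: SimulationConfig,
                   tss: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Non-overlapping planted regions: baseline UMRs/canyons plus the extra
    regions that only lose methylation in Dnmt3a-knockout conditions.
    Regions are kept clear of gene TSS neighbourhoods so that promoter
    binding profiles and canyon-edge structure stay separable signals."""
    n_extra_umr = int(round(cfg.n_umrs * (cfg.ko_umr_multiplier - 1.0)))
    n_extra_can = int(round(cfg.n_canyons * (cfg.ko_canyon_multiplier - 1.0)))
    plan = (
        [("CANYON", False)] * cfg.n_canyons
        + [("UMR", False)] * cfg.n_umrs
        + [("CANYON", True)] * n_extra_can
        + [("UMR", True)] * n_extra_umr
    )
    n = len(plan)
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "klass", "ko_only"])
    # margin leaves room for KO extension, edge flanks and edge occupancy bumps
    margin = cfg.ko_region_extension + 2000 + cfg.edge_peak_offset + 3000
    slot_margin = margin + cfg.canyon_length_range[1] // 2
    slot = length // n
    if slot <= 2 * slot_margin:
        raise ConfigurationError(
            f"genome_length: too short to place {n} regions with margin {slot_margin}")
    tss = np.sort(tss) if tss is not None and len(tss) else np.array([], dtype=np.int64)
    order = rng.permutation(n)
    rows = []
    for slot_i, idx in enumerate(order):
        klass, ko_only = plan[idx]
        lo, hi = (cfg.canyon_length_range if klass == "CANYON" else cfg.umr_length_range)
        size = int(rng.integers(lo, hi))
        base = slot_i * slot
        start = base + slot // 2 - size // 2  # fallback if no clear draw found
        for _ in range(30):
            center = base + int(rng.integers(slot_margin, slot - slot_margin))
            cand = center - size // 2
            # keep the region (plus edge-bump reach) clear of TSS windows
            lo_b, hi_b = cand - 8000, cand + size + 8000
            j = np.searchsorted(tss, lo_b)
            if j >= len(tss) or tss[j] >= hi_b:
                start = cand
                break
        rows.append((chrom, start, start + size, klass, ko_only))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "klass", "ko_only"])
    return df.sort_values("start").reset_index(drop=True)


def _plant_genes(rng: np.random.Generator, chrom: str, length: int,
                 cfg: SimulationConfig, start_index: int) -> pd.DataFrame:
    n = cfg.n_genes
    slot = length // max(n, 1)
    tss = _stratified_positions(rng, length, n, margin=max(1, slot // 3))
    strands = rng.choice(["+", "-"], size=n)
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1], size=n)
    groups = np.array(GROUPS)[np.arange(n) % len(GROUPS)]
    rng.shuffle(groups)
    deg = np.array(["none"] * n, dtype=object)
    deg_idx = rng.choice(n, size=min(cfg.n_deg, n), replace=False)
    deg[deg_idx] = np.array(DEG_CLUSTERS)[np.arange(len(deg_idx)) % len(DEG_CLUSTERS)]
    rows = []
    for i in range(n):
        if strands[i] == "+":
            start, end = int(tss[i]), min(int(tss[i] + lengths[i]), length)
        else:
            start, end = max(int(tss[i] - lengths[i]), 0), int(tss[i])
        rows.append((f"gene{start_index + i:05d}", chrom, start, end,
                     int(tss[i]), strands[i], groups[i], deg[i]))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "tss", "strand", "group", "deg_cluster"])


def _sample_cpgs(rng: np.random.Generator, length: int,
                 block_rates: np.ndarray,
                 islands: List[Tuple[int, int]],
                 island_rate: float) -> np.ndarray:
    """Draw CpG positions segment-by-segment from the piecewise rate field."""
    # breakpoints: kb grid plus island boundaries
    bounds = set(range(0, length + 1, _BLOCK))
    bounds.add(length)
    for s, e in islands:
        bounds.add(max(0, s))
        bounds.add(min(length, e))
    bounds = sorted(bounds)
    starts = np.array([s for s, e in islands], dtype=np.int64)
    ends = np.array([e for s, e in islands], dtype=np.int64)
    positions: List[np.ndarray] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg_len = e - s
        if seg_len <= 0:
            continue
        mid = (s + e) // 2
        in_island = bool(np.any((starts <= mid) & (mid < ends)))
        rate = island_rate if in_island else block_rates[min(s // _BLOCK,
                                                             len(block_rates) - 1)]
        p = min(rate / 100.0, 0.5)
        k = rng.binomial(seg_len, p)
        if k:
            pos = rng.choice(seg_len, size=k, replace=False) + s
            positions.append(np.sort(pos))
    if not positions:
        return np.array([], dtype=np.int64)
    return np.concatenate(positions).astype(np.int64)


def simulate_genome(config: SimulationConfig) -> Genome:
    """Generate chromosome sizes, CpG positions, planted regions, genes,
    satellite 1-kb windows and enhancer intervals.

    Deterministic for a fixed config (``config.seed`` drives everything;
    per-chromosome sub-streams keep chromosomes independent).
    """
    root = np.random.default_rng(config.seed)
    streams = root.spawn(config.n_chroms)
    chrom_sizes, cpg_positions, density = {}, {}, {}
    regions, genes, sats, enhs = [], [], [], []
    for ci in range(config.n_chroms):
        rng = streams[ci]
        chrom = f"chr{ci + 1}"
        length = config.genome_length
        chrom_sizes[chrom] = length

        gen = _plant_genes(rng, chrom, length, config, start_index=ci * config.n_genes)
        reg = _plant_regions(rng, chrom, length, config,
                             tss=gen["tss"].to_numpy())

        # islands: every planted region, plus gene promoters. TET1-bound
        # archetypes (G2, G3) are the CpG-dense promoter classes; other
        # groups are island-positive at a low background fraction.
        islands = [(int(s), int(e)) for s, e in zip(reg["start"], reg["end"])]
        dense_group = gen["group"].isin(["G2", "G3"]).to_numpy()
        promo = dense_group | (rng.random(len(gen))
                               < 0.2 * config.promoter_island_fraction)
        for _, g in gen[promo].iterrows():
            islands.append((max(0, g.tss - 1000), min(length, g.tss + 1000)))

        n_blocks = (length + _BLOCK - 1) // _BLOCK
        block_rates = np.exp(rng.normal(np.log(config.background_cpg_rate),
                                        config.density_log_sigma, size=n_blocks))
        block_rates = np.clip(block_rates, 0.1, config.island_cpg_rate)
        # promoters have a defined CpG environment: hold the density field at
        # the background rate within +/- 5 kb of each TSS (islands override)
        for t in gen["tss"]:
            b0 = max(0, (t - 5000) // _BLOCK)
            b1 = min(n_blocks, (t + 5000) // _BLOCK + 1)
            block_rates[b0:b1] = config.background_cpg_rate
        if config.island_cpg_rate == config.background_cpg_rate:
            # degenerate request: a statistically uniform density field
            block_rates[:] = config.background_cpg_rate
        cpg_positions[chrom] = _sample_cpgs(rng, length, block_rates, islands,
                                            config.island_cpg_rate)
        density[chrom] = block_rates

        n_sat = int(config.satellite_fraction * (length // _BLOCK))
        sat_idx = rng.choice(length // _BLOCK, size=n_sat, replace=False)
        sats.append(pd.DataFrame({"chrom": chrom, "start": sat_idx * _BLOCK,
                                  "end": (sat_idx + 1) * _BLOCK}))
        n_enh = max(1, config.n_genes // 4)
        enh_start = rng.integers(0, length - 500, size=n_enh)
        enhs.append(pd.DataFrame({"chrom": chrom, "start": np.sort(enh_start),
                                  "end": np.sort(enh_start) + 500}))
        regions.append(reg)
        genes.append(gen)

    genome = Genome(
        chrom_sizes=chrom_sizes,
        cpg_positions=cpg_positions,
        regions=pd.concat(regions, ignore_index=True),
        genes=pd.concat(genes, ignore_index=True),
        satellites=pd.concat(sats, ignore_index=True),
        enhancers=pd.concat(enhs, ignore_index=True),
        density_rate=density,
    )
    _check_genome(genome)
    return genome


def _check_genome(genome: Genome) -> None:
    for chrom, pos in genome.cpg_positions.items():
        if len(pos) and (np.diff(pos) <= 0).any():
            raise AssertionError(f"{chrom}: CpG positions not strictly increasing")
    for _, r in genome.regions.iterrows():
        size = genome.chrom_sizes[r.chrom]
        if not (0 <= r.start < r.end <= size):
            raise AssertionError("planted region outside chromosome bounds")
    # planted regions must not overlap one another
    for chrom, sub in genome.regions.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise AssertionError("planted regions overlap")
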