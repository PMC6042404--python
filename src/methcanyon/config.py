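"""Parameter containers shared across the pipeline.

All parameter blocks are plain dataclasses with eager validation so that a
bad configuration fails at construction time, naming the offending field,
rather than deep inside a simulation or segmentation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

CONDITIONS = ("WT", "Dnmt3aKO", "Tet1KO", "DKO")

PROTEINS = ("TET1", "DNMT3A1", "DNMT3A2", "DNMT3B1", "H3K4me3", "H3K27me3", "input")


class ConfigurationError(ValueError):
    """Raised when a parameter block violates its invariants."""


class DataIntegrityError(ValueError):
    """Raised when input data violate a structural invariant (e.g. meth > total)."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass
class SimulationConfig:
    """Ground-truth generator settings.

    The defaults describe the study system being emulated: a mouse-ESC-like
    methylome with ~75% background CpG methylation, planted under-methylated
    regions in the UMR (1-3.5 kb) and canyon (>= 3.5 kb) length classes,
    ~30x WGBS coverage, and chromatin tracks in which TET1 binding rises
    with local CpG density while DNMT3A1 peaks at canyon edges. Knockout
    conditions apply the corresponding directional effects.
    """

    genome_length: int = 10_000_000        # bp per chromosome
    n_chroms: int = 1
    background_cpg_rate: float = 1.0       # CpGs per 100 bp, genome background
    island_cpg_rate: float = 8.0           # CpGs per 100 bp inside CpG islands
    density_log_sigma: float = 0.5         # lognormal spread of per-kb background density
    n_canyons: int = 15
    n_umrs: int = 50
    canyon_length_range: Tuple[int, int] = (3500, 10000)
    umr_length_range: Tuple[int, int] = (1000, 3500)
    background_meth_mean: float = 0.75
    umr_meth_mean: float = 0.03
    meth_dispersion: float = 0.02          # beta-binomial dispersion; 0 => binomial
    coverage_mean: float = 30.0            # reads per CpG
    condition: str = "WT"

    # per-condition effect sizes
    ko_global_meth_shift: float = -0.15    # Dnmt3aKO / DKO background hypomethylation
    ko_region_extension: int = 500         # bp added to each side of planted regions
    ko_umr_multiplier: float = 2.0         # Dnmt3aKO plants (mult-1)*n_umrs extra UMRs
    ko_canyon_multiplier: float = 4.0      # Dnmt3aKO plants (mult-1)*n_canyons extra canyons
    tet1ko_flank_meth_gain: float = 0.15   # hypermethylation in region flanks (Tet1KO/DKO)
    tet1ko_height_multiplier: float = 2.0  # DNMT3A1 gain over former TET1 peaks
    tet1ko_width_multiplier: float = 2.0

    # occupancy generator
    bin_width: int = 50                    # bp per occupancy bin
    crossing_density: float = 1.5          # CpG/100bp where TET1 and DNMT3A1 cross
    tet1_activation_density: float = 0.5   # CpG/100bp below which TET1 stays at baseline
    occ_baseline: float = 1.0
    occ_amplitude: float = 4.0
    edge_peak_amplitude: float = 6.0       # DNMT3A1 bump at canyon edges
    edge_peak_offset: int = 1000           # bump centre, bp outside the region boundary
    edge_peak_sigma: float = 800.0
    occ_noise: float = 0.1                 # multiplicative noise sd on occupancy bins
    spike_base: int = 100_000              # spike-in tags at depth factor 1.0

    # annotation generator
    n_genes: int = 300
    n_deg: int = 210                       # genes given one of the 7 expression archetypes
    gene_length_range: Tuple[int, int] = (2000, 20000)
    min_gene_spacing: int = 20000
    satellite_fraction: float = 0.02       # fraction of 1-kb windows flagged satellite
    promoter_island_fraction: float = 0.5  # fraction of gene promoters given island density

    # expression generator
    deg_log2_effect: float = 2.0
    expr_noise_sd: float = 0.15
    expr_baseline_mean: float = 3.0
    expr_baseline_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.genome_length > 0, "genome_length", "must be positive")
        _require(self.n_chroms > 0, "n_chroms", "must be positive")
        _require(self.background_cpg_rate > 0, "background_cpg_rate", "must be positive")
        _require(self.island_cpg_rate > 0, "island_cpg_rate", "must be positive")
        lo, hi = self.umr_length_range
        _require(1000 <= lo < hi <= 3500, "umr_length_range", "must lie within [1000, 3500)")
        clo, chi = self.canyon_length_range
        _require(clo >= 3500 and clo < chi, "canyon_length_range", "must start at >= 3500")
        for name in ("background_meth_mean", "umr_meth_mean", "meth_dispersion",
                     "tet1ko_flank_meth_gain", "satellite_fraction",
                     "promoter_island_fraction"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be a fraction in [0, 1]")
        _require(self.coverage_mean > 0, "coverage_mean", "must be positive")
        _require(self.condition in CONDITIONS, "condition",
                 f"must be one of {CONDITIONS}")
        _require(self.n_genes >= self.n_deg, "n_deg", "cannot exceed n_genes")
        _require(self.bin_width > 0, "bin_width", "must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SegmentationParams:
    """Under-methylated region caller settings.

    Regions are runs of low-methylation-state CpGs from a two-state HMM,
    kept when their mean methylation ratio is at most ``max_region_meth``.
    Length classes: ``[min_umr_len, canyon_len)`` is a UMR, ``>= canyon_len``
    a canyon; shorter candidates are dropped.
    """

    max_region_meth: float = 0.10
    min_umr_len: int = 1000
    canyon_len: int = 3500
    edge_flank: int = 2000
    max_cpg_gap: int = 2000
    # HMM hyperparameters
    init_low_meth: float = 0.05
    init_high_meth: float = 0.75
    init_stay_prob: float = 0.99
    max_iter: int = 50
    tol: float = 1e-4
    low_posterior_cutoff: float = 0.5

    def __post_init__(self) -> None:
        _require(0.0 < self.max_region_meth < 1.0, "max_region_meth",
                 "must be in (0, 1)")
        _require(self.min_umr_len < self.canyon_len, "min_umr_len",
                 "must be smaller than canyon_len")
        _require(self.edge_flank >= 0, "edge_flank", "must be non-negative")
        _require(0 < self.init_low_meth < self.init_high_meth < 1,
                 "init_low_meth", "state emission means must be ordered in (0,1)")


@dataclass
class DmParams:
    """Differential methylation caller settings.

    A CpG is differentially methylated when the conservative bound of the
    posterior credible interval of the methylation difference exceeds
    ``cdif_cutoff`` and both samples have at least ``min_reads`` reads.
    Runs of at least ``min_run`` same-direction calls with adjacent spacing
    at most ``merge_window`` bp merge into a region.
    """

    cdif_cutoff: float = 0.2
    min_reads: int = 3
    merge_window: int = 300
    min_run: int = 4
    credible_level: float = 0.95
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    n_draws: int = 20000
    random_state: int = 0

    def __post_init__(self) -> None:
        _require(0.0 < self.cdif_cutoff < 1.0, "cdif_cutoff", "must be in (0, 1)")
        _require(self.min_reads >= 1, "min_reads", "must be >= 1")
        _require(self.min_run >= 2, "min_run", "must be >= 2")
        _require(0.0 < self.credible_level < 1.0, "credible_level",
                 "must be in (0, 1)")
        _require(self.prior_alpha > 0 and self.prior_beta > 0, "prior_alpha",
                 "prior pseudo-counts must be positive")
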