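"""Ground-truth generator checks: determinism, planted structure, and the
directional knockout effects downstream stages rely on."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methcanyon import SimulationConfig, ConfigurationError
from methcanyon.sim import (simulate_genome, simulate_methylome,
                            simulate_occupancy, simulate_expression)
from methcanyon.sim.expression import ARCHETYPE_SHIFTS
from methcanyon.sim.occupancy import tet1_peaks


def test_invalid_config_names_field():
    with pytest.raises(ConfigurationError, match="coverage_mean"):
        SimulationConfig(coverage_mean=-1)
    with pytest.raises(ConfigurationError, match="umr_length_range"):
        SimulationConfig(umr_length_range=(500, 3500))
    with pytest.raises(ConfigurationError, match="canyon_length_range"):
        SimulationConfig(canyon_length_range=(2000, 8000))
    with pytest.raises(ConfigurationError, match="condition"):
        SimulationConfig(condition="TripleKO")


def test_genome_deterministic(small_config):
    g1 = simulate_genome(small_config)
    g2 = simulate_genome(small_config)
    for chrom in g1.chroms:
        assert np.array_equal(g1.cpg_positions[chrom], g2.cpg_positions[chrom])
    pd.testing.assert_frame_equal(g1.regions, g2.regions)
    pd.testing.assert_frame_equal(g1.genes, g2.genes)


def test_genome_structure(small_genome, small_config):
    g = small_genome
    for chrom, pos in g.cpg_positions.items():
        assert (np.diff(pos) > 0).all()
        assert pos.min() >= 0 and pos.max() < g.chrom_sizes[chrom]
    # conservation of planted counts
    base = g.regions[~g.regions["ko_only"]]
    assert (base["klass"] == "CANYON").sum() == small_config.n_canyons
    assert (base["klass"] == "UMR").sum() == small_config.n_umrs
    # planted regions never overlap
    for _, sub in g.regions.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()
    assert len(g.satellites) > 0


def test_equal_rates_give_uniform_density():
    cfg = SimulationConfig(genome_length=2_000_000, island_cpg_rate=1.0,
                           background_cpg_rate=1.0, density_log_sigma=0.0,
                           n_canyons=2, n_umrs=4, n_genes=20, n_deg=7, seed=3)
    g = simulate_genome(cfg)
    pos = g.cpg_positions["chr1"]
    counts = np.histogram(pos, bins=np.arange(0, cfg.genome_length + 1, 1000))[0]
    # per-window counts should look like one Binomial(1000, 0.01) rate:
    # variance within ~25% of the mean (index of dispersion near 1)
    assert abs(counts.var() / counts.mean() - 1.0) < 0.25


def test_island_to_background_density_ratio():
    cfg = SimulationConfig(genome_length=10_000_000, background_cpg_rate=1.0,
                           island_cpg_rate=8.0, density_log_sigma=0.0,
                           n_canyons=10, n_umrs=30, n_genes=50, n_deg=7, seed=4)
    g = simulate_genome(cfg)
    pos = g.cpg_positions["chr1"]
    in_region = np.zeros(len(pos), dtype=bool)
    for r in g.regions.itertuples():
        lo, hi = np.searchsorted(pos, [r.start, r.end])
        in_region[lo:hi] = True
    region_bp = float((g.regions["end"] - g.regions["start"]).sum())
    island_rate = in_region.sum() / region_bp * 100
    # background windows away from islands/promoters
    bg_rate = (~in_region).sum() / (cfg.genome_length - region_bp) * 100
    assert island_rate / bg_rate == pytest.approx(8.0, rel=0.15)
    assert island_rate == pytest.approx(8.0, rel=0.1)


def test_methylome_mean_matches_configured_background():
    # empty-region genome: genome-wide mean equals the configured background
    cfg = SimulationConfig(genome_length=10_000_000, n_canyons=0, n_umrs=0,
                           ko_umr_multiplier=1.0, ko_canyon_multiplier=1.0,
                           background_meth_mean=0.75, coverage_mean=30,
                           n_genes=20, n_deg=7, seed=5)
    g = simulate_genome(cfg)
    track, _ = simulate_methylome(g, cfg)
    assert track.mean_ratio() == pytest.approx(0.75, abs=0.02)


def test_zero_meth_regions_with_binomial_limit(clean_genome, clean_config):
    cfg = dataclasses.replace(clean_config, umr_meth_mean=0.0)
    track, truth = simulate_methylome(clean_genome, cfg)
    df = track.data
    for r in truth.regions.itertuples():
        sub = df[(df["chrom"] == r.chrom) & (df["pos"] >= r.start)
                 & (df["pos"] < r.end)]
        assert (sub["meth"] == 0).all()


def test_methylome_validity(small_methylome):
    track, _ = small_methylome
    assert (track.data["meth"] <= track.data["total"]).all()
    ratios = track.data["ratio"].dropna()
    assert ((ratios >= 0) & (ratios <= 1)).all()


def test_dnmt3ako_lowers_global_methylation(small_genome, small_config):
    wt, _ = simulate_methylome(small_genome, small_config)
    ko, _ = simulate_methylome(
        small_genome, dataclasses.replace(small_config, condition="Dnmt3aKO"))
    assert ko.mean_ratio() < wt.mean_ratio()


def test_tet1ko_gains_methylation_in_flanks(clean_genome, clean_config):
    wt, truth = simulate_methylome(clean_genome, clean_config)
    ko, _ = simulate_methylome(
        clean_genome, dataclasses.replace(clean_config, condition="Tet1KO"))
    r = truth.regions.iloc[0]
    m = wt.data
    flank_wt = m[(m["chrom"] == r.chrom) & (m["pos"] >= r.end)
                 & (m["pos"] < r.end + 2000)]["ratio"].mean()
    k = ko.data
    flank_ko = k[(k["chrom"] == r.chrom) & (k["pos"] >= r.end)
                 & (k["pos"] < r.end + 2000)]["ratio"].mean()
    assert flank_ko > flank_wt + 0.05


def test_unknown_protein_rejected(small_genome, small_config):
    with pytest.raises(ConfigurationError, match="DNMT3A1"):
        simulate_occupancy(small_genome, "DNMT9", small_config)


def test_occupancy_deterministic_and_nonnegative(small_genome, small_config):
    a, _, _ = simulate_occupancy(small_genome, "TET1", small_config)
    b, _, _ = simulate_occupancy(small_genome, "TET1", small_config)
    for chrom in a.values:
        assert np.array_equal(a.values[chrom], b.values[chrom])
        assert (a.values[chrom] >= 0).all()


def test_tet1_baseline_below_activation_density():
    # no islands, density field at a constant rate below the activation
    # threshold -> TET1 identically at baseline (zero noise)
    cfg = SimulationConfig(genome_length=500_000, background_cpg_rate=0.3,
                           density_log_sigma=0.0, tet1_activation_density=1.0,
                           n_canyons=0, n_umrs=0, ko_umr_multiplier=1.0,
                           ko_canyon_multiplier=1.0, n_genes=8, n_deg=7,
                           promoter_island_fraction=0.0, occ_noise=0.0, seed=6)
    g = simulate_genome(cfg)
    track, _, _ = simulate_occupancy(g, "TET1", cfg)
    # TET1 has no TSS archetype bump for G1/G4/G5-only genes; pick clear bins
    # away from every TSS to avoid the G2/G3 promoter bumps
    arr = track.values["chr1"]
    mask = np.ones(len(arr), dtype=bool)
    for t in g.genes["tss"]:
        lo, hi = max(0, (t - 4000) // cfg.bin_width), (t + 4000) // cfg.bin_width
        mask[lo:hi] = False
    assert np.allclose(arr[mask], cfg.occ_baseline)


def test_dnmt3a1_peaks_in_canyon_flanks(clean_genome, clean_config):
    track, _, _ = simulate_occupancy(clean_genome, "DNMT3A1", clean_config)
    regs = clean_genome.regions
    canyons = regs[(regs["klass"] == "CANYON") & (~regs["ko_only"])]
    bw = track.bin_width
    for r in canyons.itertuples():
        arr = track.values[r.chrom]
        lo, hi = (r.start - 2000) // bw, (r.end + 2000) // bw
        window = arr[lo:hi]
        peak_pos = (lo + np.argmax(window)) * bw
        inside = r.start <= peak_pos < r.end
        assert not inside, "DNMT3A1 maximum must lie outside the canyon body"
        assert (r.start - 2000 <= peak_pos < r.start
                or r.end <= peak_pos < r.end + 2000)


def test_tet1ko_width_multiplier_doubles_halfmax_span():
    base = dict(genome_length=2_000_000, n_canyons=2, n_umrs=4, n_genes=30,
                n_deg=7, occ_noise=0.0, occ_amplitude=0.0,
                edge_peak_amplitude=0.0, seed=9)
    cfg = SimulationConfig(**base)
    g = simulate_genome(cfg)
    wt, _, _ = simulate_occupancy(g, "DNMT3A1", cfg)
    ko, _, _ = simulate_occupancy(
        g, "DNMT3A1", SimulationConfig(**base, condition="Tet1KO",
                                       tet1ko_width_multiplier=2.0))
    peaks = tet1_peaks(g)
    g3_tss = set(g.genes.loc[g.genes["group"] == "G3", "tss"])
    tss_peaks = peaks[(peaks["name"] == "tss_peak")
                      & (peaks["start"] + 1000).isin(g3_tss)]
    assert len(tss_peaks) >= 3
    ratios = []
    for p in tss_peaks.itertuples():
        bw = wt.bin_width
        lo, hi = (p.start - 8000) // bw, (p.end + 8000) // bw

        def span(track):
            seg = track.values[p.chrom][lo:hi] - 1.0
            above = np.flatnonzero(seg >= seg.max() / 2)
            return (above[-1] - above[0] + 1) * bw

        ratios.append(span(ko) / span(wt))
    assert np.median(ratios) == pytest.approx(2.0, rel=0.1)


def test_spike_counts_scale_with_depth(small_genome, small_config):
    t1, _, s1 = simulate_occupancy(small_genome, "H3K4me3", small_config,
                                   depth_factor=1.0)
    t3, _, s3 = simulate_occupancy(small_genome, "H3K4me3", small_config,
                                   depth_factor=3.0)
    assert s3.spike_count == 3 * s1.spike_count
    assert t3.total() == pytest.approx(3 * t1.total(), rel=1e-9)


def test_expression_zero_effect_is_null(small_genome, small_config):
    cfg = dataclasses.replace(small_config, deg_log2_effect=0.0,
                              expr_noise_sd=0.0)
    table, truth = simulate_expression(small_genome, cfg)
    assert (truth.labels == "none").all()
    vals = table[["WT", "Dnmt3aKO", "Tet1KO", "DKO"]].to_numpy()
    assert np.allclose(vals, vals[:, [0]])


def test_expression_additive_archetype(small_genome, small_config):
    table, truth = simulate_expression(small_genome, small_config)
    c1 = table[table["de_label"] == "C1"]
    log2 = np.log2(c1[["WT", "Dnmt3aKO", "Tet1KO", "DKO"]].to_numpy())
    shifts = (log2 - log2[:, [0]]).mean(axis=0)
    a = small_config.deg_log2_effect
    assert shifts[1] == pytest.approx(a, abs=0.15)
    assert shifts[2] == pytest.approx(a, abs=0.15)
    assert shifts[3] == pytest.approx(2 * a, abs=0.2)


def test_expression_needs_enough_genes():
    cfg = SimulationConfig(genome_length=500_000, n_genes=5, n_deg=5,
                           n_canyons=0, n_umrs=0, ko_umr_multiplier=1.0,
                           ko_canyon_multiplier=1.0, seed=2)
    g = simulate_genome(cfg)
    with pytest.raises(ConfigurationError, match="genes"):
        simulate_expression(g, cfg)


def test_archetype_patterns_are_distinct_directions():
    z = []
    for v in ARCHETYPE_SHIFTS.values():
        c = v - v.mean()
        z.append(c / np.linalg.norm(c))
    z = np.array(z)
    corr = z @ z.T
    off = corr[~np.eye(len(z), dtype=bool)]
    assert off.max() < 0.99
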