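"""Meta-profiles, TSS matrices, density stratification, peak coordinates,
and promoter CpG density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methcanyon import (DataIntegrityError, OccupancyTrack,
                        crossing_point, density_profile, dmr_peak_histogram,
                        promoter_cpg_density, scaled_region_profile,
                        to_peak_coordinate, tss_matrix)
from methcanyon.landscape import (DensityProfile, from_peak_coordinate,
                                  tss_associated_peaks)
from methcanyon.occupancy import build_windows
from methcanyon.sim import simulate_genome, simulate_occupancy
from methcanyon import SimulationConfig

from oracles import count_cpgs_in_window


def _track(values, bin_width=50):
    return OccupancyTrack(values={"chr1": np.asarray(values, dtype=float)},
                          bin_width=bin_width)


def _regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestScaledRegionProfile:
    def test_constant_track_flat_profile(self):
        track = _track(np.full(2000, 7.0))
        regions = _regions([("chr1", 20_000, 30_000), ("chr1", 50_000, 54_000)])
        prof = scaled_region_profile(track, regions)
        assert np.allclose(prof.values, 7.0)

    def test_length_invariance(self):
        # two regions whose bodies have the same shape after scaling:
        # a linear ramp from 0 to 1 across the body
        n = 4000
        vals = np.zeros(n)
        for start, end in ((400, 480), (1600, 2400)):
            vals[start:end] = np.linspace(0, 1, end - start)
        track = _track(vals, bin_width=50)
        regions = _regions([("chr1", 400 * 50, 480 * 50),
                            ("chr1", 1600 * 50, 2400 * 50)])
        prof = scaled_region_profile(track, regions, body_bins=40,
                                     flank=1000, flank_bin=50)
        body = prof.segment("body")
        single = scaled_region_profile(track, regions.iloc[[0]], body_bins=40,
                                       flank=1000, flank_bin=50).segment("body")
        assert np.allclose(body, single, atol=0.05)

    def test_n_regions_counts_skipped(self):
        track = _track(np.ones(100), bin_width=50)
        regions = _regions([("chr1", 0, 2000), ("chr1", 3000, 3010)])
        prof = scaled_region_profile(track, regions, body_bins=10, flank=500)
        assert prof.n_regions == 1

    def test_dnmt3a1_maxima_at_planted_edge_offset(self, clean_genome,
                                                   clean_config):
        track, _, _ = simulate_occupancy(clean_genome, "DNMT3A1", clean_config)
        regs = clean_genome.regions
        canyons = regs[(regs["klass"] == "CANYON") & (~regs["ko_only"])]
        prof = scaled_region_profile(track, canyons, body_bins=100,
                                     flank=5000, flank_bin=50)
        nf = prof.n_flank_bins
        left = prof.segment("left_flank")
        right = prof.segment("right_flank")
        # planted bump centre: edge_peak_offset bp outside each boundary
        want_left = nf - 1 - clean_config.edge_peak_offset // 50
        want_right = clean_config.edge_peak_offset // 50
        assert abs(int(np.nanargmax(left)) - want_left) <= 1
        assert abs(int(np.nanargmax(right)) - want_right) <= 1
        assert max(np.nanmax(left), np.nanmax(right)) > np.nanmax(
            prof.segment("body"))

    def test_empty_regions_rejected(self):
        with pytest.raises(DataIntegrityError):
            scaled_region_profile(_track(np.ones(10)), _regions([]))


class TestTssMatrix:
    def _genes(self, tss, strand):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(tss))],
                             "chrom": "chr1", "tss": tss, "strand": strand})

    def test_point_signal_at_plus_tss_centers(self):
        vals = np.zeros(1000)
        vals[200] = 9.0  # position 10_000..10_050
        track = _track(vals)
        mat = tss_matrix(track, self._genes([10_025], ["+"]), flank=2000,
                         bin=50)
        row = mat.iloc[0].to_numpy()
        n = len(row)
        assert np.nanargmax(row) in (n // 2 - 1, n // 2)

    def test_minus_strand_row_reversed(self):
        vals = np.arange(1000, dtype=float)
        track = _track(vals)
        plus = tss_matrix(track, self._genes([25_000], ["+"]), flank=2000,
                          bin=50).iloc[0].to_numpy()
        minus = tss_matrix(track, self._genes([25_000], ["-"]), flank=2000,
                           bin=50).iloc[0].to_numpy()
        assert np.allclose(minus, plus[::-1])

    def test_unknown_strand_rejected(self):
        with pytest.raises(DataIntegrityError):
            tss_matrix(_track(np.ones(100)), self._genes([1000], ["?"]))

    def test_chromosome_end_is_missing_not_zero(self):
        mat = tss_matrix(_track(np.ones(100)), self._genes([100], ["+"]),
                         flank=2000, bin=50)
        row = mat.iloc[0].to_numpy()
        assert np.isnan(row[0])
        assert row[-1] == 1.0 or np.isnan(row[-1])

    def test_g2_exceeds_g3_for_tet1(self, small_genome, small_config):
        track, _, _ = simulate_occupancy(small_genome, "TET1", small_config)
        mat = tss_matrix(track, small_genome.genes)
        groups = small_genome.genes.set_index("gene_id")["group"]
        g2 = mat.loc[groups[groups == "G2"].index].mean(axis=None)
        g3 = mat.loc[groups[groups == "G3"].index].mean(axis=None)
        assert g2 > g3


class TestDensityProfile:
    def _windows(self, density, signals):
        win = pd.DataFrame({"chrom": "chr1",
                            "start": np.arange(len(density)) * 1000})
        win["end"] = win["start"] + 1000
        win["cpg_density"] = density
        win["included"] = True
        for name, s in signals.items():
            win[f"signal_{name}"] = s
        return win

    def test_equal_count_bins(self):
        rng = np.random.default_rng(0)
        win = self._windows(rng.gamma(2, size=1003), {"x": np.ones(1003)})
        prof = density_profile(win, ["signal_x"], n_bins=20)
        assert prof.n_per_bin.max() - prof.n_per_bin.min() <= 1
        assert (np.diff(prof.bin_centers) >= 0).all()

    def test_forced_interpolation_crossing(self):
        prof = DensityProfile(bin_centers=np.array([1.0, 2.0]),
                              means={"a": np.array([0.0, 2.0]),
                                     "b": np.array([1.0, 1.0])},
                              n_per_bin=np.array([5, 5]))
        assert crossing_point(prof, "a", "b") == pytest.approx(1.5)

    def test_no_crossing_returns_none(self):
        prof = DensityProfile(bin_centers=np.array([1.0, 2.0, 3.0]),
                              means={"a": np.array([3.0, 4.0, 5.0]),
                                     "b": np.array([1.0, 1.0, 1.0])},
                              n_per_bin=np.array([5, 5, 5]))
        assert crossing_point(prof, "a", "b") is None

    def test_too_few_windows_rejected(self):
        win = self._windows(np.ones(5), {"x": np.ones(5)})
        with pytest.raises(DataIntegrityError):
            density_profile(win, ["signal_x"], n_bins=10)

    def test_planted_crossing_recovered(self, small_genome, small_config):
        from methcanyon.sim import simulate_methylome
        meth, _ = simulate_methylome(small_genome, small_config)
        tet1, _, _ = simulate_occupancy(small_genome, "TET1", small_config)
        d3a1, _, _ = simulate_occupancy(small_genome, "DNMT3A1", small_config)
        inp, _, _ = simulate_occupancy(small_genome, "input", small_config)
        win = build_windows(small_genome.chrom_sizes,
                            {"TET1": tet1, "DNMT3A1": d3a1},
                            satellites=small_genome.satellites, methylome=meth,
                            input_track=inp,
                            cpg_positions=small_genome.cpg_positions)
        prof = density_profile(win, ["signal_TET1", "signal_DNMT3A1"],
                               n_bins=20)
        cross = crossing_point(prof, "signal_TET1", "signal_DNMT3A1")
        assert cross == pytest.approx(small_config.crossing_density, abs=0.2)


class TestPeakCoordinate:
    def test_center_is_zero(self):
        assert to_peak_coordinate(1500, 1000, 2000) == 0.0

    def test_edges_are_plus_minus_one(self):
        assert to_peak_coordinate(2000, 1000, 2000) == 1.0
        assert to_peak_coordinate(1000, 1000, 2000) == -1.0

    def test_linear_beyond_edges(self):
        assert to_peak_coordinate(500, 1000, 2000) == -2.0

    def test_zero_length_peak_rejected(self):
        with pytest.raises(DataIntegrityError):
            to_peak_coordinate(100, 50, 50)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(pos=st.integers(-10_000, 10_000), start=st.integers(0, 5000),
           length=st.integers(1, 5000))
    def test_roundtrip_within_one_bp(self, pos, start, length):
        u = to_peak_coordinate(pos, start, start + length)
        back = from_peak_coordinate(u, start, start + length)
        assert abs(back - pos) < 1.0


class TestDmrPeakHistogram:
    def test_midpoints_land_in_expected_bins(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                              "end": [3000]})
        dmrs = pd.DataFrame({"chrom": ["chr1"] * 3,
                             "start": [1990, 2990, 4990],
                             "end": [2010, 3010, 5010]})
        # midpoints 2000 (u=0), 3000 (u=1), 5000 (u=3)
        hist = dmr_peak_histogram(dmrs, peaks, u_range=(-4, 4), n_bins=8)
        centers = (hist["u_left"] + hist["u_right"]) / 2
        got = hist.loc[hist["count"] > 0, :]
        assert len(got) == 3
        assert hist["count"].sum() == 3
        assert hist["density"].sum() * (centers.iloc[1] - centers.iloc[0]) \
            == pytest.approx(1.0)

    def test_nearest_peak_tie_goes_low(self):
        peaks = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [0, 2000], "end": [1000, 3000]})
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [1490],
                             "end": [1510]})  # midpoint 1500 equidistant
        hist = dmr_peak_histogram(dmrs, peaks, u_range=(-3, 3), n_bins=6)
        # mapped to the first (lower-coordinate) peak: u = +2
        nz = hist[hist["count"] > 0]
        assert nz.iloc[0]["u_left"] >= 1.0

    def test_empty_peaks_rejected(self):
        with pytest.raises(DataIntegrityError):
            dmr_peak_histogram(pd.DataFrame({"chrom": [], "start": [],
                                             "end": []}),
                               pd.DataFrame({"chrom": [], "start": [],
                                             "end": []}))


def test_tss_associated_peak_selection():
    peaks = pd.DataFrame({"chrom": ["chr1"] * 3,
                          "start": [900, 5000, 20_000],
                          "end": [1100, 7000, 21_000]})
    genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                          "tss": [1000], "strand": ["+"]})
    out = tss_associated_peaks(peaks, genes, max_dist=1000)
    assert list(out["start"]) == [900]


class TestPromoterCpgDensity:
    def test_forced_arithmetic(self):
        cpgs = {"chr1": np.arange(9000, 10_500, 100)}  # 15 CpGs in window
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [10_000], "strand": ["+"]})
        dens = promoter_cpg_density(genes, cpgs)
        assert dens["g"] == pytest.approx(1.0)

    def test_zero_cpgs(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [10_000], "strand": ["+"]})
        assert promoter_cpg_density(genes, {"chr1": np.array([50_000])})["g"] == 0.0

    def test_minus_strand_matches_coordinate_flip_oracle(self, small_genome):
        genes = small_genome.genes
        minus = genes[genes["strand"] == "-"].head(10)
        dens = promoter_cpg_density(minus, small_genome.cpg_positions)
        for g in minus.itertuples():
            # strand flip: upstream 1 kb is to the right of a minus TSS
            n = count_cpgs_in_window(small_genome.cpg_positions[g.chrom],
                                     g.tss - 500, g.tss + 1000)
            assert dens[g.gene_id] == pytest.approx(100.0 * n / 1500.0)

    def test_truncated_window_uses_truncated_length(self):
        cpgs = {"chr1": np.array([100, 200, 300])}
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "tss": [400], "strand": ["+"]})
        # window would be [-600, 900); truncated to [0, 900) -> length 900
        dens = promoter_cpg_density(genes, cpgs)
        assert dens["g"] == pytest.approx(100.0 * 3 / 900.0)
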