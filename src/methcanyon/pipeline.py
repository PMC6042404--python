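"""Stage orchestration: run each analysis stage from a structured config,
with manifests (input/output checksums, parameters, seed, version) and
checksum-gated re-runs.

Stage dependency order: simulate -> preprocess -> segment -> dmr ->
occupancy -> landscape -> cluster. Outputs are written atomically (temp file
then rename); a stage whose inputs, parameters and outputs are unchanged is
a no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from pathlib import Path
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (ConfigurationError, SimulationConfig, SegmentationParams,
                     DmParams)
from .tracks import MethylomeTrack, OccupancyTrack, write_bed, read_bed
from . import reads as reads_mod
from . import segmentation as seg_mod
from . import dmr as dmr_mod
from . import occupancy as occ_mod
from . import landscape as land_mod
from . import clustering as clu_mod
from .sim import (simulate_genome, simulate_methylome, simulate_occupancy,
                  simulate_expression, simulate_read_observations)

log = logging.getLogger("methcanyon")

STAGES = ["simulate", "preprocess", "segment", "dmr", "occupancy",
          "landscape", "cluster"]

# upstream files each stage requires: stage -> {filename: producing stage}
REQUIRES: Dict[str, Dict[str, str]] = {
    "simulate": {},
    "preprocess": {"reads.tsv": "simulate", "chrom_sizes.tsv": "simulate"},
    "segment": {"methylome_WT.bedgraph": "simulate"},
    "dmr": {"methylome_WT.bedgraph": "simulate",
            "methylome_KO.bedgraph": "simulate"},
    "occupancy": {"occ_TET1.bedgraph": "simulate",
                  "occ_DNMT3A1.bedgraph": "simulate",
                  "occ_input.bedgraph": "simulate",
                  "methylome_WT.bedgraph": "simulate",
                  "satellites.bed": "simulate",
                  "cpgs.tsv": "simulate"},
    "landscape": {"occ_TET1_norm.bedgraph": "occupancy",
                  "occ_DNMT3A1_norm.bedgraph": "occupancy",
                  "windows.tsv": "occupancy",
                  "regions.bed": "segment",
                  "genes.tsv": "simulate"},
    "cluster": {"tss_matrix_TET1.tsv": "landscape",
                "tss_matrix_DNMT3A1.tsv": "landscape",
                "expression.tsv": "simulate"},
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    workdir: Path
    seed: int = 0
    log_level: str = "INFO"
    simulation: dict = dataclasses.field(default_factory=dict)
    segmentation: dict = dataclasses.field(default_factory=dict)
    dm: dict = dataclasses.field(default_factory=dict)
    occupancy: dict = dataclasses.field(default_factory=dict)
    landscape: dict = dataclasses.field(default_factory=dict)
    clustering: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "workdir" not in doc:
            raise ConfigurationError("workdir: required")
        doc["workdir"] = Path(doc["workdir"])
        cfg = cls(**doc)
        # validate parameter blocks eagerly
        cfg.sim_config()
        cfg.seg_params()
        cfg.dm_params()
        return cfg

    def sim_config(self) -> SimulationConfig:
        kw = dict(self.simulation)
        kw.setdefault("seed", self.seed)
        for key in ("umr_length_range", "canyon_length_range",
                    "gene_length_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return SimulationConfig(**kw)

    def seg_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def dm_params(self) -> DmParams:
        kw = dict(self.dm)
        kw.setdefault("random_state", self.seed)
        return DmParams(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _check_inputs(stage: str, workdir: Path) -> Dict[str, str]:
    checksums = {}
    for fname, producer in REQUIRES[stage].items():
        p = workdir / fname
        if not p.exists():
            raise DependencyError(
                f"stage '{stage}' needs {fname}; run stage '{producer}' first")
        checksums[fname] = _sha256(p)
    return checksums


def _stage_params(stage: str, cfg: PipelineConfig) -> dict:
    block = {
        "simulate": cfg.sim_config().to_dict(),
        "preprocess": {"trim_bases": 3, "p_cutoff": 1e-5},
        "segment": dataclasses.asdict(cfg.seg_params()),
        "dmr": dataclasses.asdict(cfg.dm_params()),
        "occupancy": {"target_depth": cfg.occupancy.get("target_depth", 1e6)},
        "landscape": {"body_bins": cfg.landscape.get("body_bins", 100),
                      "flank": cfg.landscape.get("flank", 5000),
                      "flank_bin": cfg.landscape.get("flank_bin", 50),
                      "tss_flank": cfg.landscape.get("tss_flank", 5000),
                      "tss_bin": cfg.landscape.get("tss_bin", 50),
                      "n_density_bins": cfg.landscape.get("n_density_bins", 20)},
        "cluster": {"k_tss": cfg.clustering.get("k_tss", 5),
                    "k_deg": cfg.clustering.get("k_deg", 7)},
    }[stage]
    # JSON round-trip so stored and freshly-computed params compare equal
    # (tuples become lists, numeric types normalize)
    return json.loads(json.dumps(block))


def run_stage(stage: str, cfg: PipelineConfig, force: bool = False) -> dict:
    """Run one stage (or 'all'); returns the manifest dict."""
    if stage == "all":
        manifest = {}
        for s in STAGES:
            manifest[s] = run_stage(s, cfg, force=force)
        return manifest
    if stage not in STAGES:
        raise ConfigurationError(
            f"stage: unknown stage {stage!r}; choose from {STAGES + ['all']}")
    workdir = cfg.workdir
    workdir.mkdir(parents=True, exist_ok=True)
    inputs = _check_inputs(stage, workdir)
    params = _stage_params(stage, cfg)
    manifest_path = workdir / f"manifest_{stage}.json"
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if (old.get("inputs") == inputs and old.get("params") == params
                and old.get("seed") == cfg.seed
                and all((workdir / f).exists() for f in old.get("outputs", {}))):
            log.info("stage %s unchanged; skipping (use force to re-run)", stage)
            return old
    t0 = time.monotonic()
    outputs = _STAGE_FUNCS[stage](cfg, workdir)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "params": params,
        "inputs": inputs,
        "outputs": {f: _sha256(workdir / f) for f in outputs},
        "stats": getattr(run_stage, "last_stats", {}).get(stage, {}),
        "elapsed_s": round(time.monotonic() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _atomic_write(manifest_path,
                  lambda p: p.write_text(json.dumps(manifest, indent=2)))
    return manifest


run_stage.last_stats = {}


def _write_df(path: Path, df: pd.DataFrame, **kw) -> None:
    _atomic_write(path, lambda p: df.to_csv(p, sep="\t", index=kw.get("index", False)))


def _stage_simulate(cfg: PipelineConfig, wd: Path) -> List[str]:
    sim = cfg.sim_config()
    genome = simulate_genome(sim)
    ko = dataclasses.replace(sim, condition="Dnmt3aKO")
    track_wt, truth_wt = simulate_methylome(genome, sim)
    track_ko, _ = simulate_methylome(genome, ko)
    outputs = []

    def emit(name, writer):
        _atomic_write(wd / name, writer)
        outputs.append(name)

    emit("methylome_WT.bedgraph", track_wt.to_bedgraph)
    emit("methylome_KO.bedgraph", track_ko.to_bedgraph)
    for protein in ("TET1", "DNMT3A1", "input"):
        track, peaks, spike = simulate_occupancy(genome, protein, sim)
        emit(f"occ_{protein}.bedgraph", track.to_bedgraph)
        if protein == "TET1":
            emit("peaks.bed", lambda p: write_bed(peaks, p))
            emit("spike.tsv", lambda p: pd.DataFrame(
                [dataclasses.asdict(spike)]).to_csv(p, sep="\t", index=False))
    expr, _ = simulate_expression(genome, sim)
    emit("expression.tsv", lambda p: expr.to_csv(p, sep="\t", index=False))
    emit("genes.tsv", lambda p: genome.genes.to_csv(p, sep="\t", index=False))
    emit("satellites.bed", lambda p: write_bed(genome.satellites, p))
    emit("regions_truth.bed", lambda p: write_bed(
        truth_wt.regions.assign(name=truth_wt.regions["klass"]), p))
    emit("chrom_sizes.tsv", lambda p: pd.DataFrame(
        genome.chrom_sizes.items(), columns=["chrom", "size"]).to_csv(
            p, sep="\t", index=False))
    emit("cpgs.tsv", lambda p: pd.concat(
        [pd.DataFrame({"chrom": c, "pos": pos})
         for c, pos in genome.cpg_positions.items()]).to_csv(
             p, sep="\t", index=False))
    rds = simulate_read_observations(genome, sim, n_fragments=2000)
    emit("reads.tsv", lambda p: reads_mod.write_reads_tsv(rds, p))
    return outputs


def _stage_preprocess(cfg: PipelineConfig, wd: Path) -> List[str]:
    rds = reads_mod.read_reads_tsv(wd / "reads.tsv")
    sizes = pd.read_csv(wd / "chrom_sizes.tsv", sep="\t")
    glen = int(sizes["size"].sum())
    track, stats = reads_mod.preprocess_reads(rds, genome_length=glen)
    run_stage.last_stats["preprocess"] = stats
    _atomic_write(wd / "methylome_pileup.bedgraph", track.to_bedgraph)
    return ["methylome_pileup.bedgraph"]


def _stage_segment(cfg: PipelineConfig, wd: Path) -> List[str]:
    track = MethylomeTrack.from_bedgraph(wd / "methylome_WT.bedgraph")
    params = cfg.seg_params()
    seg = seg_mod.CanyonSegmenter(**dataclasses.asdict(params)).fit(track)
    run_stage.last_stats["segment"] = {
        "n_regions": int(len(seg.regions_)),
        "n_umr": int((seg.regions_["klass"] == "UMR").sum()),
        "n_canyon": int((seg.regions_["klass"] == "CANYON").sum()),
    }
    _atomic_write(wd / "regions.bed", lambda p: seg_mod.regions_to_bed(seg.regions_, p))
    edges = seg_mod.all_canyon_edges(
        seg.regions_[seg.regions_["klass"] == "CANYON"], flank=params.edge_flank)
    _atomic_write(wd / "canyon_edges.bed",
                  lambda p: write_bed(edges.assign(name=edges.get("side", ".")), p)
                  if len(edges) else p.write_text(""))
    _write_df(wd / "candidates.tsv", seg.candidates_)
    return ["regions.bed", "canyon_edges.bed", "candidates.tsv"]


def _stage_dmr(cfg: PipelineConfig, wd: Path) -> List[str]:
    t1 = MethylomeTrack.from_bedgraph(wd / "methylome_WT.bedgraph")
    t2 = MethylomeTrack.from_bedgraph(wd / "methylome_KO.bedgraph")
    params = cfg.dm_params()
    dmcs = dmr_mod.call_dmcs(t1, t2, params)
    dmrs = dmr_mod.merge_dmrs(dmcs, params)
    stats = dmr_mod.dmr_summary(dmrs)
    stats.update(dmr_mod.call_dmcs.last_stats)
    stats["n_dmcs"] = int(len(dmcs))
    run_stage.last_stats["dmr"] = stats
    _write_df(wd / "dmcs.tsv", dmcs)
    _write_df(wd / "dmrs.tsv", dmrs)
    return ["dmcs.tsv", "dmrs.tsv"]


def _stage_occupancy(cfg: PipelineConfig, wd: Path) -> List[str]:
    target = cfg.occupancy.get("target_depth", 1e6)
    inp = OccupancyTrack.from_bedgraph(wd / "occ_input.bedgraph")
    meth = MethylomeTrack.from_bedgraph(wd / "methylome_WT.bedgraph")
    sats = read_bed(wd / "satellites.bed")
    cpgs = pd.read_csv(wd / "cpgs.tsv", sep="\t")
    cpg_pos = {c: sub["pos"].to_numpy() for c, sub in cpgs.groupby("chrom")}
    sizes = pd.read_csv(wd / "chrom_sizes.tsv", sep="\t")
    chrom_sizes = dict(zip(sizes["chrom"], sizes["size"]))
    outputs = []
    norm = {}
    for protein in ("TET1", "DNMT3A1"):
        raw = OccupancyTrack.from_bedgraph(wd / f"occ_{protein}.bedgraph")
        norm[protein] = occ_mod.normalize_track(raw, inp, target_depth=target)
        _atomic_write(wd / f"occ_{protein}_norm.bedgraph",
                      norm[protein].to_bedgraph)
        outputs.append(f"occ_{protein}_norm.bedgraph")
    windows = occ_mod.build_windows(chrom_sizes, norm, satellites=sats,
                                    methylome=meth, input_track=inp,
                                    cpg_positions=cpg_pos)
    _write_df(wd / "windows.tsv", windows)
    outputs.append("windows.tsv")
    diff = occ_mod.differential_occupancy(norm["TET1"], norm["DNMT3A1"])
    _atomic_write(wd / "diff_TET1_vs_DNMT3A1.bedgraph", diff.to_bedgraph)
    outputs.append("diff_TET1_vs_DNMT3A1.bedgraph")
    return outputs


def _stage_landscape(cfg: PipelineConfig, wd: Path) -> List[str]:
    p = _stage_params("landscape", cfg)
    genes = pd.read_csv(wd / "genes.tsv", sep="\t")
    regions = read_bed(wd / "regions.bed")
    windows = pd.read_csv(wd / "windows.tsv", sep="\t")
    outputs = []
    tracks = {name: OccupancyTrack.from_bedgraph(wd / f"occ_{name}_norm.bedgraph")
              for name in ("TET1", "DNMT3A1")}
    canyons = regions[regions["name"] == "CANYON"]
    for name, track in tracks.items():
        if len(canyons):
            prof = land_mod.scaled_region_profile(
                track, canyons, body_bins=p["body_bins"], flank=p["flank"],
                flank_bin=p["flank_bin"])
            _write_df(wd / f"canyon_profile_{name}.tsv",
                      pd.DataFrame({"bin": np.arange(len(prof.values)),
                                    "mean_signal": prof.values,
                                    "n": prof.n_regions}))
            outputs.append(f"canyon_profile_{name}.tsv")
        mat = land_mod.tss_matrix(track, genes, flank=p["tss_flank"],
                                  bin=p["tss_bin"])
        _atomic_write(wd / f"tss_matrix_{name}.tsv",
                      lambda q, m=mat: m.to_csv(q, sep="\t", index=True,
                                                index_label="gene_id"))
        outputs.append(f"tss_matrix_{name}.tsv")
    prof = land_mod.density_profile(windows, ["signal_TET1", "signal_DNMT3A1"],
                                    n_bins=p["n_density_bins"])
    cross = land_mod.crossing_point(prof, "signal_TET1", "signal_DNMT3A1")
    run_stage.last_stats["landscape"] = {
        "crossing_density": None if cross is None else round(cross, 4)}
    _write_df(wd / "density_profile.tsv",
              pd.DataFrame({"cpg_density": prof.bin_centers,
                            "TET1": prof.means["signal_TET1"],
                            "DNMT3A1": prof.means["signal_DNMT3A1"],
                            "n": prof.n_per_bin}))
    outputs.append("density_profile.tsv")
    return outputs


def _stage_cluster(cfg: PipelineConfig, wd: Path) -> List[str]:
    p = _stage_params("cluster", cfg)
    mats = [pd.read_csv(wd / f"tss_matrix_{n}.tsv", sep="\t",
                        index_col="gene_id") for n in ("DNMT3A1", "TET1")]
    groups = clu_mod.kmeans_tss_groups(mats, k=p["k_tss"], seed=cfg.seed)
    _write_df(wd / "tss_groups.tsv",
              groups.rename_axis("gene_id").reset_index())
    expr = pd.read_csv(wd / "expression.tsv", sep="\t")
    de = expr[expr["de_label"] != "none"].set_index("gene_id")
    outputs = ["tss_groups.tsv"]
    if len(de) >= p["k_deg"]:
        clusters = clu_mod.deg_clusters(
            de.drop(columns=["de_label"]), k=p["k_deg"], seed=cfg.seed)
        _write_df(wd / "deg_clusters.tsv",
                  clusters.rename_axis("gene_id").reset_index())
        outputs.append("deg_clusters.tsv")
    run_stage.last_stats["cluster"] = {
        "group_sizes": groups.value_counts().to_dict()}
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "dmr": _stage_dmr,
    "occupancy": _stage_occupancy,
    "landscape": _stage_landscape,
    "cluster": _stage_cluster,
}
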