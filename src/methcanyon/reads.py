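"""Read-level bias filters for bisulfite data and the per-CpG pileup.

Three technical-bias filters are applied before any methylation ratio is
computed: trimming of the end-repair overhang (M-bias), removal of PCR
clonal reads by a Poisson tail cutoff on the per-start-position read count,
and single-counting of the overlapping segment of paired mates. Coordinates
are 0-based half-open; plus/minus calls are pooled per CpG (strand-collapsed
counting) and the CpG is reported on the plus-strand C.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import defaultdict
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DataIntegrityError
from .tracks import MethylomeTrack

Call = Tuple[int, bool]  # (plus-strand CpG position, methylated?)


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read's CpG methylation calls.

    ``repair_end`` flags which read end (in read orientation: '5p' or '3p')
    went through end repair and is subject to M-bias trimming; None if
    neither. ``calls`` are sorted (position, methylated) pairs within
    [start, end).
    """

    read_id: str
    mate_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    repair_end: Optional[str] = None
    calls: Tuple[Call, ...] = ()

    def __post_init__(self):
        for pos, _ in self.calls:
            if not (self.start <= pos < self.end):
                raise DataIntegrityError(
                    f"call at {pos} outside read span [{self.start},{self.end})")


def compute_ratio(meth_reads: int, total_reads: int) -> float:
    """Methylation ratio: unconverted reads over covered reads at one CpG.

    Zero-coverage sites are no-data (NaN), never 0.
    """
    if meth_reads < 0 or total_reads < 0:
        raise DataIntegrityError("negative read counts")
    if meth_reads > total_reads:
        raise DataIntegrityError("meth_reads exceeds total_reads")
    if total_reads == 0:
        return float("nan")
    return meth_reads / total_reads


def mbias_trim(read: ReadObservation, n_bases: int = 3) -> ReadObservation:
    """Drop base calls within ``n_bases`` of the flagged repair end.

    The read span shrinks accordingly, so downstream mate-overlap handling
    sees the trimmed extent. Reads shorter than ``n_bases`` come back empty;
    with ``n_bases == 0`` or no flagged end the read is returned unchanged.
    """
    if n_bases < 0:
        raise ValueError("n_bases must be >= 0")
    if n_bases == 0 or read.repair_end is None:
        return read
    if read.end - read.start <= n_bases:
        mid = read.start
        return replace(read, start=mid, end=mid, calls=())
    # map read-orientation end to a genomic side
    if read.strand == "+":
        genomic_side = "end" if read.repair_end == "3p" else "start"
    else:
        genomic_side = "start" if read.repair_end == "3p" else "end"
    if genomic_side == "end":
        new_start, new_end = read.start, read.end - n_bases
    else:
        new_start, new_end = read.start + n_bases, read.end
    calls = tuple((p, m) for p, m in read.calls if new_start <= p < new_end)
    return replace(read, start=new_start, end=new_end, calls=calls)


def clonal_max_dup(lam: float, p_cutoff: float = 1e-5) -> int:
    """Smallest k with upper Poisson tail P(X >= k+1) < p_cutoff.

    ``lam`` is the expected read count per start position (total reads over
    genome length).
    """
    if lam <= 0:
        raise ValueError("Poisson rate must be positive")
    k = 1
    while stats.poisson.sf(k, lam) >= p_cutoff:
        k += 1
    return k


def clonal_filter(reads: Sequence[ReadObservation], genome_length: int,
                  p_cutoff: float = 1e-5,
                  max_dup: Optional[int] = None) -> Tuple[int, List[ReadObservation]]:
    """Cap reads per identical (chrom, start, strand) at the Poisson-derived
    maximum duplicate count; retained reads are the first by input order.

    ``max_dup`` overrides the Poisson computation when given (e.g. the fixed
    two-duplicate cap used for ChIP libraries).
    """
    if max_dup is None:
        if genome_length <= 0:
            raise ValueError("genome_length must be positive")
        lam = len(reads) / genome_length
        max_dup = clonal_max_dup(lam, p_cutoff)
    seen: defaultdict = defaultdict(int)
    kept = []
    for r in reads:
        key = (r.chrom, r.start, r.strand)
        if seen[key] < max_dup:
            kept.append(r)
            seen[key] += 1
    return max_dup, kept


def mate_overlap_dedup(first: ReadObservation,
                       second: ReadObservation) -> ReadObservation:
    """Merge a mate pair counting the overlapping segment exactly once.

    Calls inside the overlap of the (already trimmed) spans are taken from
    the first mate; all non-overlapping calls from both mates are kept.
    """
    if first.mate_id != second.mate_id:
        raise DataIntegrityError(
            f"mate ids differ: {first.mate_id!r} vs {second.mate_id!r}")
    if first.chrom != second.chrom:
        raise DataIntegrityError("mates on different chromosomes")
    ov_start = max(first.start, second.start)
    ov_end = min(first.end, second.end)
    calls = list(first.calls) + [
        (p, m) for p, m in second.calls if not (ov_start <= p < ov_end)]
    calls.sort()
    return ReadObservation(
        read_id=f"{first.mate_id}/merged", mate_id=first.mate_id,
        chrom=first.chrom, start=min(first.start, second.start),
        end=max(first.end, second.end), strand=".", repair_end=None,
        calls=tuple(calls))


def pileup_methylome(reads: Iterable[ReadObservation], sample: str = "sample",
                     condition: str = "WT") -> MethylomeTrack:
    """Aggregate per-CpG methylated/total counts from filtered reads."""
    meth: defaultdict = defaultdict(int)
    total: defaultdict = defaultdict(int)
    for r in reads:
        for pos, m in r.calls:
            key = (r.chrom, pos)
            total[key] += 1
            meth[key] += int(m)
    if not total:
        return MethylomeTrack(pd.DataFrame(columns=["chrom", "pos", "meth", "total"]),
                              sample=sample, condition=condition)
    keys = sorted(total)
    df = pd.DataFrame({
        "chrom": [k[0] for k in keys],
        "pos": np.array([k[1] for k in keys], dtype=np.int64),
        "meth": np.array([meth[k] for k in keys], dtype=np.int64),
        "total": np.array([total[k] for k in keys], dtype=np.int64),
    })
    return MethylomeTrack(df, sample=sample, condition=condition)


def preprocess_reads(reads: Sequence[ReadObservation], genome_length: int,
                     trim_bases: int = 3, p_cutoff: float = 1e-5,
                     sample: str = "sample", condition: str = "WT",
                     ) -> Tuple[MethylomeTrack, dict]:
    """Full read-level pipeline: M-bias trim, clonal filter, mate-overlap
    single counting, pileup. Returns the track and a small stats dict."""
    trimmed = [mbias_trim(r, trim_bases) for r in reads]
    max_dup, kept = clonal_filter(trimmed, genome_length, p_cutoff)
    by_mate: defaultdict = defaultdict(list)
    for r in kept:
        by_mate[r.mate_id].append(r)
    merged: List[ReadObservation] = []
    for mates in by_mate.values():
        while len(mates) >= 2:
            a = mates.pop(0)
            b = mates.pop(0)
            mates.insert(0, mate_overlap_dedup(a, b))
        merged.extend(mates)
    track = pileup_methylome(merged, sample=sample, condition=condition)
    stats_out = {"n_input": len(reads), "n_after_clonal": len(kept),
                 "max_dup": max_dup, "n_sites": len(track)}
    return track, stats_out


# --- simplified read-observation TSV (stands in for alignment output) ------

_READ_COLUMNS = ["read_id", "mate_id", "chrom", "start", "end", "strand",
                 "repair_end", "calls"]


def write_reads_tsv(reads: Sequence[ReadObservation], path) -> None:
    rows = []
    for r in reads:
        calls = ",".join(f"{p}:{int(m)}" for p, m in r.calls) or "."
        rows.append((r.read_id, r.mate_id, r.chrom, r.start, r.end, r.strand,
                     r.repair_end or ".", calls))
    pd.DataFrame(rows, columns=_READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> List[ReadObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"calls": str})
    out = []
    for row in df.itertuples():
        calls: Tuple[Call, ...] = ()
        if isinstance(row.calls, str) and row.calls != ".":
            calls = tuple((int(tok.split(":")[0]), bool(int(tok.split(":")[1])))
                          for tok in row.calls.split(","))
        out.append(ReadObservation(
            read_id=str(row.read_id), mate_id=str(row.mate_id),
            chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            strand=str(row.strand),
            repair_end=None if row.repair_end == "." else str(row.repair_end),
            calls=calls))
    return out
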