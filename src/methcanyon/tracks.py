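"""In-memory containers for methylomes and binned occupancy signal, plus
their plain-text interchange formats (bedGraph-style TSV, BED6).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .config import DataIntegrityError

METH_COLUMNS = ["chrom", "pos", "meth", "total", "ratio"]


@dataclass
class MethylomeTrack:
    """Per-CpG methylation calls for one sample.

    ``data`` holds one row per CpG: chrom, pos (position of the C of the
    CpG on the plus strand), meth (methylated read count), total (covered
    read count) and ratio (meth/total, NaN where total == 0 — zero-coverage
    sites are flagged, never imputed as 0).
    """

    data: pd.DataFrame
    sample: str = "sample"
    condition: str = "WT"

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("chrom", "pos", "meth", "total") if c not in df.columns]
        if missing:
            raise DataIntegrityError(f"methylome table missing columns {missing}")
        if (df["meth"] > df["total"]).any():
            raise DataIntegrityError("meth count exceeds total count")
        if (df["meth"] < 0).any() or (df["total"] < 0).any():
            raise DataIntegrityError("negative read counts")
        if "ratio" not in df.columns:
            df = df.copy()
            with np.errstate(invalid="ignore", divide="ignore"):
                df["ratio"] = np.where(df["total"] > 0, df["meth"] / df["total"], np.nan)
            self.data = df
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise DataIntegrityError(
                    "CpG positions must be strictly increasing per chromosome")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.data["chrom"]))

    def chrom_data(self, chrom: str) -> pd.DataFrame:
        return self.data[self.data["chrom"] == chrom]

    def mean_ratio(self) -> float:
        """Genome-wide mean methylation ratio over covered CpGs."""
        return float(self.data["ratio"].mean())

    def to_bedgraph(self, path) -> None:
        df = self.data
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 2,     # the CpG dinucleotide
            "ratio": df["ratio"].round(6),
            "meth": df["meth"],
            "total": df["total"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path, sample: str = "sample",
                      condition: str = "WT") -> "MethylomeTrack":
        raw = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "ratio", "meth", "total"])
        df = pd.DataFrame({
            "chrom": raw["chrom"].astype(str),
            "pos": raw["start"].astype(np.int64),
            "meth": raw["meth"].astype(np.int64),
            "total": raw["total"].astype(np.int64),
        })
        return cls(df, sample=sample, condition=condition)


@dataclass
class OccupancyTrack:
    """Fixed-width-binned protein/histone signal.

    ``values`` maps chromosome name to a non-negative float array; bin ``i``
    covers ``[i*bin_width, (i+1)*bin_width)``. ``total_tags`` is the tag
    count the signal represents (defaults to the signal sum).
    """

    values: Dict[str, np.ndarray]
    bin_width: int = 10
    sample: str = "sample"
    condition: str = "WT"
    total_tags: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        if self.total_tags is None:
            self.total_tags = float(sum(v.sum() for v in self.values.values()))

    @property
    def chroms(self) -> list:
        return list(self.values)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy_with(self, values: Dict[str, np.ndarray], **kw) -> "OccupancyTrack":
        out = OccupancyTrack(values={c: v.copy() for c, v in values.items()},
                             bin_width=self.bin_width, sample=self.sample,
                             condition=self.condition)
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def value_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal at base-pair positions (NaN outside the track)."""
        arr = self.values[chrom]
        pos = np.asarray(positions)
        idx = pos // self.bin_width
        ok = (pos >= 0) & (idx < len(arr))
        out = np.full(pos.shape, np.nan)
        out[ok] = arr[idx[ok]]
        return out

    def same_grid(self, other: "OccupancyTrack") -> bool:
        return (self.bin_width == other.bin_width
                and set(self.values) == set(other.values)
                and all(len(self.values[c]) == len(other.values[c])
                        for c in self.values))

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                starts = np.arange(len(arr)) * self.bin_width
                for s, v in zip(starts, arr):
                    fh.write(f"{chrom}\t{s}\t{s + self.bin_width}\t{v:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path, sample: str = "sample",
                      condition: str = "WT") -> "OccupancyTrack":
        raw = pd.read_csv(path, sep="\t", header=None,
                          names=["chrom", "start", "end", "value"])
        widths = (raw["end"] - raw["start"]).unique()
        if len(widths) != 1:
            raise DataIntegrityError("bedGraph track has non-constant bin width")
        bw = int(widths[0])
        values = {}
        for chrom, sub in raw.groupby("chrom", sort=False):
            idx = (sub["start"] // bw).to_numpy()
            arr = np.zeros(int(idx.max()) + 1)
            arr[idx] = sub["value"].to_numpy()
            values[str(chrom)] = arr
        return cls(values=values, bin_width=bw, sample=sample, condition=condition)


def write_bed(df: pd.DataFrame, path, name_col: str = "name",
              score_col: Optional[str] = None, strand_col: Optional[str] = None) -> None:
    """Write intervals as BED6 (chrom, start, end, name, score, strand)."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "name": df[name_col] if name_col in df.columns else ".",
        "score": df[score_col] if score_col and score_col in df.columns else 0,
        "strand": df[strand_col] if strand_col and strand_col in df.columns else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + [f"extra{i}" for i in range(df.shape[1] - len(names))]
    df["chrom"] = df["chrom"].astype(str)
    return df
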