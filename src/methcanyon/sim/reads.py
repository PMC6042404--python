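"""Paired-end bisulfite read simulator.

Fragments are placed uniformly; both mates carry the same per-fragment CpG
calls (one molecule), so the mate-overlap filter genuinely has double
counting to remove. Each mate's read-orientation 3' end is flagged as the
end-repair end. Optional clonal duplication re-emits whole fragments at the
same start to exercise the Poisson duplicate filter.
"""

from __future__ import annotations

from typing import List

import numpy as np

from ..config import SimulationConfig
from ..reads import ReadObservation
from .genome import Genome
from .methylome import active_regions, _mean_field


def simulate_read_observations(genome: Genome, config: SimulationConfig,
                               n_fragments: int = 2000, read_len: int = 100,
                               frag_len_range=(150, 280),
                               duplicate_rate: float = 0.0,
                               chrom: str | None = None) -> List[ReadObservation]:
    regions = active_regions(genome, config)
    mu = _mean_field(genome, config, regions)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    chrom = chrom or genome.chroms[0]
    pos = genome.cpg_positions[chrom]
    size = genome.chrom_sizes[chrom]
    reads: List[ReadObservation] = []
    frag_id = 0
    for _ in range(n_fragments):
        flen = int(rng.integers(*frag_len_range))
        s = int(rng.integers(0, size - flen))
        lo, hi = np.searchsorted(pos, s), np.searchsorted(pos, s + flen)
        frag_calls = [(int(p), bool(rng.random() < m))
                      for p, m in zip(pos[lo:hi], mu[chrom][lo:hi])]
        n_copies = 1 + (rng.random() < duplicate_rate) * int(rng.integers(1, 4))
        for copy in range(n_copies):
            mid = f"{chrom}.frag{frag_id:07d}" + (f".dup{copy}" if copy else "")
            m1 = ReadObservation(
                read_id=mid + "/1", mate_id=mid, chrom=chrom,
                start=s, end=s + read_len, strand="+", repair_end="3p",
                calls=tuple(c for c in frag_calls if s <= c[0] < s + read_len))
            m2_start = s + flen - read_len
            m2 = ReadObservation(
                read_id=mid + "/2", mate_id=mid, chrom=chrom,
                start=m2_start, end=s + flen, strand="-", repair_end="3p",
                calls=tuple(c for c in frag_calls if m2_start <= c[0] < s + flen))
            reads.extend([m1, m2])
        frag_id += 1
    return reads
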