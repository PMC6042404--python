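"""Expression simulation: per-gene FPKM across the four genotypes with seven
planted response archetypes.

Archetype shift patterns (in units of ``deg_log2_effect``, order
WT / Dnmt3aKO / Tet1KO / DKO):

==  =================================  ==========================
C1  (0, +1, +1, +2)                    up in both knockouts, additive
C2  (0,  0, +1, +1)                    up, Tet1KO-specific
C3  (0, +1,  0, +1)                    up, Dnmt3aKO-specific
C4  (0, -1,  0, -1)                    down, Dnmt3aKO-specific
C5  (0, -1, -1, -2)                    down in both, additive
C6  (0,  0, -1, -1)                    down, Tet1KO-specific
C7  (0, -1,  0,  0)                    down in Dnmt3aKO, restored in DKO
==  =================================  ==========================

Non-archetype genes have exchangeable condition means (noise only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from ..config import SimulationConfig, ConfigurationError, CONDITIONS
from .genome import Genome, DEG_CLUSTERS

ARCHETYPE_SHIFTS: Dict[str, np.ndarray] = {
    "C1": np.array([0.0, 1.0, 1.0, 2.0]),
    "C2": np.array([0.0, 0.0, 1.0, 1.0]),
    "C3": np.array([0.0, 1.0, 0.0, 1.0]),
    "C4": np.array([0.0, -1.0, 0.0, -1.0]),
    "C5": np.array([0.0, -1.0, -1.0, -2.0]),
    "C6": np.array([0.0, 0.0, -1.0, -1.0]),
    "C7": np.array([0.0, -1.0, 0.0, 0.0]),
}


@dataclass
class ExpressionGroundTruth:
    labels: pd.Series            # gene_id -> archetype label or "none"
    log2_effect: float


def simulate_expression(genome: Genome, config: SimulationConfig):
    """Per-gene FPKM for WT, Dnmt3aKO, Tet1KO and DKO.

    Returns ``(table, truth)`` where ``table`` has one row per gene with
    FPKM columns per condition and a ``de_label`` column (archetype or
    "none"). With a zero effect size no gene is differentially expressed
    and every label is "none".
    """
    genes = genome.genes
    if len(genes) < len(DEG_CLUSTERS):
        raise ConfigurationError("n_genes: fewer genes than expression clusters")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    n = len(genes)
    base = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n)
    noise = (rng.normal(0.0, config.expr_noise_sd, size=(n, 4))
             if config.expr_noise_sd > 0 else np.zeros((n, 4)))
    labels = genes["deg_cluster"].to_numpy(dtype=object).copy()
    a = config.deg_log2_effect
    if a == 0:
        labels[:] = "none"
    log2 = base[:, None] + noise
    for i, lab in enumerate(labels):
        if lab != "none":
            log2[i] += a * ARCHETYPE_SHIFTS[lab]
    table = pd.DataFrame(2.0 ** log2, columns=list(CONDITIONS))
    table.insert(0, "gene_id", genes["gene_id"].to_numpy())
    table["de_label"] = labels
    truth = ExpressionGroundTruth(
        labels=pd.Series(labels, index=genes["gene_id"].to_numpy()),
        log2_effect=a)
    return table, truth
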