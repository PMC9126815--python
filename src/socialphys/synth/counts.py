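"""Negative-binomial count tables with planted differential expression.

Emulates the FACS design of the transcriptomic experiment: four cell
populations (D1R-tom+/− crossed with infected/non-infected) times two
conditions (scrambled vs knock-down virus), a few replicates per cell.
A chosen fraction of genes carries a planted log2 fold change in the
knock-down condition of designated population(s); the truth labels let
selection sensitivity and specificity be measured exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..transcripts import CountTable

DEFAULT_POPULATIONS = ("D1pos", "D1neg")
DEFAULT_INFECTIONS = ("infected", "noninfected")
DEFAULT_CONDITIONS = ("scr", "sh")


@dataclass
class SyntheticCountDesign:
    """Parameters of the simulated sequencing experiment."""

    n_genes: int = 2000
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    infections: tuple[str, ...] = DEFAULT_INFECTIONS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_cell: int = 2
    de_fraction: float = 0.05
    log2fc_range: tuple[float, float] = (1.0, 2.0)
    dispersion: float = 0.05           # NB: var = µ + dispersion·µ²
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)  # RPM
    library_size_range: tuple[float, float] = (0.8e6, 1.2e6)
    de_populations: tuple[str, ...] = ("D1pos",)   # where the effect lives
    de_infections: tuple[str, ...] = ("infected",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.replicates_per_cell < 2:
            raise ValueError("worst-case selection needs >= 2 replicates per cell")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def simulate_counts(design: SyntheticCountDesign) -> tuple[CountTable, pd.DataFrame]:
    """Draw a count table and the planted-truth gene labels.

    Gene baselines (in RPM units) are log-uniform over
    ``baseline_mean_range``; per-sample expected counts scale with the
    library size drawn uniformly from ``library_size_range``.  DE genes
    multiply their mean by 2^(±log2fc) — sign drawn per gene — in the
    ``sh`` condition of the designated population/infection cells.
    Counts are negative binomial with var = µ + dispersion·µ²; a zero
    dispersion degenerates to rounded means (deterministic).

    Returns the table and a truth DataFrame indexed by gene with
    columns ``is_de``, ``log2fc`` (signed, 0 for null genes).
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"gene{i:05d}" for i in range(design.n_genes)]
    lo, hi = design.baseline_mean_range
    base_rpm = np.exp(rng.uniform(np.log(lo), np.log(hi), design.n_genes))

    n_de = int(round(design.de_fraction * design.n_genes))
    if design.de_fraction > 0 and n_de < 1:
        warnings.warn("de_fraction×n_genes < 1: no genes planted")
    de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
    l2fc = np.zeros(design.n_genes)
    if n_de:
        mags = rng.uniform(*design.log2fc_range, n_de)
        signs = rng.choice([-1.0, 1.0], n_de)
        l2fc[de_idx] = mags * signs

    sample_rows = []
    col_means = {}
    for pop in design.populations:
        for inf in design.infections:
            for cond in design.conditions:
                for rep in range(1, design.replicates_per_cell + 1):
                    sid = f"{pop}_{inf}_{cond}_r{rep}"
                    sample_rows.append({"sample_id": sid, "population": pop,
                                        "infection": inf, "condition": cond,
                                        "replicate": rep})
                    mean_rpm = base_rpm.copy()
                    if (cond == "sh" and pop in design.de_populations
                            and inf in design.de_infections):
                        mean_rpm = mean_rpm * 2.0 ** l2fc
                    lib = rng.uniform(*design.library_size_range)
                    col_means[sid] = mean_rpm / 1e6 * lib

    counts = {}
    for sid, mu in col_means.items():
        if design.dispersion == 0:
            counts[sid] = np.round(mu).astype(int)
        else:
            # NB(mean µ, var µ + αµ²): n = 1/α, p = n/(n + µ)
            n_shape = 1.0 / design.dispersion
            counts[sid] = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))
    counts_df = pd.DataFrame(counts, index=genes)
    samples_df = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = pd.DataFrame({"is_de": l2fc != 0, "log2fc": l2fc}, index=genes)
    return CountTable(counts=counts_df, samples=samples_df), truth
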