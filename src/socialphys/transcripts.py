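"""Bulk count-table analysis around the worst-case fold-change selection.

The pipeline normalizes gene×sample read counts to reads per million
(RPM), filters to genes expressed above 10 RPM, and selects
differentially expressed genes by a conservative "worst-case scenario"
rule: over every cross-condition replicate pair, keep the pair giving
the minimum fold change, and select the gene only when that minimum
fold change still clears the threshold (1.5-fold) with all pairs
agreeing in direction.  Downstream: set intersections across cell
populations, PCA on transformed RPM, Fisher enrichment against curated
gene lists (e.g. SFARI autism genes), and ΔΔCt quantification for qPCR
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class CountTable:
    """Gene×sample integer read counts plus per-sample metadata.

    ``counts`` is a DataFrame indexed by gene id with one column per
    sample; ``samples`` is indexed by sample id with columns
    ``population`` (e.g. D1pos/D1neg), ``infection``, ``condition``
    (scr/sh) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.samples.index):
            raise ValueError("metadata must cover every sample column")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids matching all metadata criteria, e.g. condition='sh'."""
        sel = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            sel &= self.samples[key] == val
        return [s for s in self.counts.columns if sel.get(s, False)]


@dataclass
class WcfcResult:
    """Worst-case fold-change selection for one condition contrast."""

    table: pd.DataFrame  # gene, wcfc, direction, selected, pair
    threshold: float
    group_a: list[str]
    group_b: list[str]

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


@dataclass
class EnrichmentResult:
    """Fisher exact test of a selection against an annotation set."""

    table: np.ndarray  # 2×2: [[sel∩ann, sel∖ann], [ann∖sel, rest]]
    odds_ratio: float
    p_value: float
    alternative: str = "greater"


# ---------------------------------------------------------------------------


def rpm_normalize(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization: counts / column total × 10⁶."""
    counts = table.counts if isinstance(table, CountTable) else table
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return counts / totals * 1e6


def filter_expressed(rpm: pd.DataFrame, min_rpm: float = 10.0,
                     rule: str = "all") -> pd.DataFrame:
    """Keep genes strictly above ``min_rpm`` under the chosen rule.

    rule = 'all': above threshold in every sample (strictest);
    'any': in at least one sample; 'mean': on the sample mean.
    The comparison is strict (> min_rpm), so a gene at exactly 10 RPM
    is removed.
    """
    above = rpm > min_rpm
    if rule == "all":
        keep = above.all(axis=1)
    elif rule == "any":
        keep = above.any(axis=1)
    elif rule == "mean":
        keep = rpm.mean(axis=1) > min_rpm
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return rpm.loc[keep]


def worst_case_fc(rpm: pd.DataFrame, group_a: list[str], group_b: list[str],
                  threshold: float = 1.5, pseudocount: float = 0.0) -> WcfcResult:
    """Worst-case-scenario fold-change selection between two groups.

    For each gene, every cross-group replicate pair (i ∈ A, j ∈ B)
    yields a ratio r_ij = (b_j + ε)/(a_i + ε).  The gene's direction is
    concordant only when all ratios fall on the same side of 1; its
    worst-case fold change is then the minimum over pairs of
    max(r_ij, 1/r_ij), i.e. the fold change of the least favourable
    replicate pairing.  A gene is selected when it is concordant and the
    worst-case fold change is at least ``threshold``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("worst-case selection needs >= 2 replicates per group")
    a = rpm[group_a].to_numpy() + pseudocount
    b = rpm[group_b].to_numpy() + pseudocount
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("non-positive values: use a pseudocount or pre-filter")
    # ratios for all cross pairs: shape (genes, |A|, |B|)
    ratios = b[:, None, :] / a[:, :, None]
    up = (ratios > 1).all(axis=(1, 2))
    down = (ratios < 1).all(axis=(1, 2))
    mag = np.maximum(ratios, 1.0 / ratios)
    flat = mag.reshape(mag.shape[0], -1)
    argmin = flat.argmin(axis=1)
    wcfc = flat[np.arange(flat.shape[0]), argmin]
    wcfc = np.where(up | down, wcfc, 1.0)  # discordant: worst case is no change
    direction = np.where(up, "up", np.where(down, "down", "discordant"))
    selected = (up | down) & (wcfc >= threshold)
    pairs = [f"{group_a[i]}|{group_b[j]}"
             for i, j in zip(argmin // len(group_b), argmin % len(group_b))]
    tbl = pd.DataFrame({"wcfc": wcfc, "direction": direction,
                        "selected": selected, "pair": pairs}, index=rpm.index)
    return WcfcResult(table=tbl, threshold=threshold,
                      group_a=list(group_a), group_b=list(group_b))


def intersect_de(results: dict[str, WcfcResult]) -> dict[str, object]:
    """Shared and unique selected genes across populations.

    Returns the pairwise/overall intersection, per-population unique
    sets, the union, and for the intersection whether directions agree.
    """
    universes = [set(r.table.index) for r in results.values()]
    common_universe = set.intersection(*universes)
    if not common_universe:
        raise ValueError("results share no genes: disjoint universes")
    sel = {name: set(r.selected) for name, r in results.items()}
    shared = set.intersection(*sel.values()) if sel else set()
    union = set.union(*sel.values()) if sel else set()
    unique = {name: s - set.union(*(o for n, o in sel.items() if n != name))
              if len(sel) > 1 else s
              for name, s in sel.items()}
    agree = {}
    for g in shared:
        dirs = {results[name].table.loc[g, "direction"] for name in results}
        agree[g] = len(dirs) == 1
    return {"shared": shared, "union": union, "unique": unique,
            "direction_agrees": agree}


def pca_transform(rpm: pd.DataFrame, n_components: int | None = None,
                  transform: str = "log2") -> dict[str, object]:
    """PCA of samples over the selected genes.

    Genes are variance-stabilized with log2(x + 1) (a light-weight
    stand-in for a regularized log transform) and centred; components
    come from the singular decomposition of the gene-centred matrix.
    Returns sample scores and explained-variance fractions.
    """
    if rpm.shape[0] < 2 or rpm.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 samples")
    x = np.log2(rpm.to_numpy() + 1.0) if transform == "log2" else rpm.to_numpy()
    x = x.T  # samples × genes
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("constant matrix: PCA degenerate")
    n_components = n_components or min(x.shape)
    pca = PCA(n_components=min(n_components, min(x.shape)))
    scores = pca.fit_transform(x)
    return {"scores": pd.DataFrame(scores, index=rpm.columns,
                                   columns=[f"PC{i+1}" for i in range(scores.shape[1])]),
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "transform": transform}


def fisher_enrichment(selected: set, annotation: set, universe: set,
                      alternative: str = "greater") -> EnrichmentResult:
    """Fisher exact test of overlap between a selection and a gene set.

    The 2×2 table splits the universe by (selected, annotated); the
    default one-sided alternative tests for enrichment.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe or not annotation <= universe:
        raise ValueError("selected and annotation must be subsets of the universe")
    k = len(selected & annotation)
    table = np.array([[k, len(selected) - k],
                      [len(annotation) - k,
                       len(universe) - len(selected) - len(annotation) + k]])
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return EnrichmentResult(table=table, odds_ratio=float(odds),
                            p_value=float(p), alternative=alternative)


def delta_delta_ct(ct: pd.DataFrame, target: str, reference: str,
                   group_col: str, control_group: str) -> pd.DataFrame:
    """Relative qPCR quantification by the ΔΔCt method.

    ``ct`` has one row per sample with Ct columns per gene and a group
    column.  ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts
    the control-group mean ΔCt; relative expression = 2^(−ΔΔCt).
    """
    for col in (target, reference, group_col):
        if col not in ct.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.isfinite(ct[[target, reference]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    dct = ct[target] - ct[reference]
    control = dct[ct[group_col] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} has no samples")
    ddct = dct - control.mean()
    out = ct[[group_col]].copy()
    out["delta_ct"] = dct
    out["delta_delta_ct"] = ddct
    out["rel_expression"] = 2.0 ** (-ddct)
    return out
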