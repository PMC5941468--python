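"""Correlation-module detection on post-timepoint expression.

A deliberately small stand-in for full weighted co-expression network
analysis: adjacency |r|^power, dissimilarity 1 - adjacency, average-linkage
hierarchical clustering with a static cut, small clusters dissolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .enrichment import EnrichmentResult, permutation_enrichment


class CoexpressionError(ValueError):
    pass


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene id -> module label, 0 = unassigned
    sizes: dict[int, int]
    intra_cor: dict[int, float]  # mean intra-module |r| per module
    inter_cor: float  # mean |r| across module boundaries (NaN if < 2 modules)

    @property
    def n_modules(self) -> int:
        return len(self.sizes)

    def genes(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    expr: pd.DataFrame,
    gene_subset: list[str] | None = None,
    power: float = 6.0,
    min_size: int = 30,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Cluster genes into correlation modules.

    ``cut_height`` defaults to 0.98 of the maximum merge height.  Clusters
    smaller than ``min_size`` are dissolved to label 0.  Module labels are
    assigned 1, 2, ... in decreasing size order.
    """
    if gene_subset is None:
        gene_subset = list(expr.columns)
    missing = [g for g in gene_subset if g not in expr.columns]
    if missing:
        raise CoexpressionError(f"genes absent from expression: {missing[:10]}")
    if len(expr) < 3:
        raise CoexpressionError("need >= 3 samples")
    if len(gene_subset) < min_size:
        warnings.warn("gene subset smaller than min module size; all unassigned")
        return ModuleAssignment(
            labels=pd.Series(0, index=pd.Index(gene_subset, name="gene_id")),
            sizes={},
            intra_cor={},
            inter_cor=float("nan"),
        )
    x = expr[gene_subset].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    adj = np.abs(corr) ** power
    dissim = 1.0 - adj
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    link = hierarchy.linkage(squareform(dissim, checks=False), method="average")
    height = cut_height if cut_height is not None else 0.98 * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=height, criterion="distance")
    labels = np.zeros(len(gene_subset), dtype=int)
    next_label = 1
    sizes: dict[int, int] = {}
    order = sorted(
        np.unique(raw), key=lambda c: -(raw == c).sum()
    )
    for c in order:
        members = raw == c
        if members.sum() >= min_size:
            labels[members] = next_label
            sizes[next_label] = int(members.sum())
            next_label += 1
    series = pd.Series(labels, index=pd.Index(gene_subset, name="gene_id"))
    abs_corr = np.abs(corr)
    intra: dict[int, float] = {}
    for mod in sizes:
        idx = np.where(labels == mod)[0]
        block = abs_corr[np.ix_(idx, idx)]
        off = block[~np.eye(len(idx), dtype=bool)]
        intra[mod] = float(off.mean())
    inter = float("nan")
    if len(sizes) >= 2:
        vals = []
        mods = list(sizes)
        for i, mi in enumerate(mods):
            for mj in mods[i + 1 :]:
                vals.append(
                    abs_corr[np.ix_(np.where(labels == mi)[0], np.where(labels == mj)[0])].ravel()
                )
        inter = float(np.concatenate(vals).mean())
    return ModuleAssignment(labels=series, sizes=sizes, intra_cor=intra, inter_cor=inter)


def module_enrichment(
    modules: ModuleAssignment,
    er_set: set[str] | list[str],
    universe: list[str],
    n_perm: int = 500_000,
    mode: str = "literal",
    seed: int | None = None,
) -> dict[int, EnrichmentResult]:
    """Gene-set over-representation per detected module (labels > 0),
    universe = expressed genes."""
    out: dict[int, EnrichmentResult] = {}
    for mod in sorted(modules.sizes):
        out[mod] = permutation_enrichment(
            modules.genes(mod),
            er_set,
            universe,
            n_perm=n_perm,
            mode=mode,
            seed=seed,
            name=f"module_{mod}",
        )
    return out
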