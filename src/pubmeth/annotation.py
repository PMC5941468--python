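"""Probe-to-gene annotation: nearest TSS assignment and region categories.

Coordinates are 1-based at the I/O boundary (array-manifest convention);
interval arithmetic internally treats gene bodies as closed [start, end].
The TSS of a gene is its start on the ``+`` strand and its end on the ``-``
strand.  Signed probe-TSS distances are negative when the probe lies
upstream of the TSS relative to the gene's strand.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGION_CATEGORIES = ("TSS200", "TSS1500", "Body", "Intergenic")

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


class AnnotationError(ValueError):
    """Raised when probes cannot be annotated against the gene model."""


def validate_gene_model(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-model table and return it with a ``tss`` column added."""
    missing = [c for c in GENE_MODEL_COLUMNS if c not in genes.columns]
    if missing:
        raise AnnotationError(f"gene model missing columns: {missing}")
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene_id"].tolist()
        raise AnnotationError(f"gene start > end for: {bad}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise AnnotationError("strand must be '+' or '-'")
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    return genes


def nearest_tss(
    position: int, chrom: str, genes: pd.DataFrame
) -> tuple[str | None, int | None]:
    """Return ``(gene_id, signed_distance)`` of the TSS closest to a probe.

    Distance is minimised in absolute value over all genes on the probe's
    chromosome, ignoring strand for the minimisation itself.  Ties are broken
    toward the lexicographically smaller gene id.  The returned distance is
    signed: negative means the probe is upstream of the TSS in the gene's
    reading direction.

    Returns ``(None, None)`` when no gene lies on the chromosome.
    """
    genes = validate_gene_model(genes)
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None, None
    absd = (sub["tss"] - position).abs()
    best = absd.min()
    candidates = sub.loc[absd == best].sort_values("gene_id")
    row = candidates.iloc[0]
    return row["gene_id"], _signed_distance(position, int(row["tss"]), row["strand"])


def _signed_distance(position: int, tss: int, strand: str) -> int:
    if strand == "+":
        return int(position - tss)
    return int(tss - position)


def region_category(position: int, gene_row: pd.Series) -> str:
    """Classify a probe relative to its nearest gene.

    Order of precedence: TSS200 (within 200 bp upstream, inclusive, or at
    the TSS), TSS1500 (201-1500 bp upstream), Body (within [start, end]),
    else Intergenic.
    """
    tss = int(gene_row["tss"]) if "tss" in gene_row else (
        int(gene_row["start"]) if gene_row["strand"] == "+" else int(gene_row["end"])
    )
    signed = _signed_distance(int(position), tss, gene_row["strand"])
    if -200 <= signed <= 0:
        return "TSS200"
    if -1500 <= signed < -200:
        return "TSS1500"
    if int(gene_row["start"]) <= int(position) <= int(gene_row["end"]):
        return "Body"
    return "Intergenic"


def annotate_probes(
    probes: pd.DataFrame,
    genes: pd.DataFrame,
    multi_map: pd.Series | None = None,
    snp_overlap: pd.Series | None = None,
) -> pd.DataFrame:
    """Build a full probe-annotation table.

    Parameters
    ----------
    probes
        Table with columns ``probe_id``, ``chrom``, ``position`` (1-based).
    genes
        Gene-model table (see :data:`GENE_MODEL_COLUMNS`).
    multi_map, snp_overlap
        Optional boolean series indexed by probe id; default all-False.

    Returns
    -------
    DataFrame indexed by probe id with columns chrom, position, multi_map,
    snp_overlap, nearest_gene, tss_distance, region.
    """
    genes = validate_gene_model(genes)
    out_gene: list[str | None] = []
    out_dist: list[float] = []
    out_region: list[str] = []
    # vectorised per chromosome via sorted TSS search
    by_chrom = {c: g.sort_values("tss").reset_index(drop=True) for c, g in genes.groupby("chrom")}
    gene_lookup = genes.set_index("gene_id")
    for _, prow in probes.iterrows():
        chrom, pos = prow["chrom"], int(prow["position"])
        sub = by_chrom.get(chrom)
        if sub is None:
            out_gene.append(None)
            out_dist.append(np.nan)
            out_region.append("Intergenic")
            continue
        tss = sub["tss"].to_numpy()
        j = np.searchsorted(tss, pos)
        cand_idx = [k for k in (j - 1, j, j + 1) if 0 <= k < len(sub)]
        cand = sub.iloc[cand_idx]
        absd = (cand["tss"] - pos).abs()
        best = absd.min()
        # equal-|distance| TSS positions elsewhere in the sorted frame can
        # only occur at the same coordinate, which the +-1 window covers
        winners = sub.loc[(sub["tss"] - pos).abs() == best].sort_values("gene_id")
        row = winners.iloc[0]
        out_gene.append(row["gene_id"])
        out_dist.append(_signed_distance(pos, int(row["tss"]), row["strand"]))
        out_region.append(region_category(pos, gene_lookup.loc[row["gene_id"]]))
    ann = pd.DataFrame(
        {
            "chrom": probes["chrom"].to_numpy(),
            "position": probes["position"].to_numpy(),
            "nearest_gene": out_gene,
            "tss_distance": out_dist,
            "region": out_region,
        },
        index=pd.Index(probes["probe_id"], name="probe_id"),
    )
    ann["multi_map"] = False if multi_map is None else multi_map.reindex(ann.index).fillna(False)
    ann["snp_overlap"] = (
        False if snp_overlap is None else snp_overlap.reindex(ann.index).fillna(False)
    )
    return ann


def genes_near_dmps(dmp_probes: Sequence[str], ann: pd.DataFrame) -> list[str]:
    """Deduplicated nearest-gene list for a set of probes, stable order.

    Raises :class:`AnnotationError` if any probe is absent from ``ann`` or
    has no nearest gene.
    """
    missing = [p for p in dmp_probes if p not in ann.index]
    if missing:
        raise AnnotationError(f"probes missing from annotation: {missing[:10]}")
    seen: dict[str, None] = {}
    for p in dmp_probes:
        g = ann.loc[p, "nearest_gene"]
        if g is None or (isinstance(g, float) and np.isnan(g)):
            raise AnnotationError(f"probe {p} has no nearest gene")
        seen.setdefault(g, None)
    return list(seen)
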