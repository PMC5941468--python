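"""Confound checks: cell-composition change tests, methylation-vs-cell
correlations, cis methylation-expression correlation, and ancestry-style
subset sensitivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import DeltaMatrix, bh_fdr


class ConfoundsError(ValueError):
    pass


@dataclass
class CellCompositionTestResult:
    cell_type: str
    statistic: float | None
    p_value: float
    direction: str  # 'increase' | 'decrease' | 'none'
    note: str = ""


def _paired_cell_deltas(sheet: pd.DataFrame, cell_type: str) -> pd.Series:
    if cell_type not in sheet.columns:
        raise ConfoundsError(f"cell type {cell_type!r} not in sample sheet")
    pre = sheet[sheet["timepoint"] == "pre"].set_index("individual_id")[cell_type]
    post = sheet[sheet["timepoint"] == "post"].set_index("individual_id")[cell_type]
    common = pre.index.intersection(post.index)
    return (post.loc[common] - pre.loc[common]).sort_index()


def paired_cell_test(sheet: pd.DataFrame, cell_type: str) -> CellCompositionTestResult:
    """Wilcoxon signed-rank test of pre-vs-post proportions (two-sided)."""
    diffs = _paired_cell_deltas(sheet, cell_type)
    if len(diffs) < 6:
        raise ConfoundsError(f"need >= 6 paired individuals, got {len(diffs)}")
    mean_diff = float(diffs.mean())
    direction = "increase" if mean_diff > 0 else ("decrease" if mean_diff < 0 else "none")
    if (diffs == 0).all():
        return CellCompositionTestResult(cell_type, None, 1.0, "none", "all differences zero")
    stat, p = stats.wilcoxon(diffs.to_numpy())
    return CellCompositionTestResult(cell_type, float(stat), float(p), direction)


def delta_cell_correlation(
    delta: DeltaMatrix,
    sheet: pd.DataFrame,
    cell_types: tuple[str, ...] = ("lymphocyte", "monocyte", "eosinophil"),
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of per-probe delta-beta against each cell-type
    proportion change, with BH flags per cell type.

    Average ranks handle ties; p-values use the t approximation on the rank
    correlation.  Constant cell deltas are marked not testable.
    """
    values = delta.values
    if len(values) < 6:
        raise ConfoundsError("need >= 6 individuals")
    frames = []
    x = values.to_numpy(dtype=float)
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    rx = rx - rx.mean(axis=0, keepdims=True)
    n = len(values)
    for ct in cell_types:
        cd = _paired_cell_deltas(sheet, ct).reindex(values.index)
        if cd.isna().any():
            raise ConfoundsError(f"missing {ct} deltas for some individuals")
        if cd.nunique() <= 1:
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": values.columns,
                        "cell_type": ct,
                        "rho": np.nan,
                        "p_value": np.nan,
                        "testable": False,
                        "flagged": False,
                    }
                )
            )
            continue
        ry = stats.rankdata(cd.to_numpy())
        ry = ry - ry.mean()
        denom = np.sqrt((rx**2).sum(axis=0)) * np.sqrt((ry**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (rx * ry[:, None]).sum(axis=0) / denom
        rho = np.clip(rho, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p = np.where(np.isnan(p), np.where(np.abs(rho) >= 1.0, 0.0, np.nan), p)
        q = bh_fdr(np.nan_to_num(p, nan=1.0))
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": values.columns,
                    "cell_type": ct,
                    "rho": rho,
                    "p_value": p,
                    "testable": True,
                    "flagged": q <= fdr_level,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class CisCorrelationResult:
    pairs: pd.DataFrame  # probe_id, gene_id, r, p_value, flagged
    n_tested: int
    n_excluded: int  # probes whose nearest gene is not expressed
    fraction_flagged: float


def cis_correlation(
    beta_post: pd.DataFrame,
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    dmp_probes: list[str],
    alpha: float = 0.05,
) -> CisCorrelationResult:
    """Pearson correlation of each DMP probe's post-timepoint beta with its
    nearest gene's expression, over matched samples."""
    common = beta_post.index.intersection(expr.index)
    if len(common) == 0:
        raise ConfoundsError("no matched samples between methylation and expression")
    rows = []
    excluded = 0
    expressed = set(expr.columns)
    for p in dmp_probes:
        gene = ann.loc[p, "nearest_gene"] if p in ann.index else None
        if gene is None or gene not in expressed or p not in beta_post.columns:
            excluded += 1
            continue
        b = beta_post.loc[common, p].to_numpy(dtype=float)
        e = expr.loc[common, gene].to_numpy(dtype=float)
        if (b == b[0]).all() or (e == e[0]).all():
            excluded += 1
            continue
        r, pv = stats.pearsonr(b, e)
        rows.append({"probe_id": p, "gene_id": gene, "r": float(r), "p_value": float(pv)})
    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "r", "p_value"])
    pairs["flagged"] = pairs["p_value"] < alpha if len(pairs) else pd.Series(dtype=bool)
    n = len(pairs)
    frac = float(pairs["flagged"].mean()) if n else 0.0
    return CisCorrelationResult(pairs=pairs, n_tested=n, n_excluded=excluded, fraction_flagged=frac)


def subset_sensitivity(
    delta: DeltaMatrix, exclude_ids: list[str], dmp_probes: list[str]
) -> float:
    """Pearson r between full-sample and subset per-probe mean delta-beta
    over the DMP probes."""
    if not dmp_probes:
        raise ConfoundsError("empty DMP probe list")
    keep = [i for i in delta.values.index if i not in set(exclude_ids)]
    if len(keep) < 3:
        raise ConfoundsError("exclusion leaves fewer than 3 individuals")
    full = delta.values[dmp_probes].mean(axis=0)
    sub = delta.values.loc[keep, dmp_probes].mean(axis=0)
    if len(dmp_probes) < 2:
        raise ConfoundsError("need >= 2 probes for a correlation")
    if len(keep) == len(delta.values):
        return 1.0
    r, _ = stats.pearsonr(full.to_numpy(), sub.to_numpy())
    return float(r)
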