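"""Unsupervised puberty-status classification from a CpG predictor panel.

Samples (both timepoints stacked) are clustered on the panel's beta values
with agglomerative clustering cut at k=2; clusters are oriented against
known status to maximise balanced accuracy, then scored as a confusion
matrix with post-puberty as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


class ClassifierError(ValueError):
    pass


@dataclass
class PanelDefinition:
    name: str
    probes: list[str]
    provenance: str = ""

    def intersect(self, available: list[str] | pd.Index) -> "PanelDefinition":
        present = [p for p in self.probes if p in set(available)]
        return PanelDefinition(name=self.name, probes=present, provenance=self.provenance)


@dataclass
class ClassifierResult:
    predicted: pd.Series  # sample -> 'pre' | 'post'
    mapping: dict[int, str]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None  # percent, one decimal; None if undefined
    specificity: float | None
    linkage: str
    metric: str

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "linkage": self.linkage,
            "metric": self.metric,
            "cluster_mapping": {str(k): v for k, v in self.mapping.items()},
        }


def hclust_classify(
    beta: pd.DataFrame,
    panel: PanelDefinition,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> pd.Series:
    """Cluster samples on panel probes, cut at k=2.

    Returns integer cluster labels (1/2) indexed by sample id; deterministic
    given inputs.
    """
    panel = panel.intersect(beta.columns)
    if len(panel.probes) < 2:
        raise ClassifierError("fewer than 2 panel probes present in the matrix")
    if len(beta) < 4:
        raise ClassifierError("need >= 4 samples")
    x = beta[panel.probes].to_numpy(dtype=float)
    link = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    labels = hierarchy.fcluster(link, t=2, criterion="maxclust")
    return pd.Series(labels, index=beta.index, name="cluster")


def assign_cluster_labels(
    clusters: pd.Series,
    truth: pd.Series,
    ages: pd.Series | None = None,
) -> dict[int, str]:
    """Orient k=2 clusters to {pre, post} maximising balanced accuracy.

    Exact ties are broken by mapping the higher-mean-age cluster to post
    when ages are available, else by cluster label order.
    """
    levels = sorted(clusters.unique())
    if len(levels) != 2:
        raise ClassifierError(f"expected 2 clusters, got {len(levels)}")
    truth = truth.reindex(clusters.index)
    best_map: dict[int, str] | None = None
    best_score = -1.0
    candidates = []
    for assn in permutations(["pre", "post"]):
        mapping = dict(zip(levels, assn))
        pred = clusters.map(mapping)
        score = _balanced_accuracy(pred, truth)
        candidates.append((score, mapping))
        if score > best_score:
            best_score, best_map = score, mapping
    scores = [s for s, _ in candidates]
    if abs(scores[0] - scores[1]) < 1e-12 and ages is not None:
        ages = ages.reindex(clusters.index)
        mean_age = {lv: float(ages[clusters == lv].mean()) for lv in levels}
        older = max(levels, key=lambda lv: mean_age[lv])
        younger = min(levels, key=lambda lv: mean_age[lv])
        best_map = {older: "post", younger: "pre"}
    assert best_map is not None
    return best_map


def _balanced_accuracy(pred: pd.Series, truth: pd.Series) -> float:
    accs = []
    for cls in ("pre", "post"):
        mask = truth == cls
        if mask.sum() == 0:
            continue
        accs.append(float((pred[mask] == cls).mean()))
    return float(np.mean(accs)) if accs else 0.0


def confusion_metrics(
    predicted: pd.Series,
    truth: pd.Series,
    positive: str = "post",
    linkage: str = "complete",
    metric: str = "euclidean",
    mapping: dict[int, str] | None = None,
) -> ClassifierResult:
    """Confusion counts plus sensitivity/specificity in percent (1 decimal).

    Metrics are None when the corresponding truth class is absent.
    """
    truth = truth.reindex(predicted.index)
    if len(predicted) != len(truth):
        raise ClassifierError("length mismatch")
    pos_t = truth == positive
    pos_p = predicted == positive
    tp = int((pos_p & pos_t).sum())
    fp = int((pos_p & ~pos_t).sum())
    tn = int((~pos_p & ~pos_t).sum())
    fn = int((~pos_p & pos_t).sum())
    sens = round(100.0 * tp / (tp + fn), 1) if (tp + fn) else None
    spec = round(100.0 * tn / (tn + fp), 1) if (tn + fp) else None
    return ClassifierResult(
        predicted=predicted,
        mapping=mapping or {},
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        linkage=linkage,
        metric=metric,
    )


def classify_samples(
    beta: pd.DataFrame,
    panel: PanelDefinition,
    status: pd.Series,
    ages: pd.Series | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
    positive: str = "post",
) -> ClassifierResult:
    """End-to-end: cluster, orient, score."""
    clusters = hclust_classify(beta, panel, linkage=linkage, metric=metric)
    mapping = assign_cluster_labels(clusters, status.reindex(clusters.index), ages)
    predicted = clusters.map(mapping)
    return confusion_metrics(
        predicted, status, positive=positive, linkage=linkage, metric=metric, mapping=mapping
    )


def panel_overlap(panel: PanelDefinition, dmp_sets: dict[str, list[str]]) -> dict[str, dict]:
    """|panel ∩ set| and percentage of the panel, per DMP set."""
    panel_set = set(panel.probes)
    n = len(panel.probes)
    out = {}
    for name, probes in dmp_sets.items():
        k = len(panel_set & set(probes))
        out[name] = {
            "overlap": k,
            "panel_size": n,
            "pct_of_panel": round(100.0 * k / n, 1) if n else 0.0,
        }
    return out
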