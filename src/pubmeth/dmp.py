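"""Paired, sex-stratified differential methylation with empirical-Bayes
variance moderation.

The paired two-timepoint random-intercept design collapses exactly to a
one-sample analysis of within-individual differences, and the sex-by-age
interaction to a two-sample comparison of those differences; both use a
moderated t statistic whose per-probe variance is shrunk toward a
scaled-inverse-chi-square prior fitted across probes by method of moments
on log sample variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


class DMPError(ValueError):
    pass


@dataclass(frozen=True)
class ModerationPrior:
    """Hyperparameters of the variance prior: prior df d0 (possibly inf)
    and prior variance s0^2.  d0=0 is accepted as an explicit
    no-moderation request and reduces the tests to their classical forms."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise DMPError("prior df must be nonnegative")
        if not (self.s0_sq > 0):
            raise DMPError("prior variance must be positive")


@dataclass
class DeltaMatrix:
    """Within-individual post-minus-pre differences plus per-individual sex."""

    values: pd.DataFrame  # individuals x probes
    sex: pd.Series  # indexed by individual

    def subset(self, sex: str) -> "DeltaMatrix":
        keep = self.sex.index[self.sex == sex]
        return DeltaMatrix(self.values.loc[keep], self.sex.loc[keep])


def paired_delta(
    pre: pd.DataFrame, post: pd.DataFrame, sheet: pd.DataFrame
) -> DeltaMatrix:
    """Per-individual difference beta(post) - beta(pre).

    Probe set is the intersection of the two matrices (original pre-matrix
    order).  Every individual must appear at exactly one pre and one post
    sample; violations raise naming the individual.
    """
    probes = [p for p in pre.columns if p in set(post.columns)]
    by_tp: dict[str, dict[str, str]] = {"pre": {}, "post": {}}
    for sid, row in sheet.iterrows():
        if sid in pre.index and row["timepoint"] == "pre":
            by_tp["pre"][row["individual_id"]] = sid
        if sid in post.index and row["timepoint"] == "post":
            by_tp["post"][row["individual_id"]] = sid
    individuals = sorted(set(by_tp["pre"]) | set(by_tp["post"]))
    unpaired = [i for i in individuals if i not in by_tp["pre"] or i not in by_tp["post"]]
    if unpaired:
        raise DMPError(f"unpaired individuals: {unpaired}")
    pre_rows = pre.loc[[by_tp["pre"][i] for i in individuals], probes].to_numpy(dtype=float)
    post_rows = post.loc[[by_tp["post"][i] for i in individuals], probes].to_numpy(dtype=float)
    values = pd.DataFrame(post_rows - pre_rows, index=individuals, columns=probes)
    sex = sheet.drop_duplicates("individual_id").set_index("individual_id")["sex"]
    return DeltaMatrix(values=values, sex=sex.reindex(individuals))


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_prior(s_sq: np.ndarray, d: float) -> ModerationPrior:
    """Fit the scaled-inverse-chi-square variance prior (d0, s0^2).

    Method of moments on e = log(s^2) - digamma(d/2) + log(d/2): the excess
    of var(e) over trigamma(d/2) determines d0 through the trigamma inverse;
    d0 = inf when there is no excess (variances already exchangeable).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if len(s_sq) == 0 or np.all(s_sq == 0):
        raise DMPError("all variances are zero or missing")
    if d < 1:
        raise DMPError("residual df must be >= 1")
    positive = s_sq[s_sq > 0]
    floor = positive.min() * 1e-12 if len(positive) else 1e-300
    z = np.log(np.maximum(s_sq, floor))
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def _moderate(s_sq: np.ndarray, d: float, prior: ModerationPrior) -> tuple[np.ndarray, float]:
    """Posterior variances and total df given the prior.  d0=0 is allowed as
    an explicit no-moderation request (classical test)."""
    if math.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq), math.inf
    s_tilde = (prior.d0 * prior.s0_sq + d * s_sq) / (prior.d0 + d)
    return s_tilde, prior.d0 + d


def _two_sided_p(t: np.ndarray, df: float) -> np.ndarray:
    if math.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DMPError("p-values outside [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _finalize(
    probes, mean_delta, s_sq, s_tilde, t, df_total, p, group: str
) -> pd.DataFrame:
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "group": group,
            "mean_delta": mean_delta,
            "s2": s_sq,
            "s2_moderated": s_tilde,
            "t": t,
            "df_total": df_total,
            "p_value": p,
            "q_value": q,
            "sig_fdr05": q <= 0.05,
            "sig_fdr10": q <= 0.10,
            "direction": np.where(mean_delta > 0, "hyper", "hypo"),
        },
        index=pd.Index(probes, name="probe_id"),
    )


def moderated_paired_test(
    delta: DeltaMatrix | pd.DataFrame,
    prior: ModerationPrior | None = None,
    group: str = "combined",
) -> pd.DataFrame:
    """One-sample moderated t of mean within-individual difference per probe.

    With ``prior=None`` the prior is estimated from the data.  A prior with
    d0=0 reduces exactly to the classical paired t-test; d0=inf gives every
    probe the common variance s0^2.
    """
    values = delta.values if isinstance(delta, DeltaMatrix) else delta
    n = len(values)
    if n < 3:
        raise DMPError(f"need >= 3 individuals, got {n}")
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    s_sq = x.var(axis=0, ddof=1)
    d = n - 1
    if prior is None:
        prior = estimate_prior(s_sq, d)
    if prior.d0 == 0:
        s_tilde, df_total = s_sq, float(d)
    else:
        s_tilde, df_total = _moderate(s_sq, d, prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s_tilde / n)
    p = _two_sided_p(t, df_total)
    return _finalize(values.columns, mean, s_sq, s_tilde, t, df_total, p, group)


def interaction_test(
    delta_f: DeltaMatrix | pd.DataFrame,
    delta_m: DeltaMatrix | pd.DataFrame,
    prior: ModerationPrior | None = None,
) -> pd.DataFrame:
    """Two-sample moderated t of female vs male differences (sex x age
    interaction).  Pooled per-probe variance is moderated by the prior."""
    xf = (delta_f.values if isinstance(delta_f, DeltaMatrix) else delta_f)
    xm = (delta_m.values if isinstance(delta_m, DeltaMatrix) else delta_m)
    probes = [p for p in xf.columns if p in set(xm.columns)]
    nf, nm = len(xf), len(xm)
    if nf < 3 or nm < 3:
        raise DMPError("need >= 3 individuals per sex")
    f = xf[probes].to_numpy(dtype=float)
    m = xm[probes].to_numpy(dtype=float)
    diff = f.mean(axis=0) - m.mean(axis=0)
    d = nf + nm - 2
    pooled = ((nf - 1) * f.var(axis=0, ddof=1) + (nm - 1) * m.var(axis=0, ddof=1)) / d
    if prior is None:
        prior = estimate_prior(pooled, d)
    if prior.d0 == 0:
        s_tilde, df_total = pooled, float(d)
    else:
        s_tilde, df_total = _moderate(pooled, d, prior)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s_tilde * (1.0 / nf + 1.0 / nm))
    p = _two_sided_p(t, df_total)
    return _finalize(probes, diff, pooled, s_tilde, t, df_total, p, "interaction")


def classify_dmps(
    results_f: pd.DataFrame,
    results_m: pd.DataFrame,
    results_combined: pd.DataFrame,
    fdr_level: float = 0.05,
) -> dict[str, list[str]]:
    """Partition significant probes into female-specific, male-specific and
    shared sets; overlaps between the stratified hits are reported too."""
    col = "sig_fdr05" if fdr_level <= 0.05 else "sig_fdr10"
    sig_f = set(results_f.index[results_f[col]])
    sig_m = set(results_m.index[results_m[col]])
    sig_c = set(results_combined.index[results_combined[col]])
    order = list(results_combined.index)
    pick = lambda s: [p for p in order if p in s]
    return {
        "female_specific": pick(sig_f - sig_m),
        "male_specific": pick(sig_m - sig_f),
        "shared": pick(sig_c),
        "overlap_female_male": pick(sig_f & sig_m),
        "overlap_female_shared": pick(sig_f & sig_c),
        "overlap_male_shared": pick(sig_m & sig_c),
    }


def summarize_dmps(
    probes: list[str],
    delta: DeltaMatrix | pd.DataFrame,
    ann: pd.DataFrame | None = None,
    large_effect: float = 0.05,
) -> dict:
    """Effect-size and location summary of a DMP set.

    Percentages are rounded to one decimal.  ``large_effect`` sets the
    |delta-beta| threshold for the large-change count.
    """
    if not probes:
        return {"n": 0, "n_hyper": 0, "n_hypo": 0}
    values = delta.values if isinstance(delta, DeltaMatrix) else delta
    mean = values[list(probes)].mean(axis=0)
    n = len(probes)
    n_hyper = int((mean > 0).sum())
    n_hypo = int((mean <= 0).sum())
    absd = mean.abs()
    out = {
        "n": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "pct_hyper": round(100.0 * n_hyper / n, 1),
        "pct_hypo": round(100.0 * n_hypo / n, 1),
        "median_abs_delta": float(absd.median()),
        "min_abs_delta": float(absd.min()),
        "max_abs_delta": float(absd.max()),
        "n_large_effect": int((absd > large_effect).sum()),
    }
    if ann is not None:
        regions = ann.loc[list(probes), "region"].value_counts()
        out["region_fractions"] = {
            r: round(100.0 * int(regions.get(r, 0)) / n, 1)
            for r in ("TSS200", "TSS1500", "Body", "Intergenic")
        }
    return out
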