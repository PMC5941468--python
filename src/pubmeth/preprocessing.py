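"""Beta computation, probe filtering, confounder screening, batch adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PreprocessingError(ValueError):
    pass


def compute_beta(
    meth: pd.DataFrame, unmeth: pd.DataFrame, offset: float = 0.0
) -> pd.DataFrame:
    """Methylation fraction beta = M / (M + U + offset), elementwise.

    ``offset`` defaults to 0; array pipelines often use 100.  A zero
    denominator anywhere raises :class:`PreprocessingError`.
    """
    if meth.shape != unmeth.shape:
        raise PreprocessingError("meth and unmeth matrices are not conformable")
    if offset < 0:
        raise PreprocessingError("offset must be nonnegative")
    m = meth.to_numpy(dtype=float)
    u = unmeth.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise PreprocessingError("negative intensities")
    denom = m + u + offset
    if (denom == 0).any():
        raise PreprocessingError("M + U + offset is zero at some cells")
    return pd.DataFrame(m / denom, index=meth.index, columns=meth.columns)


def mvalue(beta: pd.DataFrame | np.ndarray, eps: float = 1e-6):
    """logit2 transform: M = log2((beta + eps) / (1 - beta + eps))."""
    b = np.asarray(beta, dtype=float)
    out = np.log2((b + eps) / (1.0 - b + eps))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def mvalue_inverse(m, eps: float = 0.0):
    """Inverse of :func:`mvalue` (exact when eps=0)."""
    x = np.power(2.0, np.asarray(m, dtype=float))
    return (x * (1 + eps) - eps) / (x + 1.0)


FILTER_REASONS = ("sex_chromosome", "multi_map", "snp_overlap", "detection_fail")


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None,
    ann: pd.DataFrame,
    detp_threshold: float = 0.01,
    sample_fraction: float = 0.75,
) -> pd.DataFrame:
    """Per-probe QC flags and keep decision.

    A probe is removed when it lies on chrX/chrY, is flagged multi-mapping
    or SNP-overlapping, or has detection p > ``detp_threshold`` in at least
    ``sample_fraction`` of samples (boundary inclusive).

    Returns a FilterReport frame indexed by probe id with one boolean column
    per reason plus ``kept``.
    """
    probes = beta.columns
    missing = [p for p in probes if p not in ann.index]
    if missing:
        raise PreprocessingError(f"probes missing annotation: {missing[:10]}")
    sub = ann.loc[probes]
    sexchrom = sub["chrom"].isin(["chrX", "chrY", "X", "Y"]).to_numpy()
    multi = sub["multi_map"].astype(bool).to_numpy()
    snp = sub["snp_overlap"].astype(bool).to_numpy()
    if detp is not None:
        dp = detp[probes].to_numpy(dtype=float)
        fail_frac = (dp > detp_threshold).mean(axis=0)
    else:
        fail_frac = np.zeros(len(probes))
    detfail = fail_frac >= sample_fraction
    report = pd.DataFrame(
        {
            "sex_chromosome": sexchrom,
            "multi_map": multi,
            "snp_overlap": snp,
            "detection_fail": detfail,
            "fail_fraction": fail_frac,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    report["kept"] = ~(sexchrom | multi | snp | detfail)
    return report


def filter_summary(report: pd.DataFrame) -> dict:
    return {
        "n_probes": int(len(report)),
        "n_kept": int(report["kept"].sum()),
        "n_removed": int((~report["kept"]).sum()),
        "by_reason": {r: int(report[r].sum()) for r in FILTER_REASONS},
    }


def apply_filter(beta: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    kept = report.index[report["kept"]]
    return beta[[p for p in beta.columns if p in set(kept)]]


def pca_screen(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: list[str],
    n_components: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Associate top principal components with sample covariates.

    Categorical covariates are tested with one-way ANOVA of PC scores by
    level; numeric covariates with a Pearson correlation test.  A covariate
    with a single level (or zero variance) is reported as not testable.

    Returns a frame with one row per (covariate, PC): p-value, testable
    flag, and a ``flagged`` column marking covariates with p < alpha on any
    of the top PCs.
    """
    if len(matrix) < 2:
        raise PreprocessingError("need at least two samples for PCA")
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    n_components = min(n_components, min(x.shape) - 1) or 1
    # thin SVD; samples x probes with probes >> samples
    u_mat, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u_mat[:, :n_components] * s[:n_components]
    rows = []
    for cov in covariates:
        vals = sheet.loc[matrix.index, cov]
        numeric = pd.api.types.is_numeric_dtype(vals)
        if numeric:
            testable = vals.nunique() > 1
        else:
            testable = vals.nunique() > 1 and vals.value_counts().min() >= 2
        for k in range(n_components):
            pc = scores[:, k]
            if not testable:
                rows.append({"covariate": cov, "pc": k + 1, "p_value": np.nan, "testable": False})
                continue
            if numeric:
                r, p = stats.pearsonr(vals.to_numpy(dtype=float), pc)
            else:
                groups = [pc[(vals == lv).to_numpy()] for lv in vals.unique()]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = stats.f_oneway(*groups)
            rows.append({"covariate": cov, "pc": k + 1, "p_value": float(p), "testable": True})
    out = pd.DataFrame(rows)
    flagged = (
        out.groupby("covariate")
        .apply(lambda g: bool((g["p_value"] < alpha).any()), include_groups=False)
        .rename("flagged")
    )
    return out.merge(flagged, on="covariate")


def adjust_batch(
    matrix: pd.DataFrame, batches: pd.Series, mode: str = "meancenter"
) -> pd.DataFrame:
    """Remove batch effects per probe.

    ``meancenter``: every batch's per-probe mean is moved to the grand mean.
    ``eb_location_scale``: batch location and scale estimates are shrunk
    toward cross-probe pooled values (method-of-moments empirical Bayes,
    normal prior on locations, inverse-gamma on scales) before the
    location-scale correction; grand means are preserved.
    """
    if mode not in {"meancenter", "eb_location_scale"}:
        raise PreprocessingError(f"unknown mode {mode!r}")
    batches = batches.reindex(matrix.index)
    levels = batches.unique()
    if len(levels) < 2:
        raise PreprocessingError("need at least two batches")
    sizes = batches.value_counts()
    if (sizes < 2).any():
        singles = sizes.index[sizes < 2].tolist()
        if mode == "eb_location_scale":
            raise PreprocessingError(f"batches with a single sample: {singles}")
        warnings.warn(f"batches with a single sample: {singles}; mean-centering anyway")

    x = matrix.to_numpy(dtype=float)
    grand = x.mean(axis=0, keepdims=True)
    out = x.copy()
    if mode == "meancenter":
        for lv in levels:
            rows = (batches == lv).to_numpy()
            out[rows] = x[rows] - x[rows].mean(axis=0, keepdims=True) + grand
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)

    # eb_location_scale: standardise per probe, shrink batch effects, correct
    pooled_sd = x.std(axis=0, ddof=1, keepdims=True)
    pooled_sd = np.where(pooled_sd == 0, 1.0, pooled_sd)
    z = (x - grand) / pooled_sd
    for lv in levels:
        rows = (batches == lv).to_numpy()
        zb = z[rows]
        gamma_hat = zb.mean(axis=0)  # per-probe batch location
        delta_hat = zb.var(axis=0, ddof=1)  # per-probe batch scale
        # normal prior on gamma: shrink toward cross-probe mean
        g_bar = gamma_hat.mean()
        tau2 = max(gamma_hat.var(ddof=1), 1e-12)
        n_b = rows.sum()
        resid_var = np.maximum(delta_hat, 1e-12)
        w = tau2 / (tau2 + resid_var / n_b)
        gamma_star = g_bar + w * (gamma_hat - g_bar)
        # inverse-gamma prior on delta via method of moments
        d_bar = delta_hat.mean()
        d_var = max(delta_hat.var(ddof=1), 1e-12)
        a_prior = d_bar**2 / d_var + 2.0
        b_prior = d_bar * (a_prior - 1.0)
        delta_star = (b_prior + 0.5 * (n_b - 1) * delta_hat) / (a_prior + 0.5 * (n_b - 1) - 1.0)
        delta_star = np.maximum(delta_star, 1e-12)
        z[rows] = (zb - gamma_star) / np.sqrt(delta_star)
    out = z * pooled_sd + grand
    # re-impose exact grand-mean preservation
    out = out - out.mean(axis=0, keepdims=True) + grand
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
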