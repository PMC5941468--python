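"""Synthetic cohort generator.

Emits paired two-timepoint methylation matrices with the statistical
structure the downstream analyses assume: bimodal beta values, a
within-individual random effect, sex-specific planted effects, batch
shifts, drifting cell-type proportions, and an expression matrix with
planted module structure and sparse cis methylation-expression coupling.
Ground truth is returned alongside so every stage can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import annotation

CELL_TYPES = ("lymphocyte", "monocyte", "eosinophil", "other")

EFFECT_CLASSES = ("female_specific", "male_specific", "shared", "null")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Effect-size defaults reproduce the regime of the target cohort: paired
    samples for 30 girls and 25 boys, 347 female-specific planted effects
    with median absolute beta change near 0.026 ranging 0.016-0.105.
    """

    n_female: int = 30
    n_male: int = 25
    n_probes: int = 2000
    n_genes: int = 400
    n_dmp_female: int = 347
    n_dmp_male: int = 50
    n_dmp_shared: int = 48
    effect_low: float = 0.016
    effect_high: float = 0.105
    effect_median: float = 0.026
    rho_pair: float = 0.7
    # (a_low, b_low, a_high, b_high, weight_low) of the two-component
    # beta mixture for probe baseline methylation
    beta_mix: tuple[float, float, float, float, float] = (1.5, 8.0, 8.0, 1.5, 0.5)
    noise_sd: float = 0.12  # per-timepoint residual s.d. on the logit scale
    n_batches: int = 2
    batch_sd: float = 0.0  # s.d. of per-batch logit-scale offsets
    cell_shift: dict[str, float] = field(
        default_factory=lambda: {"lymphocyte": -0.05, "monocyte": 0.05, "eosinophil": 0.0}
    )
    expr_modules: list[tuple[int, float]] = field(default_factory=lambda: [(50, 0.8), (40, 0.7)])
    frac_cis: float = 0.05
    er_frac: float = 0.148  # fraction of genes in the estrogen-responsive set
    # detection-p failure planting for simulate_intensities
    det_fail_probe_frac: float = 0.01
    det_fail_sample_frac: float = 0.8
    mean_intensity: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        n_planted = self.n_dmp_female + self.n_dmp_male + self.n_dmp_shared
        if n_planted > self.n_probes:
            raise SimConfigError(
                f"{n_planted} planted effects exceed {self.n_probes} probes"
            )
        if not (0 <= self.effect_low <= self.effect_median <= self.effect_high <= 1):
            raise SimConfigError("need 0 <= effect_low <= effect_median <= effect_high <= 1")
        if not (0 <= self.rho_pair < 1):
            raise SimConfigError("rho_pair must be in [0, 1)")
        if self.n_batches < 1 or min(self.n_female, self.n_male) < 0:
            raise SimConfigError("counts must be nonnegative, n_batches >= 1")
        if any(size > self.n_genes for size, _ in self.expr_modules):
            raise SimConfigError("expression module larger than n_genes")
        if not 0 <= self.frac_cis <= 1:
            raise SimConfigError("frac_cis must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expr_modules"] = [list(m) for m in self.expr_modules]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "expr_modules" in d:
            d["expr_modules"] = [tuple(m) for m in d["expr_modules"]]
        if "beta_mix" in d:
            d["beta_mix"] = tuple(d["beta_mix"])
        return cls(**d)


class SimulatedCohort(NamedTuple):
    pre: pd.DataFrame  # samples x probes
    post: pd.DataFrame
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    gene_set: set[str]
    truth: pd.DataFrame
    genes: pd.DataFrame  # gene model used for annotation


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _effect_beta_shape(cfg: SimConfig) -> float:
    """Shape b of Beta(1, b) whose scaled median equals effect_median."""
    span = cfg.effect_high - cfg.effect_low
    if span <= 0:
        return 1.0
    frac = (cfg.effect_median - cfg.effect_low) / span
    frac = min(max(frac, 1e-9), 1 - 1e-9)
    return float(np.log(2.0) / -np.log1p(-frac))


def sample_effect_sizes(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw signed planted effects with |effect| in [low, high], median near target."""
    b = _effect_beta_shape(cfg)
    mag = cfg.effect_low + (cfg.effect_high - cfg.effect_low) * rng.beta(1.0, b, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


def make_gene_model(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic gene model: genes tiled along two autosomes."""
    n = cfg.n_genes
    ids = [f"G{i:05d}" for i in range(n)]
    chroms = np.where(np.arange(n) % 2 == 0, "chr1", "chr2")
    rank = np.arange(n) // 2
    starts = 10_000 + rank * 12_000 + rng.integers(0, 2_000, size=n)
    lengths = rng.integers(2_000, 8_000, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return pd.DataFrame(
        {"gene_id": ids, "chrom": chroms, "start": starts, "end": starts + lengths, "strand": strands}
    )


def make_probe_positions(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    span = int(genes["end"].max()) + 10_000
    ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    chroms = rng.choice(["chr1", "chr2"], size=cfg.n_probes)
    positions = rng.integers(1, span, size=cfg.n_probes)
    return pd.DataFrame({"probe_id": ids, "chrom": chroms, "position": positions})


def _baseline_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    a1, b1, a2, b2, w = cfg.beta_mix
    low = rng.random(cfg.n_probes) < w
    mu = np.where(low, rng.beta(a1, b1, cfg.n_probes), rng.beta(a2, b2, cfg.n_probes))
    return np.clip(mu, 0.01, 0.99)


def _make_truth(
    cfg: SimConfig, probe_ids: list[str], ann: pd.DataFrame, gene_set: set[str], rng: np.random.Generator
) -> pd.DataFrame:
    n = cfg.n_probes
    classes = np.array(["null"] * n, dtype=object)
    chosen = rng.choice(n, size=cfg.n_dmp_female + cfg.n_dmp_male + cfg.n_dmp_shared, replace=False)
    f_idx = chosen[: cfg.n_dmp_female]
    m_idx = chosen[cfg.n_dmp_female : cfg.n_dmp_female + cfg.n_dmp_male]
    s_idx = chosen[cfg.n_dmp_female + cfg.n_dmp_male :]
    classes[f_idx] = "female_specific"
    classes[m_idx] = "male_specific"
    classes[s_idx] = "shared"
    delta = np.zeros(n)
    delta[f_idx] = sample_effect_sizes(cfg, cfg.n_dmp_female, rng)
    delta[m_idx] = sample_effect_sizes(cfg, cfg.n_dmp_male, rng)
    delta[s_idx] = sample_effect_sizes(cfg, cfg.n_dmp_shared, rng)
    genes = ann["nearest_gene"].reindex(probe_ids).to_numpy()
    truth = pd.DataFrame(
        {
            "effect_class": classes,
            "true_delta": delta,
            "assigned_gene": genes,
            "gene_in_er_set": [g in gene_set for g in genes],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return truth


def _make_sheet(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    individuals = [f"F{i:03d}" for i in range(cfg.n_female)] + [
        f"M{i:03d}" for i in range(cfg.n_male)
    ]
    sexes = ["F"] * cfg.n_female + ["M"] * cfg.n_male
    rows = []
    # pre-timepoint cell mix; post shifted by cfg.cell_shift, renormalised
    base_alpha = np.array([55.0, 25.0, 5.0, 15.0])
    ancestries = rng.choice(
        ["European", "African", "Hispanic"], size=len(individuals), p=[0.9, 0.05, 0.05]
    )
    for k, (ind, sex) in enumerate(zip(individuals, sexes)):
        pre_props = rng.dirichlet(base_alpha)
        shift = np.array([cfg.cell_shift.get(ct, 0.0) for ct in CELL_TYPES])
        post_props = np.clip(pre_props + shift + rng.normal(0, 0.01, 4), 1e-6, None)
        post_props = post_props / post_props.sum()
        for tp, props, age, status in (
            ("pre", pre_props, 8.0, "pre"),
            ("post", post_props, 14.0, "post"),
        ):
            rows.append(
                {
                    "sample_id": f"{ind}_{tp}",
                    "individual_id": ind,
                    "sex": sex,
                    "timepoint": tp,
                    "age": age + float(rng.normal(0, 0.3)),
                    "batch": "",  # filled below
                    **dict(zip(CELL_TYPES, props)),
                    "ancestry": ancestries[k],
                    "puberty_status": status,
                }
            )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    batches = np.array([f"B{i % cfg.n_batches}" for i in range(len(sheet))])
    rng.shuffle(batches)
    sheet["batch"] = batches
    return sheet


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a fully synthetic paired two-timepoint cohort.

    Returns matrices of beta values (samples x probes) for each timepoint,
    a sample sheet, a probe annotation built against a synthetic gene model,
    an estrogen-responsive gene set, the ground-truth table, and the gene
    model itself.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = make_gene_model(config, rng)
    probes = make_probe_positions(config, genes, rng)
    ann = annotation.annotate_probes(probes, genes)
    n_er = int(round(config.er_frac * config.n_genes))
    gene_set = set(rng.choice(genes["gene_id"].to_numpy(), size=n_er, replace=False))
    probe_ids = probes["probe_id"].tolist()
    truth = _make_truth(config, probe_ids, ann, gene_set, rng)
    sheet = _make_sheet(config, rng)

    mu = _baseline_means(config, rng)  # per-probe baseline
    mu_logit = _logit(mu)
    individuals = sheet["individual_id"].unique()
    n_ind = len(individuals)
    sex_by_ind = sheet.drop_duplicates("individual_id").set_index("individual_id")["sex"]

    # variance split so that corr(logit beta_pre, logit beta_post) = rho_pair
    sigma_e = config.noise_sd
    rho = config.rho_pair
    sigma_u = sigma_e * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    u = rng.normal(0.0, sigma_u, size=(n_ind, config.n_probes)) if sigma_u > 0 else np.zeros(
        (n_ind, config.n_probes)
    )
    batch_levels = sorted(sheet["batch"].unique())
    batch_offset = {b: rng.normal(0.0, config.batch_sd) if config.batch_sd > 0 else 0.0
                    for b in batch_levels}

    ind_pos = {ind: i for i, ind in enumerate(individuals)}
    mats: dict[str, pd.DataFrame] = {}
    for tp in ("pre", "post"):
        sub = sheet[sheet["timepoint"] == tp]
        eps = rng.normal(0.0, sigma_e, size=(len(sub), config.n_probes))
        rows_u = np.vstack([u[ind_pos[i]] for i in sub["individual_id"]])
        boff = np.array([batch_offset[b] for b in sub["batch"]])[:, None]
        beta = _expit(mu_logit[None, :] + rows_u + eps + boff)
        mats[tp] = pd.DataFrame(beta, index=sub.index, columns=probe_ids)

    # inject planted effects on the beta scale into post samples
    post = mats["post"]
    delta = truth["true_delta"].to_numpy()
    is_f = (sex_by_ind.reindex(sheet.loc[post.index, "individual_id"]) == "F").to_numpy()
    for cls, mask in (
        ("female_specific", is_f),
        ("male_specific", ~is_f),
        ("shared", np.ones(len(post), dtype=bool)),
    ):
        cols = truth.index[truth["effect_class"] == cls]
        if len(cols):
            post.loc[post.index[mask], cols] = post.loc[post.index[mask], cols].add(
                truth.loc[cols, "true_delta"], axis=1
            )
    mats["post"] = post.clip(0.001, 0.999)
    mats["pre"] = mats["pre"].clip(0.001, 0.999)

    return SimulatedCohort(
        pre=mats["pre"],
        post=mats["post"],
        sheet=sheet,
        annotation=ann,
        gene_set=gene_set,
        truth=truth,
        genes=genes,
    )


class SimulatedIntensities(NamedTuple):
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame
    sheet: pd.DataFrame
    beta: pd.DataFrame  # the beta values the intensities encode


def simulate_intensities(config: SimConfig) -> SimulatedIntensities:
    """Emit methylated/unmethylated intensities plus detection p-values.

    Beta recomputed as M/(M+U) matches the generating beta to float
    precision.  A ``det_fail_probe_frac`` fraction of probes is planted with
    detection p > 0.01 in a ``det_fail_sample_frac`` fraction of samples.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    sheet = _make_sheet(config, rng)
    mu = _baseline_means(config, rng)
    n_s = len(sheet)
    beta = _expit(
        _logit(mu)[None, :] + rng.normal(0.0, config.noise_sd, size=(n_s, config.n_probes))
    )
    total = rng.lognormal(np.log(config.mean_intensity), 0.3, size=beta.shape)
    meth = beta * total
    unmeth = (1.0 - beta) * total
    detp = rng.uniform(0.0, 0.005, size=beta.shape)
    n_fail = int(round(config.det_fail_probe_frac * config.n_probes))
    if n_fail:
        fail_probes = rng.choice(config.n_probes, size=n_fail, replace=False)
        n_fail_samples = int(round(config.det_fail_sample_frac * n_s))
        for j in fail_probes:
            rows = rng.choice(n_s, size=n_fail_samples, replace=False)
            detp[rows, j] = rng.uniform(0.011, 1.0, size=n_fail_samples)
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]
    idx = sheet.index
    return SimulatedIntensities(
        meth=pd.DataFrame(meth, index=idx, columns=probe_ids),
        unmeth=pd.DataFrame(unmeth, index=idx, columns=probe_ids),
        detection_p=pd.DataFrame(detp, index=idx, columns=probe_ids),
        sheet=sheet,
        beta=pd.DataFrame(beta, index=idx, columns=probe_ids),
    )


def simulate_expression(
    sheet: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    beta_post: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Post-timepoint expression with planted module and cis structure.

    Module genes load on a shared per-sample latent factor (unit marginal
    variance).  When ``beta_post`` is given, a ``frac_cis`` fraction of
    genes additionally tracks the standardised beta value of one probe
    assigned to the gene.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    post = sheet[sheet["timepoint"] == "post"]
    if post.empty:
        raise SimConfigError("sample sheet contains no post-timepoint samples")
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    n_s = len(post)
    expr = rng.normal(size=(n_s, config.n_genes))
    # non-overlapping module blocks from the front of the gene list
    cursor = 0
    for size, loading in config.expr_modules:
        if cursor + size > config.n_genes:
            raise SimConfigError("expression modules exceed n_genes")
        f = rng.normal(size=n_s)
        block = slice(cursor, cursor + size)
        expr[:, block] = loading * f[:, None] + np.sqrt(1 - loading**2) * expr[:, block]
        cursor += size
    if config.frac_cis > 0 and beta_post is not None:
        gene_to_probe: dict[str, str] = {}
        for pid, g in truth["assigned_gene"].items():
            if isinstance(g, str) and g not in gene_to_probe and pid in beta_post.columns:
                gene_to_probe[g] = pid
        candidates = [g for g in gene_ids if g in gene_to_probe]
        n_cis = int(round(config.frac_cis * config.n_genes))
        cis_genes = rng.choice(candidates, size=min(n_cis, len(candidates)), replace=False)
        bp = beta_post.reindex(post.index)
        for g in cis_genes:
            b = bp[gene_to_probe[g]].to_numpy()
            sd = b.std()
            if sd > 0:
                z = (b - b.mean()) / sd
                j = gene_ids.index(g)
                expr[:, j] = 0.7 * z + np.sqrt(1 - 0.49) * expr[:, j]
    return pd.DataFrame(expr, index=post.index, columns=gene_ids)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path, config: SimConfig) -> None:
    """Write all cohort artefacts as delimited text plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.pre.T.to_csv(out / "beta_pre.tsv", sep="\t")
    cohort.post.T.to_csv(out / "beta_post.tsv", sep="\t")
    cohort.sheet.to_csv(out / "sample_sheet.tsv", sep="\t")
    cohort.annotation.to_csv(out / "probe_annotation.tsv", sep="\t")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t")
    cohort.genes.to_csv(out / "gene_model.tsv", sep="\t", index=False)
    (out / "er_genes.txt").write_text("\n".join(sorted(cohort.gene_set)) + "\n")
    (out / "manifest.json").write_text(
        json.dumps({"seed": config.seed, "config": config.to_dict()}, indent=2)
    )
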