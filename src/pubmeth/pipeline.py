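"""End-to-end orchestration on synthetic or user-supplied data.

Stages run in dependency order: simulate -> filter -> dmp -> enrich ->
coexpress -> classify -> confounds.  Every run directory records the
resolved configuration and seed; child RNG streams are spawned
deterministically from the global seed so identical configurations give
byte-identical numeric outputs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import classifier as clf_mod
from . import coexpression as coex_mod
from . import confounds as conf_mod
from . import dmp as dmp_mod
from . import enrichment as enr_mod
from . import io as io_mod
from . import preprocessing as prep_mod
from .simulate import SimConfig, simulate_cohort, simulate_expression, write_cohort

logger = logging.getLogger("pubmeth")

DEFAULT_PIPELINE = {
    "fdr_level": 0.05,
    "n_perm": 20_000,
    "enrichment_mode": "universe",
    "coexpress_min_size": 25,
    "coexpress_power": 6.0,
    "classifier_linkage": "complete",
    "classifier_metric": "euclidean",
    "n_exclude_sensitivity": 5,
    "stages": ["simulate", "filter", "dmp", "enrich", "coexpress", "classify", "confounds"],
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "pubmeth_run",
    seed: int = 0,
    sim_config: SimConfig | None = None,
) -> Path:
    """Run the synthetic end-to-end analysis; returns the run directory.

    ``config`` overrides :data:`DEFAULT_PIPELINE` keys.  A stage failure
    aborts with the failing stage named; outputs of completed stages are
    retained in the run directory.
    """
    cfg = dict(DEFAULT_PIPELINE)
    if config:
        cfg.update(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seeds = np.random.SeedSequence(seed).spawn(8)
    child_seed = lambda i: int(seeds[i].generate_state(1)[0])
    report: dict = {"seed": seed, "config": cfg, "stages": {}}
    t0 = time.time()
    stage = "simulate"
    try:
        sim_cfg = sim_config or SimConfig(
            n_probes=1500, n_genes=300, n_dmp_female=60, n_dmp_male=20, n_dmp_shared=15,
            effect_low=0.03, effect_median=0.05, effect_high=0.12, noise_sd=0.08,
            expr_modules=[(40, 0.8), (30, 0.7)],
        )
        sim_cfg.seed = child_seed(0)
        logger.info("simulate: seed=%d n_probes=%d", sim_cfg.seed, sim_cfg.n_probes)
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, out / "synthetic", sim_cfg)
        report["stages"]["simulate"] = {"seed": sim_cfg.seed, "n_probes": sim_cfg.n_probes}

        stage = "filter"
        rep = prep_mod.filter_probes(cohort.pre, None, cohort.annotation)
        pre = prep_mod.apply_filter(cohort.pre, rep)
        post = prep_mod.apply_filter(cohort.post, rep)
        rep.to_csv(out / "filter_report.tsv", sep="\t")
        report["stages"]["filter"] = prep_mod.filter_summary(rep)

        stage = "dmp"
        delta = dmp_mod.paired_delta(pre, post, cohort.sheet)
        delta_f = delta.subset("F")
        delta_m = delta.subset("M")
        res_f = dmp_mod.moderated_paired_test(delta_f, group="female")
        res_m = dmp_mod.moderated_paired_test(delta_m, group="male")
        res_c = dmp_mod.moderated_paired_test(delta, group="combined")
        res_i = dmp_mod.interaction_test(delta_f, delta_m)
        results = pd.concat([res_f, res_m, res_c, res_i])
        results.to_csv(out / "dmp_results.tsv", sep="\t")
        sets = dmp_mod.classify_dmps(res_f, res_m, res_c, fdr_level=cfg["fdr_level"])
        summaries = {
            "female_specific": dmp_mod.summarize_dmps(
                sets["female_specific"], delta_f, cohort.annotation
            ),
            "male_specific": dmp_mod.summarize_dmps(
                sets["male_specific"], delta_m, cohort.annotation
            ),
            "shared": dmp_mod.summarize_dmps(sets["shared"], delta, cohort.annotation),
        }
        report["stages"]["dmp"] = {
            "set_sizes": {k: len(v) for k, v in sets.items()},
            "summaries": summaries,
        }

        stage = "enrich"
        universe = list(cohort.genes["gene_id"])
        enrich_block = {}
        if sets["female_specific"]:
            genes_f = ann_mod.genes_near_dmps(sets["female_specific"], cohort.annotation)
            res = enr_mod.permutation_enrichment(
                genes_f,
                cohort.gene_set,
                universe,
                n_perm=cfg["n_perm"],
                mode=cfg["enrichment_mode"],
                seed=child_seed(1),
                name="female_dmp_genes",
            )
            enrich_block["female_dmp_genes"] = res.to_dict()
        report["stages"]["enrich"] = enrich_block

        stage = "coexpress"
        expr = simulate_expression(cohort.sheet, cohort.truth, sim_cfg, beta_post=post)
        female_post = cohort.sheet[(cohort.sheet["sex"] == "F") & (cohort.sheet["timepoint"] == "post")]
        expr_f = expr.loc[[s for s in expr.index if s in set(female_post.index)]]
        modules = coex_mod.detect_modules(
            expr_f, power=cfg["coexpress_power"], min_size=cfg["coexpress_min_size"]
        )
        modules.labels.to_frame("module").to_csv(out / "modules.tsv", sep="\t")
        mod_enr = coex_mod.module_enrichment(
            modules,
            cohort.gene_set,
            list(expr.columns),
            n_perm=cfg["n_perm"],
            mode="universe",
            seed=child_seed(2),
        )
        report["stages"]["coexpress"] = {
            "n_modules": modules.n_modules,
            "sizes": modules.sizes,
            "enrichment": {str(k): v.to_dict() for k, v in mod_enr.items()},
        }

        stage = "classify"
        # shared-class probes shift in every post sample, so they act like a
        # status-predictive panel for both sexes
        planted = list(cohort.truth.index[cohort.truth["effect_class"] == "shared"])
        panel = clf_mod.PanelDefinition("planted_dmp_panel", planted, "synthetic truth probes")
        stacked = pd.concat([pre, post])
        status = cohort.sheet["puberty_status"]
        ages = cohort.sheet["age"]
        clf = clf_mod.classify_samples(
            stacked,
            panel,
            status,
            ages,
            linkage=cfg["classifier_linkage"],
            metric=cfg["classifier_metric"],
        )
        report["stages"]["classify"] = clf.to_dict()

        stage = "confounds"
        cell_tests = {
            ct: vars(conf_mod.paired_cell_test(cohort.sheet, ct))
            for ct in ("lymphocyte", "monocyte", "eosinophil")
        }
        dmp_probes = sets["female_specific"] or list(delta.values.columns[:20])
        cis = conf_mod.cis_correlation(post, expr, cohort.annotation, dmp_probes)
        rng = np.random.default_rng(child_seed(3))
        excl = list(
            rng.choice(delta.values.index, size=min(cfg["n_exclude_sensitivity"],
                                                    len(delta.values) - 3), replace=False)
        )
        sens_r = conf_mod.subset_sensitivity(delta, excl, dmp_probes)
        report["stages"]["confounds"] = {
            "cell_tests": cell_tests,
            "cis": {
                "n_tested": cis.n_tested,
                "n_excluded": cis.n_excluded,
                "fraction_flagged": cis.fraction_flagged,
            },
            "subset_sensitivity_r": sens_r,
            "excluded_individuals": excl,
        }

        stage = "truth_recovery"
        truth_f = set(cohort.truth.index[cohort.truth["effect_class"] == "female_specific"])
        found_f = set(sets["female_specific"])
        big = set(
            cohort.truth.index[
                (cohort.truth["effect_class"] == "female_specific")
                & (cohort.truth["true_delta"].abs() >= 0.05)
            ]
        )
        recovered_big = len(big & found_f)
        report["recovery"] = {
            "precision_female": (len(truth_f & found_f) / len(found_f)) if found_f else None,
            "recall_female": (len(truth_f & found_f) / len(truth_f)) if truth_f else None,
            "recall_large_effect": (recovered_big / len(big)) if big else None,
        }
    except Exception as exc:  # noqa: BLE001 - report failing stage then re-raise
        io_mod.write_json(report, out / "report.json")
        logger.removeHandler(handler)
        handler.close()
        raise PipelineError(stage, exc) from exc

    report["elapsed_s"] = round(time.time() - t0, 2)
    io_mod.write_json(report, out / "report.json")
    logger.info("pipeline complete in %.1fs", report["elapsed_s"])
    logger.removeHandler(handler)
    handler.close()
    return out
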