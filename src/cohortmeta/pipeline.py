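"""End-to-end orchestration of the multi-cohort biomarker evaluation.

``run_all`` executes, in order: cohort simulation (or loading), target-gene
effect-size meta-analysis with subgroup/sensitivity/Begg analyses,
diagnostic-accuracy meta-analysis (per-cohort ROC -> Youden cutoff -> 2x2,
pooled accuracy, sROC, Fagan), DEG/CEG screening with vote counting and
SMD confirmation, and downstream IHC/survival (plus hub ranking and ORA
when an edge list / GMT is supplied). All randomness flows from one root
seed; outputs are TSV/JSON stamped with the config hash and seed, and the
whole run is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any, Mapping, Optional

import pandas as pd

from . import downstream, io, meta_diagnostic, meta_effect, screen, simulate
from .preprocess import summarize_group
from .types import CONTROL, TUMOR, ExpressionCohort

log = logging.getLogger("cohortmeta")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "target": "TARGET",
    "pretest": 0.2,
    "min_repetition": 5,
    "lfc_threshold": 1.0,
    "alpha": 0.05,
    "r_threshold": 0.3,
    "smd_correction": "cohen",
    "model": "auto",
    "simulation": {},
    "edges": None,  # optional STRING-style TSV for hub ranking
    "gmt": None,  # optional GMT for over-representation analysis
    "hub_k": 10,
    "stages": ["meta_effect", "meta_diagnostic", "screen", "downstream"],
}

_FLOAT_FMT = "%.10g"


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def _meta_result_dict(result) -> dict[str, Any]:
    return {
        "pooled": result.pooled,
        "se": result.se,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "Q": result.Q,
        "df": result.df,
        "I2": result.I2,
        "tau2": result.tau2,
        "model": result.model,
        "k": result.k,
        "het_p": result.het_p,
    }


@_stage("meta_effect")
def _run_meta_effect(cohorts, ihc_records, target, correction, model, out):
    summaries = {c.cohort_id: summarize_group(c, target) for c in cohorts}
    effects = meta_effect.effects_from_summaries(summaries, correction=correction)
    labels = ["mRNA"] * len(effects)
    ihc_summary = downstream.ihc_group_summary(ihc_records)
    effects.append(meta_effect.smd(ihc_summary, correction=correction, label="IHC"))
    labels.append("IHC")

    per_subgroup, overall = meta_effect.subgroup_pool(effects, labels, model=model)
    loo = meta_effect.leave_one_out(effects, model=model)
    tau, z, begg_p = meta_effect.beggs_test(effects)

    forest = pd.DataFrame(
        {
            "label": [e.label for e in effects],
            "subgroup": labels,
            "smd": [e.estimate for e in effects],
            "variance": [e.variance for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
        }
    )
    forest.to_csv(os.path.join(out, "forest.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    payload = {
        "overall": _meta_result_dict(overall),
        "subgroups": {k: _meta_result_dict(v) for k, v in per_subgroup.items()},
        "leave_one_out": [_meta_result_dict(r) for r in loo],
        "beggs": {"tau": tau, "z": z, "p": begg_p},
    }
    with open(os.path.join(out, "meta_effect.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log.info("meta_effect: %d studies, overall SMD %.3f", len(effects), overall.pooled)
    return {"effects": effects, "overall": overall, "subgroups": per_subgroup, "beggs_p": begg_p}


@_stage("meta_diagnostic")
def _run_meta_diagnostic(cohorts, target, pretest, out):
    tables = []
    roc_rows = []
    for cohort in cohorts:
        values = cohort.values_for(target).to_numpy(dtype=float)
        labels = cohort.group.to_numpy()
        roc = meta_diagnostic.roc_curve(values, labels)
        cutoff, sens, spec = meta_diagnostic.youden_cutoff(roc)
        tables.append(meta_diagnostic.to_two_by_two(values, labels, cutoff, label=cohort.cohort_id))
        roc_rows.append(
            {"cohort": cohort.cohort_id, "auc": roc.auc, "cutoff": cutoff, "sens": sens, "spec": spec}
        )
    pooled = meta_diagnostic.pool_accuracy(tables)
    curve = meta_diagnostic.sroc(tables)
    pooled.sroc_auc = curve.auc
    post_pos, post_neg = meta_diagnostic.fagan(pretest, pooled.pooled_sens, pooled.pooled_spec)

    pd.DataFrame(roc_rows).to_csv(
        os.path.join(out, "per_cohort_roc.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        [
            {"cohort": t.label, "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "cutoff": t.cutoff}
            for t in tables
        ]
    ).to_csv(os.path.join(out, "two_by_two.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame({"fpr": curve.fpr, "sens": curve.sens}).to_csv(
        os.path.join(out, "sroc_curve.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    payload = {
        "pooled_sens": pooled.pooled_sens,
        "sens_ci": list(pooled.sens_ci),
        "pooled_spec": pooled.pooled_spec,
        "spec_ci": list(pooled.spec_ci),
        "lr_pos": pooled.lr_pos,
        "lr_neg": pooled.lr_neg,
        "dor": pooled.dor,
        "sroc_auc": curve.auc,
        "pretest": pretest,
        "posttest_positive": post_pos,
        "posttest_negative": post_neg,
    }
    with open(os.path.join(out, "diagnostic.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    log.info("meta_diagnostic: sROC AUC %.3f, pooled sens %.3f spec %.3f", curve.auc, pooled.pooled_sens, pooled.pooled_spec)
    return {"tables": tables, "pooled": pooled, "sroc": curve, "fagan": (post_pos, post_neg)}


@_stage("screen")
def _run_screen(cohorts, target, cfg, out):
    de_frames = [screen.de_screen(c, cfg["lfc_threshold"], cfg["alpha"]) for c in cohorts]
    ceg_frames = [
        screen.ceg_screen(c, target, cfg["r_threshold"], cfg["alpha"]) for c in cohorts
    ]
    de_votes = screen.vote_count(de_frames, cfg["min_repetition"])
    ceg_votes = screen.vote_count(ceg_frames, cfg["min_repetition"])

    candidates = sorted(
        screen.accepted_genes(de_votes, screen.UP) | screen.accepted_genes(de_votes, screen.DOWN)
    )
    summaries = {
        gene: [summarize_group(c, gene) for c in cohorts if gene in c.matrix.index]
        for gene in candidates
    }
    confirmed = screen.smd_confirm(summaries, model=cfg["model"], correction=cfg["smd_correction"])
    confirmed_up = set(confirmed.index[confirmed["status"] == screen.UP])
    confirmed_down = set(confirmed.index[confirmed["status"] == screen.DOWN])
    set_a, set_b = screen.intersect_sets(
        confirmed_up,
        confirmed_down,
        screen.accepted_genes(ceg_votes, "pos"),
        screen.accepted_genes(ceg_votes, "neg"),
        target=target,
    )

    de_votes.to_csv(os.path.join(out, "deg_votes.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    ceg_votes.to_csv(os.path.join(out, "ceg_votes.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    confirmed.to_csv(os.path.join(out, "smd_confirmed.tsv"), sep="\t", float_format=_FLOAT_FMT)
    with open(os.path.join(out, "gene_set_A.txt"), "w") as fh:
        fh.write("\n".join(sorted(set_a)) + ("\n" if set_a else ""))
    with open(os.path.join(out, "gene_set_B.txt"), "w") as fh:
        fh.write("\n".join(sorted(set_b)) + ("\n" if set_b else ""))
    log.info("screen: |A|=%d, |B|=%d from %d DEG candidates", len(set_a), len(set_b), len(candidates))
    return {"set_a": set_a, "set_b": set_b, "confirmed": confirmed, "de_votes": de_votes, "ceg_votes": ceg_votes}


@_stage("downstream")
def _run_downstream(cohorts, ihc_records, sim_spec, target, cfg, screen_result, out):
    results: dict[str, Any] = {}
    # IHC group comparison
    ihc_summary = downstream.ihc_group_summary(ihc_records)
    t_res = meta_diagnostic.two_sample_t(ihc_summary, variant="welch")
    ihc_effect = meta_effect.smd(ihc_summary, correction=cfg["smd_correction"])
    irs_rows = [
        {
            "specimen_id": r.specimen_id,
            "group": r.group,
            "irs": downstream.specimen_irs(r),
        }
        for r in ihc_records
    ]
    pd.DataFrame(irs_rows).to_csv(os.path.join(out, "ihc_irs.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
    results["ihc"] = {
        "n_tumor": ihc_summary.n1,
        "mean_tumor": ihc_summary.mean1,
        "sd_tumor": ihc_summary.sd1,
        "n_control": ihc_summary.n0,
        "mean_control": ihc_summary.mean0,
        "sd_control": ihc_summary.sd0,
        "welch_t": t_res.t,
        "welch_p": t_res.p,
        "smd": ihc_effect.estimate,
        "smd_ci": [ihc_effect.ci_low, ihc_effect.ci_high],
    }

    # survival: tumors of the largest cohort carry the survival endpoint
    cohort = max(cohorts, key=lambda c: c.n_tumor)
    tumors = cohort.group[cohort.group == TUMOR].index
    expr = cohort.matrix.loc[target, tumors].to_numpy(dtype=float)
    surv = simulate.simulate_survival(sim_spec, expr)
    fit = downstream.survival_median_split(expr, surv["time"], surv["event"])
    pd.concat([fit.km_high, fit.km_low]).to_csv(
        os.path.join(out, "km_curves.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    results["survival"] = {
        "cohort": cohort.cohort_id,
        "chi2": fit.chi2,
        "p": fit.p,
        "hr": fit.hr,
        "n_high": fit.n_high,
        "n_low": fit.n_low,
    }

    if cfg.get("edges"):
        edges = io.read_edge_list(cfg["edges"], min_score=0.4)
        hubs = downstream.hub_rank(edges, cfg["hub_k"])
        hubs.to_csv(os.path.join(out, "hub_genes.tsv"), sep="\t", index=False)
        results["hubs"] = hubs["gene"].tolist()
    if cfg.get("gmt") and screen_result["set_a"]:
        gene_sets = io.read_gmt(cfg["gmt"])
        universe = sorted(cohorts[0].matrix.index)
        enrich = downstream.ora(sorted(screen_result["set_a"]), universe, gene_sets)
        enrich.to_csv(os.path.join(out, "ora_set_a.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT)
        results["ora_terms"] = len(enrich)

    with open(os.path.join(out, "downstream.json"), "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    log.info("downstream: IHC SMD %.3f, survival HR %.2f", ihc_effect.estimate, fit.hr)
    return results


def run_all(config: Optional[Mapping[str, Any]] = None, out_dir: str = "results") -> dict[str, Any]:
    """Run the full simulated analysis; write outputs under ``out_dir``."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    os.makedirs(out_dir, exist_ok=True)
    cfg_hash = _config_hash(cfg)

    # the analysis target (cfg["target"]) is looked up in the simulated data;
    # the generator's own gene naming stays under cfg["simulation"]
    sim_kwargs = dict(cfg["simulation"])
    sim_spec = simulate.SimulationSpec(seed=cfg["seed"], **sim_kwargs)
    cohorts, truth = simulate.simulate_cohorts(sim_spec)
    ihc_records = simulate.simulate_ihc(sim_spec)
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", float_format=_FLOAT_FMT)

    target = cfg["target"].upper()
    if target not in cohorts[0].matrix.index:
        raise RuntimeError(f"stage 'setup' failed: target gene {target!r} absent from cohorts")

    bundle: dict[str, Any] = {"config_hash": cfg_hash, "seed": cfg["seed"]}
    stages = cfg["stages"]
    if "meta_effect" in stages:
        bundle["meta_effect"] = _run_meta_effect(
            cohorts, ihc_records, target, cfg["smd_correction"], cfg["model"], out_dir
        )
    if "meta_diagnostic" in stages:
        bundle["meta_diagnostic"] = _run_meta_diagnostic(cohorts, target, cfg["pretest"], out_dir)
    if "screen" in stages:
        bundle["screen"] = _run_screen(cohorts, target, cfg, out_dir)
    if "downstream" in stages:
        bundle["downstream"] = _run_downstream(
            cohorts, ihc_records, sim_spec, target, cfg, bundle.get("screen", {"set_a": set()}), out_dir
        )

    echo = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v) for k, v in cfg.items()}
    echo["config_hash"] = cfg_hash
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True, default=str)
    return bundle
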