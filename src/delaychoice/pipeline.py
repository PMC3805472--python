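"""End-to-end runs: design -> simulate -> fit -> analyze -> mediate.

A run is fully determined by a :class:`RunConfig` plus its master seed;
re-running writes byte-identical outputs, recorded in a manifest with
SHA-256 checksums per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__, mediation, model, stats
from ._rng import stage_seed
from .cohort import Cohort, CohortConfig, GroupConfig, GROUP_PRESETS, simulate_cohort
from .task_design import schedule_to_csv

__all__ = ["RunConfig", "run_healthy_experiment", "run_patient_experiment",
           "config_from_dict", "write_run_outputs"]

log = logging.getLogger("delaychoice")

STAGES = ("schedule", "agent", "ratings", "choices", "neural", "fit", "mediate")


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    cohort: CohortConfig
    seed: int = 0
    outdir: str | None = None
    analyses: tuple = ("fits", "behavior", "interaction", "mediation")
    n_boot: int = 10_000

    def validate(self):
        self.cohort.validate()
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        return self


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain dict (parsed YAML/JSON).

    Each entry of ``groups`` names a ``preset`` (healthy/CTL/AD/bvFTD) and
    may override any GroupConfig field.
    """
    groups = []
    for g in d.get("groups", [{"preset": "healthy", "n": 20}]):
        g = dict(g)
        preset = GROUP_PRESETS[g.pop("preset", "healthy")]
        groups.append(dataclasses.replace(preset, **g))
    cc = CohortConfig(
        groups=groups,
        variant=d.get("variant", "exp2"),
        n_episodic_sessions=d.get("n_episodic_sessions", 2),
        include_monetary=d.get("include_monetary", d.get("variant", "exp2") in ("exp1", "exp2")),
        beta1=d.get("beta1", 1.0),
        bold_noise_sd=d.get("bold_noise_sd", 1.0),
    )
    return RunConfig(cohort=cc, seed=int(d.get("seed", 0)),
                     outdir=d.get("outdir"),
                     n_boot=int(d.get("n_boot", 10_000))).validate()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def _test_dict(t: stats.TestResult) -> dict:
    return {"statistic": t.statistic, "df": t.df, "p": t.p, "side": t.side}


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception:
        log.error("stage %s failed", name)
        raise RuntimeError(f"pipeline stage {name!r} failed") from None
    log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
    return out


# ---------------------------------------------------------------------------
# analyses shared by both experiment flavours

def _fit_all(cohort: Cohort) -> dict:
    """Per-subject fits per task, plus a pooled group fit on episodic trials."""
    fits = {"subjects": {}, "group": None}
    pooled = []
    for s in cohort.subjects:
        entry = {}
        for task in ("episodic", "monetary"):
            try:
                trials = s.valued_trials(task)
            except ValueError:
                continue
            fr = model.fit_parameters(trials, mode="subject")
            entry[task] = fr.to_dict()
            if task == "episodic":
                pooled.append(trials)
        fits["subjects"][s.subject_id] = entry
    if pooled:
        fr = model.fit_parameters(pd.concat(pooled, ignore_index=True), mode="group")
        fits["group"] = fr.to_dict()
    return fits


def _richness_tables(cohort: Cohort):
    """Per-subject (richness, sim rating) item tables for the slope test."""
    return [s.ratings.rename(columns={"rating_sim": "rating"})[["richness", "rating"]]
            for s in cohort.subjects]


def _eco_choice_tables(cohort: Cohort):
    """Per-subject ecological trials: delayed-option richness vs nonimpulsive choice."""
    out = []
    for s in cohort.subjects:
        rich = s.ratings.set_index("item")["richness"]
        parts = []
        for sched in s.schedules:
            if sched.task != "episodic":
                continue
            t = sched.trials
            eco = t[t["condition"] == "ecological"]
            ch = s.choices[(s.choices["session"] == sched.session)
                           & (s.choices["task"] == "episodic")]
            ch = ch.set_index("trial_index")["choice"]
            parts.append(pd.DataFrame({
                "richness": eco["del_item"].map(rich).to_numpy(float),
                "nonimpulsive": (eco["trial_index"].map(ch) == "nonimpulsive")
                                .astype(float).to_numpy(),
            }))
        out.append(pd.concat(parts, ignore_index=True))
    return out


def _behavior_analyses(cohort: Cohort, fits: dict) -> dict:
    rates = cohort.choice_rates()
    res: dict = {}

    res["richness_rating_slope_test"] = _test_dict(stats.per_subject_slope_test(
        _richness_tables(cohort), "richness", "rating", side="greater"))
    res["richness_choice_slope_test"] = _test_dict(stats.per_subject_slope_test(
        _eco_choice_tables(cohort), "richness", "nonimpulsive", side="greater"))

    # across-subject coupling of mean richness and mean Sim rating
    mr = [float(s.ratings["richness"].mean()) for s in cohort.subjects]
    ms = [float(s.ratings["rating_sim"].mean()) for s in cohort.subjects]
    fit = stats.robust_fit(mr, ms)
    res["richness_rating_across_subjects"] = {
        "slope": fit.slope(), "t": float(fit.tvalues[1]),
        "p": float(sps.t.sf(fit.tvalues[1], len(mr) - 2)), "side": "greater"}

    ep = rates[rates["task"] == "episodic"].groupby("subject")["nonimpulsive_rate"].mean()
    res["impulsive_rate_episodic_pct"] = float(100 * (1 - ep.mean()))
    if (rates["task"] == "monetary").any():
        mo = rates[rates["task"] == "monetary"].groupby("subject")["nonimpulsive_rate"].mean()
        res["impulsive_rate_monetary_pct"] = float(100 * (1 - mo.mean()))
        both = pd.concat([ep.rename("episodic"), mo.rename("monetary")], axis=1).dropna()
        fit = stats.robust_fit(both["monetary"], both["episodic"])
        res["choice_rate_intersubject_correlation"] = {
            "slope": fit.slope(), "t": float(fit.tvalues[1]), "n": len(both)}
        ks = pd.DataFrame({
            "episodic": {sid: np.log10(f["episodic"]["k"])
                         for sid, f in fits["subjects"].items() if "episodic" in f},
            "monetary": {sid: np.log10(f["monetary"]["k"])
                         for sid, f in fits["subjects"].items() if "monetary" in f},
        }).dropna()
        fit = stats.robust_fit(ks["monetary"], ks["episodic"])
        res["log_k_intersubject_correlation"] = {
            "slope": fit.slope(), "t": float(fit.tvalues[1]), "n": len(ks)}

    # Fig-2-style binned summaries
    rich_tabs = [t.astype(float) for t in _richness_tables(cohort)]
    res["rating_vs_richness_binned"] = stats.bin_summary(
        rich_tabs, "richness", "rating", n_bins=8)
    dv_tabs = []
    for s in cohort.subjects:
        trials = s.valued_trials("episodic")
        f = fits["subjects"][s.subject_id]["episodic"]
        vd = model.value_difference(trials, model.ModelParams(k=f["k"], beta=f["beta"]))
        dv_tabs.append(pd.DataFrame({
            "dv_del_imm": -vd["dv_imm_del"],
            "nonimpulsive": (trials["choice"] == "nonimpulsive").astype(float),
        }))
    res["choice_rate_vs_value_binned"] = stats.bin_summary(
        dv_tabs, "dv_del_imm", "nonimpulsive", n_bins=9)

    # prediction scores by condition (fitted per subject over all trials)
    scores = {"ecological": [], "control": []}
    for s in cohort.subjects:
        trials = s.valued_trials("episodic")
        f = fits["subjects"][s.subject_id]["episodic"]
        params = model.ModelParams(k=f["k"], beta=f["beta"])
        cond = pd.concat([sc.trials.assign(session=sc.session)
                          for sc in s.schedules if sc.task == "episodic"],
                         ignore_index=True)["condition"]
        for c in scores:
            sub = trials[cond.to_numpy() == c]
            scores[c].append(model.prediction_score(params, sub))
    res["prediction_score_ecological_pct"] = float(np.nanmean(scores["ecological"]))
    res["prediction_score_control_pct"] = float(np.nanmean(scores["control"]))
    return res


def _interaction_analysis(cohort: Cohort) -> dict:
    """PPI-style GLM: is the BOLD-behaviour correlation ecological-specific?"""
    rates = cohort.choice_rates()
    ep = rates[rates["task"] == "episodic"]
    rows = []
    for s in cohort.subjects:
        for condition, yval in (("ecological", s.bold), ("control", s.bold_control)):
            r = ep[(ep["subject"] == s.subject_id) & (ep["condition"] == condition)]
            rows.append({"subject": s.subject_id, "condition": condition,
                         "Y": yval, "X": float(r["nonimpulsive_rate"].iloc[0]),
                         "age": s.params.age})
    data = pd.DataFrame(rows)
    res = stats.interaction_correlation_test(data, covariates=("age",), side="greater")
    return {"interaction_t": res.interaction_t, "interaction_p": res.interaction_p,
            "df_resid": res.df_resid, "coef": res.coef.to_dict(), "side": res.side}


def _mediation_analysis(cohort: Cohort, n_boot: int, seed: int) -> dict:
    rates = cohort.choice_rates()
    eco = rates[(rates["task"] == "episodic") & (rates["condition"] == "ecological")]
    eco = eco.set_index("subject")["nonimpulsive_rate"]
    man = cohort.manifest().set_index("subject")
    res = mediation.mediate(man["GM"], man["BOLD"], eco.loc[man.index],
                            n_boot=n_boot, seed=stage_seed(seed, "mediate"))
    return res.to_dict()


def run_healthy_experiment(config: RunConfig) -> dict:
    """Full healthy-cohort pipeline: schedules, cohort, fits, behavioural
    statistics, intersubject interaction GLM, and mediation."""
    config.validate()
    cohort = _stage("simulate", simulate_cohort, config.cohort, config.seed)
    fits = _stage("fit", _fit_all, cohort)
    results = {
        "n_subjects": len(cohort.subjects),
        "variant": config.cohort.variant,
        "seed": config.seed,
        "fits": fits,
        "behavior": _stage("behavior", _behavior_analyses, cohort, fits),
        "interaction_glm": _stage("interaction", _interaction_analysis, cohort),
        "mediation": _stage("mediate", _mediation_analysis, cohort,
                            config.n_boot, config.seed),
    }
    if config.outdir is not None:
        write_run_outputs(config, cohort, results)
    return results


def run_patient_experiment(config: RunConfig) -> dict:
    """Patient-cohort pipeline: per-group rates by condition, group
    comparisons, Group x Condition interaction, and the age-adjusted GLM."""
    config.validate()
    if len(config.cohort.groups) < 2:
        raise ValueError("patient experiment needs at least 2 groups")
    cohort = _stage("simulate", simulate_cohort, config.cohort, config.seed)
    rates = cohort.choice_rates()
    ep = rates[rates["task"] == "episodic"]
    results: dict = {
        "seed": config.seed,
        "variant": config.cohort.variant,
        "group_rates": ep.groupby(["group", "condition"])["nonimpulsive_rate"]
                        .agg(["mean", "sem", "count"]).reset_index(),
    }

    inter = _stage("interaction", stats.group_condition_interaction, ep)
    results["group_condition_interaction"] = {
        "F": inter.statistic, "df": list(np.atleast_1d(inter.df)), "p": inter.p}

    wide = ep.pivot_table(index=["subject", "group", "age"], columns="condition",
                          values="nonimpulsive_rate").reset_index()
    wide["delta"] = wide["ecological"] - wide["control"]

    comparisons = {}
    groups = sorted(wide["group"].unique())
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            for cond in ("ecological", "control"):
                a = wide.loc[wide["group"] == ga, cond]
                b = wide.loc[wide["group"] == gb, cond]
                t = sps.ttest_ind(a, b)
                comparisons[f"{ga}_vs_{gb}_{cond}"] = {
                    "t": float(t.statistic), "p": float(t.pvalue),
                    "df": len(a) + len(b) - 2}
    results["group_comparisons"] = comparisons

    if len(groups) == 2:
        adj = _stage("age_glm", stats.covariate_adjusted_group_test,
                     wide["delta"], wide["group"], wide["age"])
        results["age_adjusted_glm"] = {
            "group": _test_dict(adj["group"]),
            **({"age": _test_dict(adj["age"])} if "age" in adj else {}),
            "reference": adj["reference"]}
    if config.outdir is not None:
        write_run_outputs(config, cohort, results)
    return results


# ---------------------------------------------------------------------------
# output bundle + manifest

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_run_outputs(config: RunConfig, cohort: Cohort, results: dict) -> dict:
    """Write schedules, cohort tables and results, then a checksum manifest."""
    out = Path(config.outdir)
    (out / "schedules").mkdir(parents=True, exist_ok=True)
    (out / "cohort").mkdir(exist_ok=True)
    for s in cohort.subjects:
        for sched in s.schedules:
            schedule_to_csv(sched, out / "schedules" /
                            f"{s.subject_id}_s{sched.session}_{sched.task}.csv")
        s.ratings.to_csv(out / "cohort" / f"{s.subject_id}_ratings.csv", index=False)
        s.choices.to_csv(out / "cohort" / f"{s.subject_id}_choices.csv", index=False)
    cohort.manifest().to_csv(out / "cohort" / "cohort_manifest.csv", index=False)
    cohort.choice_rates().to_csv(out / "cohort" / "choice_rates.csv", index=False)
    (out / "results.json").write_text(
        json.dumps(_jsonify(results), indent=2, sort_keys=True))

    cfg_json = json.dumps(_jsonify(config), sort_keys=True, default=str)
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": int(config.seed),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
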