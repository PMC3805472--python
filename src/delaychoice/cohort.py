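"""Synthetic subjects and cohorts for the intertemporal-choice pipeline.

Real participant data are not available, so analyses run on simulated
agents whose generative structure mirrors what the statistics assume:

* item likeability is coupled to simulation richness (agents who imagine a
  Sim option with more detail value it more), both within and between
  subjects;
* choices are drawn from the hyperbolic-discounting + softmax model with
  the agent's true (k, beta);
* group phenotypes dissociate two kinds of impulsivity — AD-like agents
  carry a Sim-specific valuation deficit ``delta_sim`` (ecological-condition
  impulsivity only), bvFTD-like agents an elevated discount rate k
  (impulsivity in every condition);
* per-subject scalar neural measures follow a mediation path: GM ~ Normal,
  BOLD = beta1*GM + noise, and BOLD (plus optionally GM directly) lowers
  the agent's delta_sim, so behaviour sits downstream of the neural chain.

All randomness flows from one master seed through named substreams
(schedule, agent, ratings, choices, neural), so any layer reproduces
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import model, task_design
from ._rng import substream
from .catalog import ItemCatalog, default_catalog

__all__ = [
    "AgentParams",
    "GroupConfig",
    "CohortConfig",
    "SubjectData",
    "Cohort",
    "GROUP_PRESETS",
    "simulate_ratings_and_richness",
    "simulate_choices",
    "simulate_neural",
    "simulate_mediation_triples",
    "simulate_cohort",
]

RICHNESS_LO, RICHNESS_HI = 0, 20
RATING_LO, RATING_HI = -10, 10


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth generative parameters of one synthetic subject."""

    k: float                      # discount rate, per day
    beta: float                   # softmax temperature, rating units
    rating_mean: float = 4.0      # baseline likeability, rating units
    rating_noise_sd: float = 2.0  # item-level valuation noise, rating units
    richness_mean: float = 10.0   # mean imagined detail count, 0-20 scale
    richness_sd: float = 4.0
    richness_slope: float = 0.5   # rating units per imagined detail
    delta_sim: float = 0.0        # Sim-specific value loss, rating units (>= 0)
    group: str = "healthy"
    age: float = 25.0

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not RICHNESS_LO <= self.richness_mean <= RICHNESS_HI:
            raise ValueError("richness mean must lie in [0, 20]")
        if self.delta_sim < 0:
            raise ValueError("delta_sim must be >= 0")


def _trunc_normal(mean, sd, lo, hi, size, rng):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_ratings_and_richness(agent: AgentParams, catalog: ItemCatalog,
                                  rng: np.random.Generator) -> pd.DataFrame:
    """Per-item richness reports and likeability ratings for one agent.

    Richness is a truncated normal on [0, 20], rounded to integers; the
    latent item value is baseline + slope * (richness - richness mean) +
    noise, and the Sim-mode value is additionally reduced by ``delta_sim``
    before rounding and clipping to the [-10, 10] rating scale. Returns one
    row per item with columns ``domain, item, richness, rating_obs,
    rating_sim``.
    """
    frame = catalog.to_frame()
    n = len(frame)
    richness = np.rint(_trunc_normal(agent.richness_mean, agent.richness_sd,
                                     RICHNESS_LO, RICHNESS_HI, n, rng)).astype(int)
    noise = rng.normal(0.0, agent.rating_noise_sd, n) if agent.rating_noise_sd > 0 else 0.0
    latent = agent.rating_mean + agent.richness_slope * (richness - agent.richness_mean) + noise
    rating_obs = np.clip(np.rint(latent), RATING_LO, RATING_HI).astype(int)
    rating_sim = np.clip(np.rint(latent - agent.delta_sim), RATING_LO, RATING_HI).astype(int)
    return pd.DataFrame({
        "domain": frame["domain"],
        "item": frame["item"],
        "richness": richness,
        "rating_obs": rating_obs,
        "rating_sim": rating_sim,
    })


def simulate_choices(agent: AgentParams, schedule: task_design.TrialSchedule,
                     ratings: pd.DataFrame | None,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Trial-by-trial choices from the softmax rule at the agent's true (k, beta).

    Returns columns ``trial_index, p_imp, choice``; ``p_imp`` is the model
    probability of the impulsive (immediate) choice actually used for the
    draw.
    """
    values = model.trial_values(schedule, ratings)
    vd = model.discounted_value(values["R_d"], values["D_days"], agent.k)
    p_imp = model.choice_probability(values["Vi"], vd, agent.beta)
    imp = rng.random(len(values)) < p_imp
    return pd.DataFrame({
        "trial_index": values["trial_index"],
        "p_imp": np.asarray(p_imp, float),
        "choice": np.where(imp, "impulsive", "nonimpulsive"),
    })


def simulate_neural(n: int, beta1: float, bold_noise_sd: float,
                    rng: np.random.Generator,
                    gm_mean: float = 0.0, gm_sd: float = 1.0) -> pd.DataFrame:
    """Per-subject scalar neural measures: GM ~ Normal, BOLD = beta1*GM + noise."""
    if bold_noise_sd < 0 or gm_sd < 0:
        raise ValueError("noise SDs must be >= 0")
    gm = rng.normal(gm_mean, gm_sd, n)
    bold = beta1 * gm + (rng.normal(0.0, bold_noise_sd, n) if bold_noise_sd > 0 else 0.0)
    return pd.DataFrame({"GM": gm, "BOLD": bold})


def simulate_mediation_triples(n: int, beta0: float, beta1: float, beta2: float,
                               rng: np.random.Generator,
                               gm_sd: float = 1.0,
                               bold_noise_sd: float = 0.5,
                               choice_noise_sd: float = 0.5) -> pd.DataFrame:
    """(GM, BOLD, CHOICE) generated directly from the mediation path equations.

    BOLD = beta1*GM + e1 and CHOICE = beta0*GM + beta2*BOLD + e2; the ground
    truth for mediation parameter-recovery and coverage studies.
    """
    neural = simulate_neural(n, beta1, bold_noise_sd, rng, gm_sd=gm_sd)
    e2 = rng.normal(0.0, choice_noise_sd, n) if choice_noise_sd > 0 else 0.0
    neural["CHOICE"] = beta0 * neural["GM"] + beta2 * neural["BOLD"] + e2
    return neural


# ---------------------------------------------------------------------------
# cohort-level simulation

@dataclass(frozen=True)
class GroupConfig:
    """Generative distributions for one group of agents.

    ``delta_sim_base`` is reduced by the neural couplings (``w_bold *
    BOLD + w_gm * GM``) and clipped at zero to give each agent's
    ``delta_sim``, which builds the GM -> BOLD -> behaviour mediation chain
    into the cohort when the couplings are non-zero.
    """

    n: int = 20
    group: str = "healthy"
    log10_k_mean: float = -3.0
    log10_k_sd: float = 0.5
    ln_beta_mean: float = math.log(2.0)
    ln_beta_sd: float = 0.2
    rating_mean: float = 4.0
    rating_between_sd: float = 1.0   # between-subject spread of baseline liking
    rating_noise_sd: float = 2.0
    richness_mean: float = 10.0
    richness_between_sd: float = 3.0
    richness_sd: float = 4.0
    richness_slope: float = 0.5
    richness_between_slope: float = 0.3  # couples mean richness to baseline liking
    delta_sim_base: float = 0.0
    delta_sim_sd: float = 0.0
    w_bold: float = 0.0
    w_gm: float = 0.0
    age_mean: float = 25.0
    age_sd: float = 2.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("log10_k_sd", "ln_beta_sd", "rating_between_sd",
                     "rating_noise_sd", "richness_between_sd", "richness_sd",
                     "delta_sim_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: default phenotypes: healthy young (neural coupling on), elderly control,
#: AD-like (Sim-specific value loss), bvFTD-like (10x steeper discounting)
GROUP_PRESETS = {
    "healthy": GroupConfig(group="healthy", delta_sim_base=3.0, w_bold=1.5,
                           age_mean=24.0, age_sd=2.0),
    "CTL": GroupConfig(group="CTL", age_mean=72.0, age_sd=6.0),
    "AD": GroupConfig(group="AD", delta_sim_base=5.0, delta_sim_sd=1.0,
                      age_mean=76.0, age_sd=6.0),
    "bvFTD": GroupConfig(group="bvFTD", log10_k_mean=-2.0,
                         age_mean=66.0, age_sd=8.0),
}


@dataclass
class CohortConfig:
    """Everything needed to simulate a cohort deterministically."""

    groups: list                     # list[GroupConfig]
    variant: str = "exp2"
    n_episodic_sessions: int = 2
    include_monetary: bool = True
    beta1: float = 1.0               # GM -> BOLD path used for neural generation
    bold_noise_sd: float = 1.0
    catalog: ItemCatalog = field(default_factory=default_catalog)

    def validate(self):
        if not self.groups:
            raise ValueError("cohort config must define at least one group")
        if sum(g.n for g in self.groups) < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.bold_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        task_design._check_variant(self.variant)
        return self


@dataclass
class SubjectData:
    """One simulated subject: parameters, ratings, schedules, choices, neural."""

    subject_id: str
    params: AgentParams
    ratings: pd.DataFrame
    schedules: list
    choices: pd.DataFrame            # trial_index, session, task, p_imp, choice
    gm: float
    bold: float                      # ecological nonimpulsive-minus-impulsive contrast
    bold_control: float = 0.0        # same contrast in the control condition (null)

    def valued_trials(self, task: str = "episodic") -> pd.DataFrame:
        """Concatenated valued-trial table over this subject's sessions of ``task``."""
        parts = []
        for sched in self.schedules:
            if sched.task != task:
                continue
            ch = self.choices[(self.choices["session"] == sched.session)
                              & (self.choices["task"] == sched.task)]
            parts.append(model.make_valued_trials(sched, self.ratings, ch))
        if not parts:
            raise ValueError(f"subject has no {task!r} sessions")
        return pd.concat(parts, ignore_index=True)


@dataclass
class Cohort:
    subjects: list
    config: CohortConfig
    seed: int

    def manifest(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            p = s.params
            rows.append({
                "subject": s.subject_id, "group": p.group, "age": p.age,
                "k": p.k, "beta": p.beta, "delta_sim": p.delta_sim,
                "GM": s.gm, "BOLD": s.bold, "BOLD_control": s.bold_control,
            })
        return pd.DataFrame(rows)

    def choice_rates(self) -> pd.DataFrame:
        """Per subject x task x condition nonimpulsive choice rate (tidy)."""
        rows = []
        for s in self.subjects:
            merged = []
            for sched in s.schedules:
                t = sched.trials[["trial_index", "condition"]].copy()
                t["session"] = sched.session
                t["task"] = sched.task
                merged.append(t)
            cond = pd.concat(merged, ignore_index=True)
            ch = s.choices.merge(cond, on=["trial_index", "session", "task"])
            for (task, condition), sub in ch.groupby(["task", "condition"]):
                rows.append({
                    "subject": s.subject_id, "group": s.params.group,
                    "age": s.params.age, "task": task, "condition": condition,
                    "nonimpulsive_rate": float((sub["choice"] == "nonimpulsive").mean()),
                })
        return pd.DataFrame(rows)


def _draw_agent(g: GroupConfig, gm: float, bold: float,
                rng: np.random.Generator) -> AgentParams:
    richness_mean = float(_trunc_normal(g.richness_mean, g.richness_between_sd,
                                        RICHNESS_LO, RICHNESS_HI, 1, rng)[0])
    rating_mean = (g.rating_mean
                   + g.richness_between_slope * (richness_mean - g.richness_mean)
                   + (rng.normal(0.0, g.rating_between_sd) if g.rating_between_sd > 0 else 0.0))
    delta_base = g.delta_sim_base + (rng.normal(0.0, g.delta_sim_sd)
                                     if g.delta_sim_sd > 0 else 0.0)
    delta_sim = max(0.0, delta_base - g.w_bold * bold - g.w_gm * gm)
    return AgentParams(
        k=float(10.0 ** rng.normal(g.log10_k_mean, g.log10_k_sd)),
        beta=float(np.exp(rng.normal(g.ln_beta_mean, g.ln_beta_sd))),
        rating_mean=float(rating_mean),
        rating_noise_sd=g.rating_noise_sd,
        richness_mean=richness_mean,
        richness_sd=g.richness_sd,
        richness_slope=g.richness_slope,
        delta_sim=float(delta_sim),
        group=g.group,
        age=float(rng.normal(g.age_mean, g.age_sd)),
    )


def simulate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Simulate a full cohort: neural -> agents -> ratings -> schedules -> choices."""
    config.validate()
    catalog = config.catalog
    if config.variant == "expB":
        catalog = catalog.restrict(("food",))
    subjects = []
    idx = 0
    for g in config.groups:
        neural_rng = substream(seed, f"neural:{g.group}")
        neural = simulate_neural(g.n, config.beta1, config.bold_noise_sd, neural_rng)
        # control-condition contrast: same marginal spread, no coupling to GM
        # or behaviour (the ecological specificity the interaction GLM tests)
        bold_sd = float(np.hypot(config.beta1, config.bold_noise_sd))
        bold_ctl = neural_rng.normal(0.0, bold_sd, g.n)
        for j in range(g.n):
            gm, bold = float(neural["GM"][j]), float(neural["BOLD"][j])
            agent = _draw_agent(g, gm, bold, substream(seed, "agent", idx))
            ratings = simulate_ratings_and_richness(
                agent, catalog, substream(seed, "ratings", idx))
            schedules = []
            for sess in range(config.n_episodic_sessions):
                schedules.append(task_design.generate_episodic_schedule(
                    config.variant, catalog,
                    substream(seed, "schedule", idx * 17 + sess).integers(2**31),
                    session=sess))
            if config.include_monetary and config.variant != "expB":
                schedules.append(task_design.generate_monetary_schedule(
                    config.variant,
                    substream(seed, "schedule", idx * 17 + 13).integers(2**31),
                    session=config.n_episodic_sessions))
            choice_parts = []
            for sched in schedules:
                ch = simulate_choices(agent, sched, ratings,
                                      substream(seed, "choices", idx * 17 + sched.session))
                ch["session"] = sched.session
                ch["task"] = sched.task
                choice_parts.append(ch)
            subjects.append(SubjectData(
                subject_id=f"{g.group}_{j:03d}",
                params=agent,
                ratings=ratings,
                schedules=schedules,
                choices=pd.concat(choice_parts, ignore_index=True),
                gm=gm,
                bold=bold,
                bold_control=float(bold_ctl[j]),
            ))
            idx += 1
    return Cohort(subjects=subjects, config=config, seed=seed)
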