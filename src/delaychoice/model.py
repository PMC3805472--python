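"""Hyperbolic discounting + softmax choice model and its ML fitting.

The model values a delayed reward as V = R / (1 + k*D), with R the
likeability rating (episodic task) or the rescaled monetary payoff, D the
delay in days and k the subject's discount rate. Given the discounted
values, the probability of the impulsive choice (taking the immediate
option) follows a softmax rule

    P_imp = exp(Vi/beta) / (exp(Vi/beta) + exp(Vd/beta))

with temperature beta. (k, beta) are adjusted over all conditions and
domains to maximize the log-likelihood of the observed choices, either per
subject or pooled over a group. Monetary amounts are first mapped affinely
onto the [-10, 10] rating interval so both tasks share one value scale.

Valued trials are exchanged as a DataFrame with columns ``Vi`` (immediate
value), ``R_d`` (undiscounted delayed value), ``D_days`` (delay, > 0) and
``choice`` ("impulsive" | "nonimpulsive").
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ModelParams",
    "FitResult",
    "transform_monetary",
    "discounted_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_parameters",
    "prediction_score",
    "value_difference",
    "trial_values",
    "make_valued_trials",
]

RATING_LO, RATING_HI = -10.0, 10.0

#: deterministic search grid: log10 k over [-5, 0], natural-log beta over [-2, 3]
GRID_LOG10K = np.linspace(-5.0, 0.0, 25)
GRID_LNBETA = np.linspace(-2.0, 3.0, 25)


@dataclass(frozen=True)
class ModelParams:
    """Discount rate k (per day) and softmax temperature beta (value units)."""

    k: float
    beta: float

    def __post_init__(self):
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


@dataclass
class FitResult:
    """Maximum-likelihood estimate with fit diagnostics."""

    params: ModelParams
    log_likelihood: float
    n_trials: int
    prediction_score: float
    boundary: bool
    degenerate: bool
    mode: str  # "subject" | "group"

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(k=self.params.k, beta=self.params.beta)
        del d["params"]
        return d


def transform_monetary(amounts, amount_range=None):
    """Affine map of euro amounts onto the [-10, 10] rating interval.

    By default the empirical [min, max] of ``amounts`` (the union of a
    session's immediate and delayed payoffs) maps to [-10, 10]; pass
    ``amount_range=(lo, hi)`` to use a fixed theoretical range instead.
    """
    a = np.asarray(amounts, dtype=float)
    lo, hi = amount_range if amount_range is not None else (a.min(), a.max())
    if not hi > lo:
        raise ValueError("degenerate amount range: all amounts equal")
    return RATING_LO + (RATING_HI - RATING_LO) * (a - lo) / (hi - lo)


def discounted_value(R, D, k):
    """Hyperbolic present value V = R / (1 + k*D)."""
    R = np.asarray(R, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("delay D must be >= 0")
    if np.any(np.asarray(k) < 0):
        raise ValueError("discount rate k must be >= 0")
    return R / (1.0 + k * D)


def choice_probability(Vi, Vd, beta):
    """P(impulsive) under the softmax rule, in the overflow-safe logistic form."""
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be > 0")
    return special.expit((np.asarray(Vi, float) - np.asarray(Vd, float)) / beta)


def _unpack(trials: pd.DataFrame):
    vi = trials["Vi"].to_numpy(float)
    rd = trials["R_d"].to_numpy(float)
    d = trials["D_days"].to_numpy(float)
    imp = trials["choice"].to_numpy()
    if not np.isin(imp, ("impulsive", "nonimpulsive")).all():
        raise ValueError("choice column must be 'impulsive' or 'nonimpulsive'")
    sign = np.where(imp == "impulsive", 1.0, -1.0)
    return vi, rd, d, sign


def negative_log_likelihood(params: ModelParams, trials: pd.DataFrame) -> float:
    """-sum log P(observed choice | k, beta) over the trial table."""
    if len(trials) == 0:
        raise ValueError("empty trial list")
    vi, rd, d, sign = _unpack(trials)
    vd = discounted_value(rd, d, params.k)
    # log P(choice) = log_expit(sign * (Vi - Vd)/beta), sign=+1 for impulsive
    return float(-special.log_expit(sign * (vi - vd) / params.beta).sum())


def _grid_nll(vi, rd, d, sign, log10k=GRID_LOG10K, lnbeta=GRID_LNBETA):
    """NLL over the full (k, beta) grid; returns (nll[nk, nb], k, beta)."""
    k = 10.0 ** np.asarray(log10k)
    beta = np.exp(np.asarray(lnbeta))
    vd = rd[None, :] / (1.0 + k[:, None] * d[None, :])  # (nk, n)
    s = sign[None, :] * (vi[None, :] - vd)  # (nk, n)
    nll = -special.log_expit(s[:, None, :] / beta[None, :, None]).sum(axis=2)
    return nll, k, beta


def fit_parameters(trials: pd.DataFrame, mode: str = "subject") -> FitResult:
    """Fit (k, beta) by maximum likelihood: coarse grid + Nelder-Mead refinement.

    Parameters are searched in log space (positivity by construction) on a
    deterministic 25x25 grid, then refined from the grid optimum; no random
    restarts, so the result is a pure function of the trial table. ``mode``
    is recorded on the result; group fits pool all rows into one likelihood
    (callers concatenate subjects' tables).

    Degenerate data (all choices identical, or all value contrasts zero)
    never raises: the result carries ``degenerate=True`` and, when the
    optimum sits on the search-grid edge, ``boundary=True``.
    """
    if mode not in ("subject", "group"):
        raise ValueError(f"mode must be 'subject' or 'group', got {mode!r}")
    if len(trials) == 0:
        raise ValueError("empty trial list")
    vi, rd, d, sign = _unpack(trials)
    degenerate = (len(set(sign)) == 1)

    nll_grid, kg, bg = _grid_nll(vi, rd, d, sign)
    ik, ib = np.unravel_index(np.argmin(nll_grid), nll_grid.shape)
    x0 = np.array([GRID_LOG10K[ik], GRID_LNBETA[ib]])

    def fun(x):
        k, beta = 10.0 ** x[0], np.exp(x[1])
        vd = rd / (1.0 + k * d)
        return -special.log_expit(sign * (vi - vd) / beta).sum()

    res = optimize.minimize(fun, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500})
    x = res.x
    boundary = bool(
        x[0] <= GRID_LOG10K[0] or x[0] >= GRID_LOG10K[-1]
        or x[1] <= GRID_LNBETA[0] or x[1] >= GRID_LNBETA[-1]
    )
    params = ModelParams(k=float(10.0 ** x[0]), beta=float(np.exp(x[1])))
    score = prediction_score(params, trials)
    return FitResult(
        params=params,
        log_likelihood=float(-res.fun),
        n_trials=len(trials),
        prediction_score=score,
        boundary=boundary or degenerate,
        degenerate=degenerate,
        mode=mode,
    )


def prediction_score(params: ModelParams, trials: pd.DataFrame) -> float:
    """Percentage of trials where the higher-valued option was chosen.

    Trials whose two discounted values tie exactly are excluded from the
    denominator ("the higher value estimate" is undefined there); returns
    NaN if every trial is tied.
    """
    vi, rd, d, sign = _unpack(trials)
    vd = discounted_value(rd, d, params.k)
    untied = vi != vd
    if not untied.any():
        return float("nan")
    model_imp = vi[untied] > vd[untied]
    chose_imp = sign[untied] > 0
    return float(100.0 * (model_imp == chose_imp).mean())


def value_difference(trials: pd.DataFrame, params: ModelParams) -> pd.DataFrame:
    """Per-trial signed value contrasts under the fitted model.

    Returns columns ``Vi``, ``Vd``, ``dv_imm_del`` (Vi - Vd) and
    ``dv_chosen_unchosen`` (value of the chosen minus unchosen option) for
    downstream binning and summaries.
    """
    vi, rd, d, sign = _unpack(trials)
    vd = discounted_value(rd, d, params.k)
    dv = vi - vd
    return pd.DataFrame({
        "Vi": vi,
        "Vd": vd,
        "dv_imm_del": dv,
        "dv_chosen_unchosen": np.where(sign > 0, dv, -dv),
    }, index=trials.index)


def trial_values(schedule, ratings: pd.DataFrame | None = None) -> pd.DataFrame:
    """Option values (Vi, R_d) for every trial of one session.

    For episodic sessions ``ratings`` must hold one row per item with
    columns ``item``, ``rating_obs``, ``rating_sim`` (the value the subject
    assigns to the item under each presentation mode); a scheduled item
    missing from the table raises, naming the item. Monetary sessions
    ignore ``ratings`` and rescale the session's amounts onto [-10, 10].
    """
    t = schedule.trials
    if schedule.task == "monetary":
        amounts = np.concatenate([t["imm_amount"], t["del_amount"]])
        scaled = transform_monetary(amounts)
        vi, rdel = scaled[: len(t)], scaled[len(t):]
    else:
        if ratings is None:
            raise ValueError("episodic schedules require a ratings table")
        by_item = ratings.set_index("item")
        vi, rdel = [], []
        for _, row in t.iterrows():
            for item, mode, dest in ((row["imm_item"], row["imm_mode"], vi),
                                     (row["del_item"], row["del_mode"], rdel)):
                if item not in by_item.index:
                    raise KeyError(f"no rating for scheduled item {item!r}")
                dest.append(float(by_item.loc[item, f"rating_{mode}"]))
    return pd.DataFrame({
        "trial_index": t["trial_index"].to_numpy(),
        "Vi": np.asarray(vi, float),
        "R_d": np.asarray(rdel, float),
        "D_days": t["delay_days"].to_numpy(float),
    })


def make_valued_trials(schedule, ratings: pd.DataFrame | None,
                       choices: pd.DataFrame) -> pd.DataFrame:
    """Valued-trial table (see :func:`trial_values`) joined with observed choices."""
    out = trial_values(schedule, ratings)
    ch = choices.set_index("trial_index")["choice"]
    out["choice"] = out["trial_index"].map(ch).to_numpy()
    if out["choice"].isna().any():
        missing = out.loc[out["choice"].isna(), "trial_index"].tolist()
        raise ValueError(f"missing choices for trials {missing}")
    return out
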