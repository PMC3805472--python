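"""Generation and validation of intertemporal-choice task schedules.

The episodic task opposes a less pleasant immediate item to a more pleasant
delayed item; the presentation mode of each option is either observed
(picture, "obs") or simulated (text only, "sim"). A full session holds 72
trials — 36 obs/sim (ecological condition: immediate observed, delayed
simulated), 18 obs/obs and 18 sim/sim (control condition) — with domain
(food/culture/sport), condition and delay (1 month / 1 year / 10 years)
fully crossed. The monetary task keeps the same condition x delay structure
but the options are euro payoffs: immediate amounts are a without-replacement
draw from the 0.5:0.5:36 grid and each delayed amount adds an extra drawn
without replacement from 1:36.

Variant ``expA`` reuses the full episodic factorial with choice screens only;
variant ``expB`` restricts to the food domain with delays 1 day / 1 month /
5 years (36 trials by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ItemCatalog

__all__ = [
    "TrialSchedule",
    "ValidationReport",
    "generate_episodic_schedule",
    "generate_monetary_schedule",
    "validate_schedule",
    "schedule_to_csv",
    "schedule_from_csv",
    "DELAY_DAYS",
    "IMMEDIATE_GRID",
    "EXTRA_GRID",
]

# Delay-to-days conversion: 1 day=1, 1 month=30, 1 year=365, 5 years=1825,
# 10 years=3650.
DELAY_DAYS = {"1 day": 1, "1 month": 30, "1 year": 365, "5 years": 1825, "10 years": 3650}

#: delay sets (in days) per experiment variant
VARIANT_DELAYS = {
    "exp1": (30, 365, 3650),
    "exp2": (30, 365, 3650),
    "expA": (30, 365, 3650),
    "expB": (1, 30, 1825),
}

#: immediate monetary amounts, EUR (72 values)
IMMEDIATE_GRID = tuple(np.arange(0.5, 36.001, 0.5))
#: extra amounts added to form the delayed payoff, EUR (36 values)
EXTRA_GRID = tuple(range(1, 37))

SUBTYPES = ("obs_sim", "obs_obs", "sim_sim")
#: per-session trial count by subtype for a full 72-trial session
FULL_SUBTYPE_COUNTS = {"obs_sim": 36, "obs_obs": 18, "sim_sim": 18}
#: expB keeps the same 2:1:1 ratio over 36 trials
EXPB_SUBTYPE_COUNTS = {"obs_sim": 18, "obs_obs": 9, "sim_sim": 9}

_SUBTYPE_MODES = {"obs_sim": ("obs", "sim"), "obs_obs": ("obs", "obs"), "sim_sim": ("sim", "sim")}

CSV_COLUMNS = [
    "trial_index", "task", "variant", "session", "subtype", "condition",
    "domain", "delay_days", "imm_mode", "del_mode", "imm_item", "del_item",
    "imm_amount", "del_amount", "order_flag", "imm_side",
]


@dataclass
class TrialSchedule:
    """One session's ordered trial table.

    ``trials`` is a DataFrame with one row per trial (columns as in
    :data:`CSV_COLUMNS`); episodic rows carry item labels and NaN amounts,
    monetary rows the reverse.
    """

    variant: str
    task: str  # "episodic" | "monetary"
    session: int
    trials: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def delays(self) -> tuple:
        return tuple(sorted(self.trials["delay_days"].unique()))


def _check_variant(variant: str) -> str:
    if variant not in VARIANT_DELAYS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANT_DELAYS)}"
        )
    return variant


def _counterbalanced(labels, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact half/half assignment of two labels over n trials, shuffled."""
    half = n // 2
    arr = np.array([labels[0]] * half + [labels[1]] * (n - half), dtype=object)
    rng.shuffle(arr)
    return arr


class _ItemDeck:
    """Per-domain shuffled deck consumed without replacement.

    Reshuffled from the full list whenever fewer than two items remain, so
    the two options of any single trial are always distinct.
    """

    def __init__(self, items, rng: np.random.Generator):
        self._items = list(items)
        self._rng = rng
        self._deck: list = []

    def draw_pair(self):
        if len(self._deck) < 2:
            self._deck = list(self._items)
            self._rng.shuffle(self._deck)
        return self._deck.pop(), self._deck.pop()


def _finalize(rows, variant, task, session, rng) -> TrialSchedule:
    n = len(rows)
    order = rng.permutation(n)
    df = pd.DataFrame([rows[i] for i in order])
    df["order_flag"] = _counterbalanced(("imm_first", "del_first"), n, rng)
    df["imm_side"] = _counterbalanced(("left", "right"), n, rng)
    df["trial_index"] = np.arange(n)
    df["task"] = task
    df["variant"] = variant
    df["session"] = session
    if task == "episodic":
        df["imm_amount"] = np.nan
        df["del_amount"] = np.nan
        df["imm_item"] = ""   # filled by the generator after the order shuffle
        df["del_item"] = ""
    else:
        df["imm_item"] = ""
        df["del_item"] = ""
        df["imm_amount"] = np.nan  # filled by the generator after the order shuffle
        df["del_amount"] = np.nan
        df["domain"] = "monetary"
    return TrialSchedule(variant, task, session, df[CSV_COLUMNS].reset_index(drop=True))


def generate_episodic_schedule(
    variant: str,
    catalog: ItemCatalog,
    seed: int,
    session: int = 0,
) -> TrialSchedule:
    """Generate one episodic session for ``variant`` from ``catalog``.

    Full variants cross subtype x domain x delay with equal cell counts
    (4 obs/sim and 2 of each control subtype per domain-delay cell); expB
    crosses subtype x delay in the food domain only. Trial order, item
    draws, presentation order and screen side are randomized per ``seed``.
    """
    _check_variant(variant)
    rng = np.random.default_rng(seed)
    delays = VARIANT_DELAYS[variant]
    if variant == "expB":
        domains = ("food",)
        subtype_counts = EXPB_SUBTYPE_COUNTS
    else:
        domains = ("food", "culture", "sport")
        subtype_counts = FULL_SUBTYPE_COUNTS
    for d in domains:
        if catalog.n_items(d) < 2:
            raise ValueError(
                f"catalog too small in domain {d!r}: need at least 2 items, "
                f"have {catalog.n_items(d)}"
            )

    decks = {d: _ItemDeck(catalog.items[d], rng) for d in domains}
    rows = []
    for subtype, total in subtype_counts.items():
        reps = total // (len(domains) * len(delays))
        imm_mode, del_mode = _SUBTYPE_MODES[subtype]
        for domain in domains:
            for delay in delays:
                for _ in range(reps):
                    rows.append({
                        "subtype": subtype,
                        "condition": "ecological" if subtype == "obs_sim" else "control",
                        "domain": domain,
                        "delay_days": delay,
                        "imm_mode": imm_mode,
                        "del_mode": del_mode,
                    })
    sched = _finalize(rows, variant, "episodic", session, rng)
    # items are drawn in presentation order (after the order shuffle)
    imm_items, del_items = [], []
    for domain in sched.trials["domain"]:
        a, b = decks[domain].draw_pair()
        imm_items.append(a)
        del_items.append(b)
    sched.trials["imm_item"] = imm_items
    sched.trials["del_item"] = del_items
    return sched


def generate_monetary_schedule(variant: str, seed: int, session: int = 0) -> TrialSchedule:
    """Generate one 72-trial monetary session.

    Immediate payoffs use each value of the 0.5:0.5:36 grid exactly once;
    extras are drawn without replacement from 1:36 within each half-session
    block of 36 trials (the 36-element vector is refilled once).
    """
    _check_variant(variant)
    if variant == "expB":
        raise ValueError("the monetary task has no expB variant")
    rng = np.random.default_rng(seed)
    delays = VARIANT_DELAYS[variant]
    rows = []
    for subtype, total in FULL_SUBTYPE_COUNTS.items():
        reps = total // len(delays)
        imm_mode, del_mode = _SUBTYPE_MODES[subtype]
        for delay in delays:
            for _ in range(reps):
                rows.append({
                    "subtype": subtype,
                    "condition": "ecological" if subtype == "obs_sim" else "control",
                    "domain": "monetary",
                    "delay_days": delay,
                    "imm_mode": imm_mode,
                    "del_mode": del_mode,
                })
    sched = _finalize(rows, variant, "monetary", session, rng)
    n = len(sched.trials)
    imm = rng.permutation(np.asarray(IMMEDIATE_GRID))
    extras = np.concatenate([
        rng.permutation(np.asarray(EXTRA_GRID, dtype=float))
        for _ in range(0, n, len(EXTRA_GRID))
    ])[:n]
    sched.trials["imm_amount"] = imm[:n]
    sched.trials["del_amount"] = imm[:n] + extras
    return sched


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Outcome of every schedule invariant check."""

    checks: list = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "", offending=()):
        self.checks.append({
            "check": name,
            "passed": bool(passed),
            "detail": detail,
            "offending_trials": list(offending),
        })

    @property
    def passed(self) -> bool:
        return all(c["passed"] for c in self.checks)

    def failures(self) -> list:
        return [c for c in self.checks if not c["passed"]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.checks)


def _expected_counts(schedule: TrialSchedule) -> dict:
    if schedule.task == "episodic" and schedule.variant == "expB":
        return EXPB_SUBTYPE_COUNTS
    return FULL_SUBTYPE_COUNTS


def validate_schedule(schedule: TrialSchedule) -> ValidationReport:
    """Check every session invariant; always returns a full report."""
    t = schedule.trials
    rep = ValidationReport()
    expected = _expected_counts(schedule)
    n_expected = sum(expected.values())

    rep.add("trial_count", len(t) == n_expected,
            f"expected {n_expected}, got {len(t)}")

    counts = t["subtype"].value_counts().to_dict()
    ok = all(counts.get(s, 0) == c for s, c in expected.items())
    rep.add("subtype_counts", ok, f"expected {expected}, got {counts}")

    eco_ok = (t["subtype"].eq("obs_sim") == t["condition"].eq("ecological"))
    rep.add("condition_consistency", eco_ok.all(),
            "ecological iff subtype obs_sim",
            t.index[~eco_ok])

    delay_ok = t["delay_days"].gt(0)
    rep.add("positive_delay", delay_ok.all(),
            "delayed option delay must be > 0 (immediate option is delay 0)",
            t.index[~delay_ok])

    allowed = set(VARIANT_DELAYS.get(schedule.variant, ()))
    in_set = t["delay_days"].isin(allowed)
    rep.add("delay_set", in_set.all(),
            f"delays must lie in {sorted(allowed)}", t.index[~in_set])

    # equal delay frequency within each subtype
    bal = True
    for s, sub in t.groupby("subtype"):
        vc = sub["delay_days"].value_counts()
        bal &= (len(set(vc)) == 1) and (len(vc) == 3)
    rep.add("delay_balance_within_subtype", bal,
            "each delay equally frequent within each subtype")

    if schedule.task == "episodic":
        bal = True
        for s, sub in t.groupby("subtype"):
            vc = sub.groupby(["domain", "delay_days"]).size()
            bal &= len(set(vc)) == 1
        rep.add("domain_delay_crossing", bal,
                "domain x delay fully crossed with equal frequency per subtype")

    # equal numbers of obs and sim options within each condition
    mode_ok = True
    detail = []
    for cond, sub in t.groupby("condition"):
        modes = pd.concat([sub["imm_mode"], sub["del_mode"]]).value_counts()
        detail.append(f"{cond}: {modes.to_dict()}")
        mode_ok &= modes.get("obs", 0) == modes.get("sim", 0)
    rep.add("obs_sim_option_balance", mode_ok,
            "equal obs and sim option counts per condition; " + "; ".join(detail))

    for col, labels in (("order_flag", ("imm_first", "del_first")),
                        ("imm_side", ("left", "right"))):
        vc = t[col].value_counts()
        ok = abs(vc.get(labels[0], 0) - vc.get(labels[1], 0)) <= len(t) % 2
        rep.add(f"counterbalance_{col}", ok, f"{vc.to_dict()}")

    if schedule.task == "monetary":
        imm = t["imm_amount"].to_numpy(float)
        grid = np.asarray(IMMEDIATE_GRID)
        on_grid = np.isin(imm, grid)
        rep.add("imm_amount_grid", on_grid.all(),
                "immediate amounts from the 0.5:0.5:36 grid", t.index[~on_grid])
        rep.add("imm_amount_distinct", len(np.unique(imm)) == len(imm),
                "immediate amounts drawn without replacement")
        extra = t["del_amount"].to_numpy(float) - imm
        in_range = (extra >= 1) & (extra <= 36)
        rep.add("extra_range", in_range.all(),
                "delayed - immediate in [1, 36]", t.index[~in_range])
        vc = pd.Series(extra).value_counts()
        per = len(t) // len(EXTRA_GRID)
        rep.add("extra_without_replacement",
                set(vc.index) <= set(float(e) for e in EXTRA_GRID)
                and (vc == per).all() and len(vc) == len(EXTRA_GRID),
                f"each extra value used exactly {per}x across the session")
    else:
        same = t["imm_item"] == t["del_item"]
        rep.add("distinct_items", ~same.any(),
                "the two options of a trial are different items", t.index[same])
    return rep


# ---------------------------------------------------------------------------
# serialization (UTF-8 CSV, header row, dot decimal)

def schedule_to_csv(schedule: TrialSchedule, path) -> None:
    schedule.trials.to_csv(path, index=False)


def schedule_from_csv(path) -> TrialSchedule:
    df = pd.read_csv(path, keep_default_na=False,
                     na_values={"imm_amount": [""], "del_amount": [""]})
    df = df[CSV_COLUMNS]
    return TrialSchedule(
        variant=str(df["variant"].iloc[0]),
        task=str(df["task"].iloc[0]),
        session=int(df["session"].iloc[0]),
        trials=df.reset_index(drop=True),
    )
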