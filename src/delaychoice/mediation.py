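"""Bootstrap mediation analysis linking anatomy, activity, and behaviour.

Tests whether the relation between a per-subject anatomical measure (GM,
grey-matter density) and behaviour (CHOICE, e.g., the ecological
nonimpulsive choice rate) is explained by a functional measure (BOLD).
Two linear models are estimated by OLS (intercepts included):

    BOLD   = b1 * GM
    CHOICE = b0 * GM + b2 * BOLD

The indirect (mediated) effect is b1*b2, the direct effect b0, and their
sum equals the marginal GM coefficient of CHOICE ~ GM exactly (an OLS
identity, asserted on every run). Path significance uses a nonparametric
case-resampling bootstrap of subjects (default 10,000 bootsamples) with
percentile confidence intervals; bias-corrected accelerated (BCa)
intervals are available as an option. "Full mediation" is flagged when the
indirect CI excludes zero while the direct CI contains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["MediationResult", "PathEstimate", "mediate"]

PATHS = ("b1", "b2", "b0", "indirect", "total")


@dataclass
class PathEstimate:
    estimate: float
    se: float            # bootstrap standard deviation
    ci: tuple            # (lo, hi)
    p: float             # doubled bootstrap tail proportion

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class MediationResult:
    paths: dict                   # name -> PathEstimate
    n: int
    n_boot: int
    seed: int
    ci_method: str
    alpha: float
    full_mediation: bool
    total_effect_gap: float       # |total - (b0 + b1*b2)|, ~ machine precision
    boot_distributions: dict = field(default_factory=dict, repr=False)

    def __getitem__(self, name: str) -> PathEstimate:
        return self.paths[name]

    def to_dict(self) -> dict:
        return {
            "n": self.n, "n_boot": self.n_boot, "seed": self.seed,
            "ci_method": self.ci_method, "alpha": self.alpha,
            "full_mediation": self.full_mediation,
            "paths": {
                name: {"estimate": p.estimate, "se": p.se,
                       "ci_low": p.ci[0], "ci_high": p.ci[1], "p": p.p}
                for name, p in self.paths.items()
            },
        }


def _design(x_cols, n):
    return np.column_stack([np.ones(n)] + list(x_cols))


def _fit_paths(gm, bold, choice, cov):
    """(b1, b2, b0, indirect, total) by OLS on one sample."""
    n = len(gm)
    Xg = _design([gm] + cov, n)
    Xgb = _design([gm, bold] + cov, n)
    c1, *_ = np.linalg.lstsq(Xg, bold, rcond=None)
    c2, *_ = np.linalg.lstsq(Xgb, choice, rcond=None)
    ct, *_ = np.linalg.lstsq(Xg, choice, rcond=None)
    b1, b0, b2, total = c1[1], c2[1], c2[2], ct[1]
    return np.array([b1, b2, b0, b1 * b2, total])


def _boot_paths_closed_form(gm, bold, choice, idx):
    """Vectorized no-covariate bootstrap: path estimates per resample.

    Uses centered cross-moments per bootstrap sample; algebraically
    identical to per-sample OLS with intercepts.
    """
    g, b, c = gm[idx], bold[idx], choice[idx]
    g = g - g.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    c = c - c.mean(axis=1, keepdims=True)
    sgg = (g * g).sum(axis=1)
    sgb = (g * b).sum(axis=1)
    sbb = (b * b).sum(axis=1)
    sgc = (g * c).sum(axis=1)
    sbc = (b * c).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = sgb / sgg
        det = sgg * sbb - sgb**2
        b0 = (sbb * sgc - sgb * sbc) / det
        b2 = (sgg * sbc - sgb * sgc) / det
        total = sgc / sgg
    return np.column_stack([b1, b2, b0, b1 * b2, total])


def _bca_interval(dist, point, jack, alpha):
    """Bias-corrected accelerated interval from a bootstrap distribution."""
    z0 = sps.norm.ppf(np.clip((dist < point).mean(), 1e-10, 1 - 1e-10))
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum() ** 1.5)
    a = num / den if den > 0 else 0.0
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        z = sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        out.append(float(np.quantile(dist, adj)))
    return tuple(out)


def mediate(gm, bold, choice, n_boot: int = 10_000, seed: int = 0,
            covariates: pd.DataFrame | None = None,
            standardize: bool = False,
            ci_method: str = "percentile",
            alpha: float = 0.05) -> MediationResult:
    """Three-variable mediation with bootstrap significance tests.

    Parameters are per-subject scalars of equal length (n >= 5). Optional
    ``covariates`` (one column per nuisance variable, e.g. age) enter both
    path regressions. ``standardize`` z-scores GM, BOLD and CHOICE before
    estimation. Two-sided p-values are twice the smaller bootstrap tail
    proportion around zero.
    """
    gm = np.asarray(gm, float)
    bold = np.asarray(bold, float)
    choice = np.asarray(choice, float)
    n = len(gm)
    if not (len(bold) == len(choice) == n):
        raise ValueError("GM, BOLD and CHOICE must have equal length")
    if n < 5:
        raise ValueError("mediation needs at least 5 subjects")
    if np.ptp(gm) == 0 or np.ptp(bold) == 0:
        raise ValueError("constant GM or BOLD: no identifiable path")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small; intervals will be unstable",
                      UserWarning)
    if ci_method not in ("percentile", "bca"):
        raise ValueError("ci_method must be 'percentile' or 'bca'")

    if standardize:
        gm = (gm - gm.mean()) / gm.std(ddof=1)
        bold = (bold - bold.mean()) / bold.std(ddof=1)
        choice = (choice - choice.mean()) / choice.std(ddof=1)

    cov = []
    if covariates is not None and len(covariates.columns) > 0:
        cov = [np.asarray(covariates[c], float) for c in covariates.columns]

    point = _fit_paths(gm, bold, choice, cov)
    gap = abs(point[4] - (point[2] + point[3]))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    if cov:
        boot = np.empty((n_boot, 5))
        for i in range(n_boot):
            j = idx[i]
            boot[i] = _fit_paths(gm[j], bold[j], choice[j], [c[j] for c in cov])
    else:
        boot = _boot_paths_closed_form(gm, bold, choice, idx)
    ok = np.isfinite(boot).all(axis=1)
    boot = boot[ok]

    if ci_method == "bca":
        keep = np.ones(n, bool)
        jack = np.empty((n, 5))
        for i in range(n):
            keep[i] = False
            jack[i] = _fit_paths(gm[keep], bold[keep], choice[keep],
                                 [c[keep] for c in cov])
            keep[i] = True

    paths = {}
    for j, name in enumerate(PATHS):
        dist = boot[:, j]
        if ci_method == "percentile":
            ci = (float(np.quantile(dist, alpha / 2)),
                  float(np.quantile(dist, 1 - alpha / 2)))
        else:
            ci = _bca_interval(dist, point[j], jack[:, j], alpha)
        p = 2.0 * min((dist <= 0).mean(), (dist >= 0).mean())
        paths[name] = PathEstimate(
            estimate=float(point[j]),
            se=float(dist.std(ddof=1)),
            ci=ci,
            p=float(min(1.0, max(p, 1.0 / len(dist)))),
        )

    indirect, direct = paths["indirect"], paths["b0"]
    full = (not (indirect.ci[0] <= 0 <= indirect.ci[1])) and \
           (direct.ci[0] <= 0 <= direct.ci[1])
    return MediationResult(
        paths=paths, n=n, n_boot=n_boot, seed=seed, ci_method=ci_method,
        alpha=alpha, full_mediation=bool(full), total_effect_gap=float(gap),
        boot_distributions={name: boot[:, j] for j, name in enumerate(PATHS)},
    )
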