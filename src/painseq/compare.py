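"""Model comparison by PSIS-LOO ELPD and between-condition HDI contrasts.

Expected log pointwise predictive density (ELPD) is estimated by
Pareto-smoothed importance-sampling leave-one-out cross-validation over
single trial responses (the observation unit of the per-trial likelihood).
Models are ranked by ELPD; each non-winning model is annotated with its
ELPD difference to the winner, the standard error of that difference
(computed from the paired pointwise contributions) and the *sigma effect*
``|difference| / SE`` — the significance heuristic, with >= 2 sigma read as
a robust difference.  ``LOOIC = -2 * ELPD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az

from .fit import PosteriorFit

__all__ = ["LooResult", "ComparisonResult", "HdiContrast",
           "elpd_loo", "compare_models", "hdi_contrast"]

SIGMA_SIGNIFICANT = 2.0
PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fit."""

    model_id: str
    elpd: float
    se: float
    p_loo: float
    pointwise: np.ndarray          # per-observation elpd contributions
    pareto_k: np.ndarray
    n_obs: int

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


@dataclass
class ComparisonResult:
    """Ranked model comparison: per-model ELPD/LOOIC plus differences to
    the best model with SEs and sigma effects."""

    table: pd.DataFrame
    loos: dict[str, LooResult] = field(repr=False, default_factory=dict)

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def sigma(self, model_id: str) -> float:
        return float(self.table.loc[model_id, "sigma"])

    def significant_over(self, worse: str, better: str | None = None) -> bool:
        """Whether ``better`` (default: the winner) outranks ``worse`` by at
        least the 2-sigma heuristic."""
        if better is None:
            better = self.best
        if better == worse:
            return False
        if self.table.loc[better, "elpd"] < self.table.loc[worse, "elpd"]:
            return False
        return self.sigma(worse) >= SIGMA_SIGNIFICANT if better == self.best else \
            _pairwise_sigma(self.loos[better], self.loos[worse]) >= SIGMA_SIGNIFICANT


@dataclass
class HdiContrast:
    """HDI of a between-condition difference of posterior draws."""

    parameter: str
    lower: float
    upper: float
    level: float = 0.95
    conditions: tuple[str, str] | None = None

    @property
    def significant(self) -> bool:
        """Zero-exclusion rule: the difference is credibly non-zero iff the
        interval does not contain 0."""
        return not (self.lower <= 0.0 <= self.upper)


def _pointwise_matrix(fit: PosteriorFit) -> np.ndarray:
    ll = fit.idata.log_likelihood["resp"]
    return np.asarray(ll).reshape(-1, ll.shape[-1])   # (draws, n_obs)


def elpd_loo(fit: PosteriorFit) -> LooResult:
    """PSIS-LOO for one fit, pointwise over answered trial responses."""
    if "log_likelihood" not in fit.idata.groups():
        raise ValueError("fit lacks a pointwise log-likelihood matrix")
    loo = az.loo(fit.idata, pointwise=True)
    return LooResult(
        model_id=fit.model_id,
        elpd=float(loo.elpd_loo),
        se=float(loo.se),
        p_loo=float(loo.p_loo),
        pointwise=np.asarray(loo.loo_i),
        pareto_k=np.asarray(loo.pareto_k),
        n_obs=int(loo.n_data_points),
    )


def _pairwise_sigma(a: LooResult, b: LooResult) -> float:
    diff = a.pointwise - b.pointwise
    se = float(np.sqrt(len(diff) * np.var(diff, ddof=1))) if len(diff) > 1 else 0.0
    total = float(np.sum(diff))
    return abs(total) / se if se > 0 else 0.0


def compare_models(fits: list[PosteriorFit]) -> ComparisonResult:
    """Rank fits of the same data by ELPD.

    All fits must cover identical observation units.  The returned table has
    one row per model (best first) with columns ``elpd, se, looic, elpd_diff,
    diff_se, sigma, n_bad_k``; the sigma effect of the best model is 0.
    """
    if not fits:
        raise ValueError("no fits supplied")
    n_obs = {int(f.idata.log_likelihood["resp"].shape[-1]) for f in fits}
    if len(n_obs) != 1:
        raise ValueError("fits cover different observation units")
    loos = {f.model_id: elpd_loo(f) for f in fits}
    if len(loos) != len(fits):
        raise ValueError("duplicate model ids among fits")

    order = sorted(loos, key=lambda m: loos[m].elpd, reverse=True)
    best = loos[order[0]]
    rows = []
    for m in order:
        lo = loos[m]
        diff_pw = best.pointwise - lo.pointwise
        diff = float(np.sum(diff_pw))
        diff_se = (float(np.sqrt(len(diff_pw) * np.var(diff_pw, ddof=1)))
                   if m != best.model_id and len(diff_pw) > 1 else 0.0)
        sigma = abs(diff) / diff_se if diff_se > 0 else 0.0
        rows.append({"model": m, "elpd": lo.elpd, "se": lo.se, "looic": lo.looic,
                     "elpd_diff": diff, "diff_se": diff_se, "sigma": sigma,
                     "n_bad_k": lo.n_bad_k})
    table = pd.DataFrame(rows).set_index("model")
    return ComparisonResult(table=table, loos=loos)


def hdi_contrast(draws_a, draws_b, level: float = 0.95,
                 parameter: str = "", conditions=None,
                 seed: int = 0) -> HdiContrast:
    """95% (by default) highest-density interval of the paired difference
    ``draws_a - draws_b`` of merged posterior draws.

    Unequal draw counts are reconciled by randomly subsampling the longer
    set (seeded).  The ``significant`` flag applies the zero-exclusion rule.
    """
    a = np.ravel(np.asarray(draws_a, dtype=float))
    b = np.ravel(np.asarray(draws_b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 draws per side")
    if a.size != b.size:
        rng = np.random.default_rng(seed)
        if a.size > b.size:
            a = rng.choice(a, size=b.size, replace=False)
        else:
            b = rng.choice(b, size=a.size, replace=False)
    lower, upper = az.hdi(a - b, hdi_prob=level)
    return HdiContrast(parameter=parameter, lower=float(lower),
                       upper=float(upper), level=level,
                       conditions=tuple(conditions) if conditions else None)
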