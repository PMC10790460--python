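"""Concentration indices, equity gaps, and the assembled equity suite.

Core quantities, for a binary coverage outcome ``y`` with weighted mean
``mu`` and a fractional rank ``F`` of the chosen ranking variable:

* Wagstaff concentration index  ``CI_W = (2 / mu) * Cov(y, F)`` —
  equivalently twice the area between the concentration curve and the
  45-degree line of perfect equality; positive = coverage concentrated
  among the higher-ranked (more privileged / richer).
* Erreygers correction          ``CI_E = 4 * mu * CI_W`` for bounded
  outcomes.
* Absolute Equity Gap           ``AEG = coverage(top 20% of F) -
  coverage(bottom 20% of F)``.
* Equity level                  ``1 - |CI_W|`` (reporting convenience).

All covariances and variances are weighted population moments.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import (_as_weights, fractional_rank, rank_quintile, round_half_up,
                     wcov, wmean, wvar)
from .ranking import (FairnessSpec, fit_direct_unfairness_model,
                      predict_unfairness_index)
from .wealth import wealth_scores


def wagstaff_ci(y, frank, weights=None) -> float:
    """Wagstaff concentration index: 2/mu times the weighted population
    covariance of the outcome with the fractional rank."""
    mu = wmean(y, weights)
    if mu <= 0:
        raise ValueError("concentration index undefined: mean coverage is zero")
    return 2.0 / mu * wcov(y, frank, weights)


def erreygers_ci(mu: float, ci_wagstaff: float) -> float:
    """Erreygers corrected index for bounded outcomes: 4 * mu * CI_W."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must lie in [0, 1], got {mu}")
    return 4.0 * mu * ci_wagstaff


def quintile_summary(y, frank, weights=None) -> pd.DataFrame:
    """Per rank-quintile observation count, weighted coverage, and
    weighted within-quintile standard deviation."""
    y = np.asarray(y, dtype=float)
    w = _as_weights(weights, len(y))
    q = rank_quintile(frank)
    rows = []
    for k in range(1, 6):
        m = q == k
        if m.any():
            rows.append({"quintile": k, "n": int(m.sum()),
                         "coverage": wmean(y[m], w[m]),
                         "s": float(np.sqrt(wvar(y[m], w[m])))})
        else:
            rows.append({"quintile": k, "n": 0, "coverage": np.nan, "s": np.nan})
    return pd.DataFrame(rows).set_index("quintile")


def absolute_equity_gap(y, frank, weights=None) -> tuple[float, pd.DataFrame]:
    """Coverage difference between the top and bottom 20% of the ranking.

    Quintile membership comes from the fractional rank's cumulative-weight
    cuts. Returns the gap and the full per-quintile summary.
    """
    summary = quintile_summary(y, frank, weights)
    if summary.loc[1, "n"] == 0 or summary.loc[5, "n"] == 0:
        raise ValueError("empty extreme rank quintile: AEG undefined")
    aeg = float(summary.loc[5, "coverage"] - summary.loc[1, "coverage"])
    return aeg, summary


def ci_confidence_bounds(ci: float, y, weights=None,
                         mode: str = "estimator") -> tuple[float, float]:
    """95% bounds for a concentration index.

    ``mode="as_printed"`` uses the half-width 1.96*sqrt(Var(y)) literally.
    ``mode="estimator"`` (default) divides the variance by the effective
    sample size (sum w)^2 / (sum w^2); the literal formula ignores sample
    size and yields implausibly wide intervals for survey-scale data.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations for confidence bounds")
    w = _as_weights(weights, len(y))
    var = wvar(y, w)
    if mode == "as_printed":
        half = 1.96 * np.sqrt(var)
    elif mode == "estimator":
        n_eff = w.sum() ** 2 / np.sum(w ** 2)
        half = 1.96 * np.sqrt(var / n_eff)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return (ci - half, ci + half)


def aeg_confidence_bounds(aeg: float, summary: pd.DataFrame) -> tuple[float, float]:
    """95% bounds for the AEG: aeg +/- 1.96*sqrt(s5^2/n5 + s1^2/n1)."""
    for k in (1, 5):
        if k not in summary.index or summary.loc[k, "n"] < 2:
            raise ValueError(f"rank quintile {k} missing or too small for AEG bounds")
    half = 1.96 * np.sqrt(summary.loc[5, "s"] ** 2 / summary.loc[5, "n"]
                          + summary.loc[1, "s"] ** 2 / summary.loc[1, "n"])
    return (aeg - half, aeg + half)


def equity_level(ci_wagstaff: float) -> float:
    """Equity level: 1 minus the absolute Wagstaff index (1 = perfectly
    equitable). Report tables round half-up to 2 decimals."""
    return 1.0 - abs(ci_wagstaff)


def concentration_curve(y, frank, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Concentration-curve points: cumulative population share vs
    cumulative outcome share, ordered by rank, from (0,0) to (1,1).

    Individuals sharing a fractional rank (a tie group) are aggregated
    into one point, so the trapezoid area reproduces the covariance-based
    index exactly.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(frank, dtype=float)
    w = _as_weights(weights, len(y))
    total_y = np.sum(w * y)
    if total_y <= 0:
        raise ValueError("concentration curve undefined: mean coverage is zero")
    order = np.argsort(f, kind="stable")
    uniq, inv = np.unique(f[order], return_inverse=True)
    gw = np.bincount(inv, weights=w[order])
    gy = np.bincount(inv, weights=(w * y)[order])
    pop_share = np.concatenate([[0.0], np.cumsum(gw) / np.sum(w)])
    out_share = np.concatenate([[0.0], np.cumsum(gy) / total_y])
    pop_share[-1] = 1.0
    out_share[-1] = 1.0
    return pop_share, out_share


def ci_from_curve(pop_share, out_share) -> float:
    """Concentration index from the curve: 1 - 2 * (area under curve),
    i.e. twice the signed area between the 45-degree line and the curve."""
    area = np.trapezoid(out_share, pop_share)
    return float(1.0 - 2.0 * area)


@dataclass
class EquityResult:
    """All equity metrics for one outcome under one ranking."""
    outcome: str
    ranking_kind: str              # "composite" | "wealth_only"
    n: int
    mu: float
    ci_wagstaff: float
    ci_erreygers: float
    aeg: float
    ci_bounds: tuple[float, float]
    aeg_bounds: tuple[float, float]
    equity_level: float
    quintile_summary: pd.DataFrame

    def as_row(self) -> dict:
        return {
            "outcome": self.outcome, "ranking": self.ranking_kind, "n": self.n,
            "coverage_pct": round_half_up(100 * self.mu, 1),
            "ci_wagstaff": round_half_up(self.ci_wagstaff, 3),
            "ci_low": round_half_up(self.ci_bounds[0], 3),
            "ci_high": round_half_up(self.ci_bounds[1], 3),
            "ci_erreygers": round_half_up(self.ci_erreygers, 3),
            "aeg": round_half_up(self.aeg, 3),
            "aeg_low": round_half_up(self.aeg_bounds[0], 3),
            "aeg_high": round_half_up(self.aeg_bounds[1], 3),
            "equity_level": round_half_up(self.equity_level, 2),
        }


def equity_for_outcome(y, frank, weights=None, outcome: str = "",
                       ranking_kind: str = "composite",
                       eq4_mode: str = "estimator") -> EquityResult:
    """Compute the full metric set for one outcome given its ranking."""
    y = np.asarray(y, dtype=float)
    mu = wmean(y, weights)
    ci_w = wagstaff_ci(y, frank, weights)
    aeg, summary = absolute_equity_gap(y, frank, weights)
    return EquityResult(
        outcome=outcome, ranking_kind=ranking_kind, n=len(y), mu=mu,
        ci_wagstaff=ci_w, ci_erreygers=erreygers_ci(mu, ci_w), aeg=aeg,
        ci_bounds=ci_confidence_bounds(ci_w, y, weights, mode=eq4_mode),
        aeg_bounds=aeg_confidence_bounds(aeg, summary),
        equity_level=equity_level(ci_w), quintile_summary=summary)


def _ses_score(pop: pd.DataFrame) -> pd.Series:
    if "ses_score" in pop.columns:
        return pop["ses_score"].astype(float)
    asset_cols = [c for c in pop.columns if c.startswith("asset_")]
    if not asset_cols:
        raise ValueError("wealth-only ranking needs a 'ses_score' column or asset_* columns")
    return wealth_scores(pop[asset_cols]).scores


def compute_equity_suite(pop: pd.DataFrame, outcomes: pd.DataFrame,
                         spec: FairnessSpec, outcome_names=None,
                         ranking_kind: str = "composite",
                         eq4_mode: str = "estimator",
                         ) -> dict[str, EquityResult]:
    """One EquityResult per outcome.

    ``ranking_kind="composite"`` fits the direct-unfairness model per
    outcome and ranks by its predictions; ``"wealth_only"`` ranks by the
    household SES score, the traditional wealth-based index. Children
    for whom an outcome is undefined (e.g. the 24-month cut for FULL /
    COMPLETE) are excluded from that outcome, and ranks are recomputed
    within the eligible subset.
    """
    if ranking_kind not in ("composite", "wealth_only"):
        raise ValueError(f"unknown ranking_kind {ranking_kind!r}")
    if outcome_names is None:
        outcome_names = [c for c in outcomes.columns if not c.startswith("underage_")]
    weights_all = (pop["weight"].to_numpy(dtype=float)
                   if "weight" in pop.columns else np.ones(len(pop)))
    score = _ses_score(pop) if ranking_kind == "wealth_only" else None

    results: dict[str, EquityResult] = {}
    for name in outcome_names:
        mask = outcomes[name].notna().to_numpy()
        y = outcomes[name].to_numpy(dtype=float)[mask]
        w = weights_all[mask]
        if ranking_kind == "composite":
            model = fit_direct_unfairness_model(pop, outcomes, spec, name)
            vci = predict_unfairness_index(model, pop.loc[mask], outcomes, spec)
            frank = fractional_rank(vci.to_numpy(), w)
        else:
            frank = fractional_rank(score.to_numpy()[mask], w)
        results[name] = equity_for_outcome(y, frank, w, outcome=name,
                                           ranking_kind=ranking_kind,
                                           eq4_mode=eq4_mode)
    return results
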