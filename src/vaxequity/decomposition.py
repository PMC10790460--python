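"""Regression decomposition of the concentration index.

Attributes the concentration index of a binary outcome to the fair and
unfair covariates of the ranking model, Wagstaff-van Doorslaer-Watanabe
style adapted to the logistic link: the contribution of design term k is

    contribution_k = (m_k * xbar_k / mu) * C_k = 2 * m_k * Cov(x_k, F) / mu

where ``m_k`` is the average marginal effect of the term (for a dummy,
the weighted mean change in predicted probability switching it 0 -> 1
holding the rest; for a continuous term, mean(p(1-p)) * beta_k),
``xbar_k`` its weighted mean, and ``C_k`` its concentration index
against the same fractional rank F used for the outcome's own index.
The residual is whatever the contributions do not explain:
``residual = CI - sum_k contribution_k``; signed shares (contribution /
CI * 100) plus the residual share add to exactly 100%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._stats import _as_weights, wcov, wmean
from .metrics import wagstaff_ci
from .ranking import FairnessSpec, RankingModel, _build_design

#: |CI| below which percentage shares are not reported
CI_SHARE_TOLERANCE = 1e-9


@dataclass
class DecompositionResult:
    outcome: str
    ci_wagstaff: float
    mu: float
    terms: pd.DataFrame          # per design term: group, mean, ame, contribution, share
    groups: pd.DataFrame         # per factor group: contribution, share
    residual: float
    residual_percent: float | None
    shares_defined: bool


def default_grouping(terms) -> dict[str, str]:
    """Map design terms to factor groups: dummies collapse to their
    covariate ("region[eastern]" -> "region"); the fair age and underage
    terms share one "age_underage" group."""
    grouping = {}
    for t in terms:
        if t == "const":
            continue
        if t in ("age_months", "underage"):
            grouping[t] = "age_underage"
        else:
            grouping[t] = t.split("[", 1)[0]
    return grouping


def aggregate_factor_groups(contributions: pd.Series,
                            grouping: dict[str, str]) -> pd.Series:
    """Sum per-term contributions (or shares) into factor groups; every
    term must be assigned to exactly one group."""
    unassigned = [t for t in contributions.index if t not in grouping]
    if unassigned:
        raise ValueError(f"terms not assigned to any factor group: {unassigned}")
    groups = pd.Series({t: grouping[t] for t in contributions.index})
    return contributions.groupby(groups).sum()


def decompose_ci(model: RankingModel, pop: pd.DataFrame, outcomes: pd.DataFrame,
                 spec: FairnessSpec, frank=None, weights=None,
                 grouping: dict[str, str] | None = None) -> DecompositionResult:
    """Decompose the composite concentration index of the model's outcome.

    ``frank`` defaults to the fractional rank of the model's own
    predictions on the eligible children, i.e. the same ranking the
    outcome's concentration index uses.
    """
    from .ranking import fractional_rank, predict_unfairness_index

    name = model.outcome
    mask = outcomes[name].notna().to_numpy()
    sub = pop.loc[mask]
    y = outcomes[name].to_numpy(dtype=float)[mask]
    w = _as_weights(weights, len(y)) if weights is not None else (
        sub["weight"].to_numpy(dtype=float) if "weight" in sub else np.ones(len(y)))
    if frank is None:
        vci = predict_unfairness_index(model, sub, outcomes, spec)
        frank = fractional_rank(vci.to_numpy(), w)
    frank = np.asarray(frank, dtype=float)

    X, _, _, _ = _build_design(sub, outcomes, spec, name,
                               fit_levels=model.levels, fit_fair=model.fair_terms)
    X = X[model.terms]
    beta = model.params.to_numpy()
    Xv = X.to_numpy()
    p = expit(Xv @ beta)

    mu = wmean(y, w)
    ci = wagstaff_ci(y, frank, w)

    rows = []
    for j, term in enumerate(model.terms):
        if term == "const":
            continue
        xk = Xv[:, j]
        is_binary = np.isin(np.unique(xk), (0.0, 1.0)).all()
        if is_binary:
            X1, X0 = Xv.copy(), Xv.copy()
            X1[:, j] = 1.0
            X0[:, j] = 0.0
            ame = wmean(expit(X1 @ beta) - expit(X0 @ beta), w)
        else:
            ame = wmean(p * (1.0 - p), w) * beta[j]
        xbar = wmean(xk, w)
        contribution = 2.0 * ame * wcov(xk, frank, w) / mu
        rank_ci = 2.0 * wcov(xk, frank, w) / xbar if xbar != 0 else np.nan
        rows.append({"term": term, "mean": xbar, "ame": ame,
                     "rank_ci": rank_ci, "contribution": contribution})
    terms = pd.DataFrame(rows).set_index("term")

    grouping = grouping or default_grouping(terms.index)
    terms["group"] = [grouping[t] for t in terms.index]
    residual = ci - terms["contribution"].sum()

    shares_defined = abs(ci) >= CI_SHARE_TOLERANCE
    if shares_defined:
        terms["share_percent"] = terms["contribution"] / ci * 100.0
        residual_percent = residual / ci * 100.0
    else:
        terms["share_percent"] = np.nan
        residual_percent = None

    group_contrib = aggregate_factor_groups(terms["contribution"], grouping)
    groups = pd.DataFrame({"contribution": group_contrib})
    groups["share_percent"] = (group_contrib / ci * 100.0 if shares_defined else np.nan)

    return DecompositionResult(outcome=name, ci_wagstaff=ci, mu=mu, terms=terms,
                               groups=groups, residual=residual,
                               residual_percent=residual_percent,
                               shares_defined=shares_defined)
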