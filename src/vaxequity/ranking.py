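"""Direct-unfairness ranking via logistic prediction.

Instead of ranking children by wealth alone, the composite equity
analysis ranks them by *direct unfairness*: the predicted coverage from
a logistic model containing the fair source of variation (the child's
age / not-yet-due status) and the unfair sources (region, urban/rural
residence, maternal education, socioeconomic quintile, sex, insurance).
The cumulative-distribution (fractional) rank of that prediction is the
ranking variable F entering the concentration index.

Each unfair covariate has a declared "more privileged" level, which is
used as the dummy-coding reference so fitted coefficients read as
log-odds penalties of the less privileged situations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from ._stats import fractional_rank, rank_quintile

DEFAULT_UNFAIR = ("region", "residence", "maternal_education",
                  "ses_quintile", "sex", "insured")
DEFAULT_PRIVILEGED = {
    "region": "central",
    "residence": "urban",
    "maternal_education": "secondary+",
    "ses_quintile": "5",
    "sex": "male",
    "insured": "yes",
}

#: |log-odds| beyond which a dummy is treated as perfectly separating
SEPARATION_THRESHOLD = 15.0


@dataclass
class FairnessSpec:
    """Which covariates count as fair vs unfair, and who is privileged."""
    fair: tuple[str, ...] = ("age_months", "underage")
    unfair: tuple[str, ...] = DEFAULT_UNFAIR
    privileged: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRIVILEGED))

    def __post_init__(self):
        self.fair = tuple(self.fair)
        self.unfair = tuple(self.unfair)
        overlap = set(self.fair) & set(self.unfair)
        if overlap:
            raise ValueError(f"covariates listed as both fair and unfair: {sorted(overlap)}")
        missing = [c for c in self.unfair if c not in self.privileged]
        if missing:
            raise ValueError(f"no privileged level declared for: {missing}")


@dataclass
class RankingModel:
    """Fitted direct-unfairness logistic model for one outcome."""
    outcome: str
    params: pd.Series                 # log-odds per design term (incl. const)
    bse: pd.Series                    # standard errors, for audit/recovery
    levels: dict[str, list[str]]      # non-reference levels per unfair covariate
    reference: dict[str, str]         # privileged (reference) level per covariate
    fair_terms: tuple[str, ...]       # fair design terms actually included
    underage_col: str | None
    converged: bool
    n: int

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)


def _underage_column(outcome_name: str, outcomes: pd.DataFrame) -> str | None:
    col = f"underage_{outcome_name}"
    return col if col in outcomes.columns else None


def _dummy_columns(values: pd.Series, cov: str, ref: str,
                   levels: list[str] | None) -> tuple[pd.DataFrame, list[str]]:
    vals = values.astype(str)
    if levels is None:
        levels = sorted(set(vals.unique()) - {ref})
    else:
        unseen = sorted(set(vals.unique()) - {ref} - set(levels))
        if unseen:
            raise ValueError(
                f"covariate {cov!r} has level(s) {unseen} not seen when the model was fitted")
    cols = {f"{cov}[{lvl}]": (vals == lvl).astype(float) for lvl in levels}
    return pd.DataFrame(cols, index=values.index), levels


def _build_design(pop: pd.DataFrame, outcomes: pd.DataFrame, spec: FairnessSpec,
                  outcome_name: str, fit_levels: dict[str, list[str]] | None = None,
                  fit_fair: tuple[str, ...] | None = None,
                  ) -> tuple[pd.DataFrame, dict[str, list[str]], tuple[str, ...], str | None]:
    blocks = [pd.Series(1.0, index=pop.index, name="const")]
    fair_terms: list[str] = []
    underage_col = None
    for cov in spec.fair:
        if cov == "underage":
            underage_col = _underage_column(outcome_name, outcomes)
            if underage_col is None:
                continue
            col = outcomes.loc[pop.index, underage_col].astype(float)
            col.name = "underage"
        else:
            if cov not in pop.columns:
                raise ValueError(f"fair covariate {cov!r} not in population table")
            col = pop[cov].astype(float)
        if fit_fair is None and col.nunique() < 2:
            continue  # constant in the fitting sample: no information
        if fit_fair is not None and col.name not in fit_fair:
            continue
        blocks.append(col)
        fair_terms.append(str(col.name))

    levels_used: dict[str, list[str]] = {}
    for cov in spec.unfair:
        if cov not in pop.columns:
            raise ValueError(f"unfair covariate {cov!r} not in population table")
        ref = str(spec.privileged[cov])
        dummies, lv = _dummy_columns(pop[cov], cov, ref,
                                     None if fit_levels is None else fit_levels[cov])
        levels_used[cov] = lv
        blocks.append(dummies)
    X = pd.concat(blocks, axis=1)
    return X, levels_used, tuple(fair_terms), underage_col


def fit_direct_unfairness_model(pop: pd.DataFrame, outcomes: pd.DataFrame,
                                spec: FairnessSpec, outcome_name: str,
                                use_weights: bool = True) -> RankingModel:
    """Maximum-likelihood logistic fit of one binary outcome on the fair
    and unfair covariates, survey weights entering as frequency weights.

    Rows where the outcome is undefined (NaN, e.g. over-24-month children
    for the fully-immunized-for-age outcome) are excluded.
    """
    if outcome_name not in outcomes.columns:
        raise ValueError(f"unknown outcome {outcome_name!r}")
    y = outcomes[outcome_name]
    mask = y.notna()
    y = y[mask].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"degenerate outcome {outcome_name!r}: only one class present")
    sub = pop.loc[mask.index[mask]]
    X, levels, fair_terms, underage_col = _build_design(sub, outcomes, spec, outcome_name)
    w = sub["weight"].to_numpy(dtype=float) if (use_weights and "weight" in sub) else None

    model = sm.GLM(y.to_numpy(), X.to_numpy(), family=sm.families.Binomial(),
                   freq_weights=w)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with _warnings.catch_warnings():
        # separation is re-diagnosed below with the offending term named
        _warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit()
    params = pd.Series(res.params, index=X.columns)
    # Only unfair dummies are checked for separation: the fair underage
    # indicator separates dose outcomes by construction (not-yet-due
    # children cannot have received the dose), which is benign — it just
    # ranks them at the bottom of predicted coverage.
    unfair_terms = [t for t in X.columns if t not in ("const", *fair_terms)]
    worst = params[unfair_terms].abs()
    if len(worst) and worst.max() > SEPARATION_THRESHOLD:
        raise ValueError(
            f"possible perfect separation: term {worst.idxmax()!r} has "
            f"|log-odds| {worst.max():.1f}")
    return RankingModel(outcome=outcome_name, params=params,
                        bse=pd.Series(res.bse, index=X.columns),
                        levels=levels, reference={c: str(spec.privileged[c]) for c in spec.unfair},
                        fair_terms=fair_terms, underage_col=underage_col,
                        converged=bool(getattr(res, "converged", True)), n=int(mask.sum()))


def predict_unfairness_index(model: RankingModel, pop: pd.DataFrame,
                             outcomes: pd.DataFrame, spec: FairnessSpec) -> pd.Series:
    """Per-child predicted coverage probability (vci_du) from a fitted model."""
    X, _, _, _ = _build_design(pop, outcomes, spec, model.outcome,
                               fit_levels=model.levels, fit_fair=model.fair_terms)
    X = X[model.terms]
    eta = X.to_numpy() @ model.params.to_numpy()
    return pd.Series(expit(eta), index=pop.index, name="vci_du")


def ranking_table(vci_du, weights=None) -> pd.DataFrame:
    """Assemble the ranking table: index value, fractional rank, quintile."""
    vci = pd.Series(vci_du)
    frank = fractional_rank(vci.to_numpy(), weights)
    return pd.DataFrame({"vci_du": vci.to_numpy(),
                         "frank": frank,
                         "rank_quintile": rank_quintile(frank)},
                        index=vci.index)


__all__ = ["FairnessSpec", "RankingModel", "fit_direct_unfairness_model",
           "predict_unfairness_index", "fractional_rank", "ranking_table",
           "DEFAULT_UNFAIR", "DEFAULT_PRIVILEGED"]
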