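"""Survey table ingestion, run configuration, and the end-to-end pipeline.

Native input is CSV plus a YAML run configuration. Survey exports (e.g.
a DHS child recode converted to CSV) are adapted through a
:class:`ColumnMapping` that renames source columns to the canonical
fields and recodes raw values (dose codes, residence codes, ...) with
an exhaustive recode map or a declared default. Every recode is tallied
and written to the run log.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from ._stats import round_half_up, wmean
from .decomposition import decompose_ci
from .metrics import compute_equity_suite, equity_for_outcome
from .ranking import (FairnessSpec, fit_direct_unfairness_model, fractional_rank,
                      predict_unfairness_index)
from .schedule import Schedule, ScheduleEntry, derive_outcomes, uganda_epi_schedule
from .simulate import DoseEffects, SimConfig, generate_population
from .wealth import wealth_scores, weighted_quintiles

_RAISE = object()


@dataclass
class ColumnSpec:
    """How one canonical field is read: source column, value recodes,
    and a default for raw codes absent from the recode map (omit the
    default to make unrecognized codes an error)."""
    source: str
    recode: Optional[Mapping[Any, Any]] = None
    default: Any = _RAISE


@dataclass
class ColumnMapping:
    columns: dict[str, ColumnSpec] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ColumnMapping":
        cols = {}
        for canonical, spec in d.items():
            if isinstance(spec, str):
                cols[canonical] = ColumnSpec(source=spec)
            else:
                cols[canonical] = ColumnSpec(
                    source=spec["source"], recode=spec.get("recode"),
                    default=spec.get("default", _RAISE) if "default" in spec else _RAISE)
        return cls(cols)


def read_population(path, mapping: ColumnMapping,
                    required: Optional[list[str]] = None,
                    ) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Read a survey CSV through a column mapping.

    Returns the typed, recoded population table and a tally of raw
    values per recoded column (for the run log).
    """
    raw = pd.read_csv(path)
    required = required or []
    missing = [c for c in required if c not in mapping.columns]
    if missing:
        raise ValueError(f"required canonical columns not mapped: {missing}")
    out = pd.DataFrame(index=raw.index)
    tallies: dict[str, dict] = {}
    for canonical, spec in mapping.columns.items():
        if spec.source not in raw.columns:
            raise ValueError(f"source column {spec.source!r} (for {canonical!r}) "
                             f"not found in {path}")
        col = raw[spec.source]
        if spec.recode is not None:
            tallies[canonical] = {str(k): int(v)
                                  for k, v in col.value_counts(dropna=False).items()}
            rec = dict(spec.recode)

            def _map(v):
                if v in rec:
                    return rec[v]
                if pd.isna(v):
                    return rec.get("missing", np.nan if spec.default is _RAISE else spec.default)
                if spec.default is _RAISE:
                    raise ValueError(f"unrecognized code {v!r} in column {canonical!r} "
                                     f"(source {spec.source!r}) with no default")
                return spec.default

            col = col.map(_map)
        out[canonical] = col
    if "age_months" in out:
        out["age_months"] = out["age_months"].astype(int)
    if "weight" in out:
        out["weight"] = out["weight"].astype(float)
    if "child_id" not in out:
        out.insert(0, "child_id", np.arange(len(out)))
    return out, tallies


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "vaxequity_out"
    outcome_names: Optional[list[str]] = None     # None = all derivable
    ranking_kinds: tuple[str, ...] = ("composite", "wealth_only")
    simulate: Optional[SimConfig] = None          # either simulate ...
    input_path: Optional[str] = None              # ... or read a CSV
    mapping: Optional[ColumnMapping] = None
    fairness: FairnessSpec = field(default_factory=FairnessSpec)
    schedule: Schedule = field(default_factory=uganda_epi_schedule)
    strict_zero: bool = False
    eq4_mode: str = "estimator"

    def __post_init__(self):
        if (self.simulate is None) == (self.input_path is None):
            raise ValueError("configure exactly one of 'simulate' or 'input_path'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        schedule = (_schedule_from_list(d["schedule"]) if "schedule" in d
                    else uganda_epi_schedule())
        sim = None
        if "simulate" in d:
            sim = sim_config_from_dict(d["simulate"], schedule=schedule,
                                       seed=d.get("seed", 0))
        fairness = FairnessSpec(**d.get("fairness", {})) if "fairness" in d else FairnessSpec()
        mapping = (ColumnMapping.from_dict(d["mapping"]) if "mapping" in d else None)
        ranking = d.get("ranking", "both")
        kinds = {"composite": ("composite",), "wealth": ("wealth_only",),
                 "wealth_only": ("wealth_only",),
                 "both": ("composite", "wealth_only")}[ranking]
        return cls(seed=int(d.get("seed", 0)), output_dir=d.get("output_dir", "vaxequity_out"),
                   outcome_names=d.get("outcomes"), ranking_kinds=kinds,
                   simulate=sim, input_path=d.get("input"), mapping=mapping,
                   fairness=fairness, schedule=schedule,
                   strict_zero=bool(d.get("strict_zero", False)),
                   eq4_mode="as_printed" if d.get("naive_eq4") else d.get("eq4_mode", "estimator"))


def _schedule_from_list(entries: list[Mapping[str, Any]]) -> Schedule:
    return Schedule(tuple(ScheduleEntry(e["antigen"], int(e["dose_number"]),
                                        int(e["due_age_days"]), e.get("name", ""))
                          for e in entries))


def sim_config_from_dict(d: Mapping[str, Any], schedule: Optional[Schedule] = None,
                         seed: int = 0) -> SimConfig:
    d = dict(d)
    if "effects" in d:
        d["effects"] = {dose: DoseEffects(intercept=float(e.get("intercept", 0.0)),
                                          coefficients=e.get("coefficients", {}))
                        for dose, e in d["effects"].items()}
    d.setdefault("seed", seed)
    if schedule is not None:
        d.setdefault("schedule", schedule)
    return SimConfig(**d)


# --------------------------------------------------------------------------
# pipeline


def _ensure_ses(pop: pd.DataFrame, log: dict) -> pd.DataFrame:
    """Fill in ses_score / ses_quintile from the asset battery when the
    input does not carry them (e.g. a DHS file with precomputed quintiles
    bypasses this)."""
    asset_cols = [c for c in pop.columns if c.startswith("asset_")]
    weights = pop["weight"].to_numpy(float) if "weight" in pop else None
    if "ses_score" not in pop.columns and asset_cols:
        res = wealth_scores(pop[asset_cols])
        pop = pop.assign(ses_score=res.scores)
        log["wealth_index"] = {"n_assets": len(asset_cols),
                               "dropped_constant": res.dropped,
                               "explained_share": round(res.explained_share, 4)}
    if "ses_quintile" not in pop.columns and "ses_score" in pop.columns:
        pop = pop.assign(ses_quintile=weighted_quintiles(pop["ses_score"], weights))
    return pop


def _stratum_coverage(pop: pd.DataFrame, outcomes: pd.DataFrame,
                      spec: FairnessSpec, outcome_names: list[str]) -> pd.DataFrame:
    w = pop["weight"].to_numpy(float) if "weight" in pop else np.ones(len(pop))
    rows = []
    for cov in spec.unfair:
        for level, idx in pop.groupby(cov, sort=True).groups.items():
            loc = pop.index.get_indexer(idx)
            for name in outcome_names:
                y = outcomes[name].to_numpy(float)[loc]
                ok = ~np.isnan(y)
                if ok.any():
                    rows.append({"covariate": cov, "level": level, "outcome": name,
                                 "n": int(ok.sum()),
                                 "coverage_pct": round_half_up(
                                     100 * wmean(y[ok], w[loc][ok]), 1)})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the report bundle.

    Writes to ``config.output_dir``: ``national_metrics.csv`` (one row
    per outcome x ranking kind), ``stratum_coverage.csv``,
    ``decomposition.csv`` (long format), and ``run_log.json``. Returns
    the in-memory tables. Deterministic given config + seed.
    """
    log: dict[str, Any] = {"seed": config.seed}

    if config.simulate is not None:
        pop = generate_population(config.simulate)
        log["input"] = {"kind": "simulated", "n_children": len(pop)}
    else:
        if config.mapping is None:
            raise ValueError("reading a CSV input requires a column mapping")
        pop, tallies = read_population(config.input_path, config.mapping)
        log["input"] = {"kind": "csv", "path": str(config.input_path),
                        "n_children": len(pop), "recode_tallies": tallies}
    pop = _ensure_ses(pop, log)

    outcomes = derive_outcomes(pop, config.schedule, strict_zero=config.strict_zero)
    log["missing_dose_values_recoded_to_0"] = outcomes.attrs["missing_dose_values"]

    names = config.outcome_names or (config.schedule.dose_names + ["zero", "full", "complete"])
    unknown = [n for n in names if n not in outcomes.columns]
    if unknown:
        raise ValueError(f"outcomes not derivable from the schedule: {unknown}")
    weights = pop["weight"].to_numpy(float) if "weight" in pop else np.ones(len(pop))

    metric_rows, decomp_rows = [], []
    for kind in config.ranking_kinds:
        if kind == "composite":
            for name in names:
                try:
                    model = fit_direct_unfairness_model(pop, outcomes, config.fairness, name)
                except ValueError as exc:
                    raise ValueError(f"[rank:{name}] {exc}") from exc
                mask = outcomes[name].notna().to_numpy()
                sub = pop.loc[mask]
                vci = predict_unfairness_index(model, sub, outcomes, config.fairness)
                frank = fractional_rank(vci.to_numpy(), weights[mask])
                res = equity_for_outcome(outcomes[name].to_numpy(float)[mask], frank,
                                         weights[mask], outcome=name,
                                         ranking_kind=kind, eq4_mode=config.eq4_mode)
                metric_rows.append(res.as_row())
                dec = decompose_ci(model, pop, outcomes, config.fairness,
                                   frank=frank, weights=weights[mask])
                for group, row in dec.groups.iterrows():
                    decomp_rows.append({"outcome": name, "factor": group,
                                        "contribution": row["contribution"],
                                        "share_percent": row["share_percent"]})
                decomp_rows.append({"outcome": name, "factor": "residual",
                                    "contribution": dec.residual,
                                    "share_percent": dec.residual_percent})
        else:
            suite = compute_equity_suite(pop, outcomes, config.fairness, names,
                                         ranking_kind=kind, eq4_mode=config.eq4_mode)
            metric_rows += [suite[name].as_row() for name in names]

    national = pd.DataFrame(metric_rows)
    stratum = _stratum_coverage(pop, outcomes, config.fairness, names)
    decomposition = pd.DataFrame(decomp_rows)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    national.to_csv(outdir / "national_metrics.csv", index=False)
    stratum.to_csv(outdir / "stratum_coverage.csv", index=False)
    decomposition.to_csv(outdir / "decomposition.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)

    return {"population": pop, "outcomes": outcomes, "national_metrics": national,
            "stratum_coverage": stratum, "decomposition": decomposition, "log": log}
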