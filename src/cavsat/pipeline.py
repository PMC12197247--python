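"""End-to-end orchestration: exclusions → outcomes → matching → weighting →
counterfactual effects → sensitivity → network, with deterministic seeding
and plain-text report emission (CSV/JSON only)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .cohort import COVARIATES, covariate_matrix, read_cohort, treatment_indicator, write_cohort
from .effects import DoubleResidualEstimator, TLearner, effects, weighted_aggregate
from .matching import MatchedDataset, balance_report, MATCHERS, PropensityModel
from .network import build_network, correlation_matrix
from .outcomes import OUTCOME_METRICS, attach_outcomes
from .sensitivity import DEFAULT_GAMMA_GRID, sensitivity_sweep
from .weighting import (
    DEFAULT_DIMENSION_WEIGHTS,
    MethodQuality,
    composite_weight,
    cv_r2,
    rosenbaum_robustness,
)

log = logging.getLogger("cavsat")


class SimulationSettings(BaseModel):
    n_total: int = 396
    treated_fraction: float = 48.0 / 396.0
    effect_ipr_pp: float = 6.4
    effect_los_days: float = 0.15
    effect_cost_multiplier: float = 1.02
    zero_improvement_rate: float = 0.02


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    input_path: str | None = None  # None -> simulate
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    covariates: list[str] = Field(default_factory=lambda: list(COVARIATES))
    caliper_sd: float = 0.2
    exact_vars: list[str] = Field(default_factory=lambda: ["gender"])
    genetic_generations: int = 10
    genetic_pop: int = 20
    folds: int = 5
    gamma: float = 1.5
    alpha: float = 0.05
    dimension_weights: tuple[float, float, float, float, float] = DEFAULT_DIMENSION_WEIGHTS
    forest_size: int = 500
    cv_forest_size: int = 200
    dr_forest_size: int = 200
    network_threshold: float = 0.3
    network_method: str = "spearman"
    network_scope: str = "cohort"  # 'cohort' or a matching method name
    gamma_grid: list[float] = Field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    seed: int = 0

    @field_validator("dimension_weights")
    @classmethod
    def _dims_sum_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("dimension weights must sum to 1")
        return v

    @field_validator("gamma")
    @classmethod
    def _gamma_ge_one(cls, v):
        if v < 1.0:
            raise ValueError("gamma must be >= 1")
        return v


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    cohort: pd.DataFrame
    exclusions: list
    matched: dict[str, MatchedDataset]
    balance: dict[str, object]
    quality: dict[str, MethodQuality]
    weights: dict[str, float]
    effects_table: pd.DataFrame
    ite_tables: dict[str, pd.DataFrame]
    sensitivity: pd.DataFrame
    network_edges: pd.DataFrame
    network: object
    provenance: dict = field(default_factory=dict)
    matching_skipped: bool = False


def _pair_diffs(df: pd.DataFrame, md: MatchedDataset) -> dict[str, np.ndarray]:
    out = {}
    for m in OUTCOME_METRICS:
        y = df[m].to_numpy(dtype=float)
        out[m] = y[md.treated_indices] - y[md.control_indices]
    return out


def _child_seed(ss: np.random.SeedSequence, *key) -> int:
    h = hashlib.sha256(repr((ss.entropy, key)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; fully reproducible from (config, seed)."""
    ss = np.random.SeedSequence(config.seed)

    # --- cohort
    if config.input_path is not None:
        log.info("reading cohort from %s", config.input_path)
        raw = read_cohort(config.input_path)
    else:
        from .simulate import CohortParams, OutcomeModel, generate_cohort

        sim = config.simulation
        params = CohortParams(
            n_total=sim.n_total,
            treated_fraction=sim.treated_fraction,
            outcome_model=OutcomeModel(
                effect_ipr_pp=sim.effect_ipr_pp,
                effect_los_days=sim.effect_los_days,
                effect_cost_multiplier=sim.effect_cost_multiplier,
                zero_improvement_rate=sim.zero_improvement_rate,
            ),
            seed=config.seed,
        )
        log.info("simulating cohort: n=%d", sim.n_total)
        raw = generate_cohort(params)

    # --- exclusions + outcomes
    df, exclusions = attach_outcomes(raw)
    df = df.reset_index(drop=True)
    log.info("exclusions: %d records dropped, %d analysed", len(exclusions), len(df))
    X = covariate_matrix(df, config.covariates)
    t = treatment_indicator(df)
    n_t, n_c = int(t.sum()), int((1 - t).sum())

    # --- matching (triggered only for arm imbalance beyond 2:1)
    ratio = max(n_t, n_c) / max(min(n_t, n_c), 1)
    matched: dict[str, MatchedDataset] = {}
    matching_skipped = ratio <= 2.0
    if matching_skipped:
        log.info("arm ratio %.2f <= 2:1; matching skipped, single-cohort analysis", ratio)
        matched["unmatched"] = MatchedDataset(method="unmatched", pairs=(), retained_n=min(n_t, n_c))
    else:
        ps = PropensityModel().fit(X, t)
        for name, fn in MATCHERS.items():
            if name == "genetic":
                md = fn(X, t, generations=config.genetic_generations,
                        pop_size=config.genetic_pop, seed=_child_seed(ss, "genetic"))
            elif name == "nearest_caliper":
                md = fn(X, t, caliper_sd=config.caliper_sd, propensity=ps)
            elif name == "optimal_exact":
                md = fn(X, t, exact=tuple(config.exact_vars), propensity=ps)
            else:
                md = fn(X, t)
            matched[name] = md
            log.info("matching %s: %d pairs", name, md.retained_n)

    # --- balance, quality, weights
    balance = {}
    quality = {}
    if not matching_skipped:
        for name, md in matched.items():
            bt = balance_report(X, t, list(md.pairs))
            balance[name] = bt
            idx = md.all_indices
            r2 = cv_r2(
                X.iloc[idx], t[idx], df.iloc[idx][list(OUTCOME_METRICS)],
                k=config.folds, seed=_child_seed(ss, "cv", name),
                n_estimators=config.cv_forest_size,
            )
            rob = rosenbaum_robustness(_pair_diffs(df, md), gamma=config.gamma, alpha=config.alpha)
            quality[name] = MethodQuality(
                mean_smd=bt.mean_smd,
                max_smd=bt.max_smd,
                cv_r2=r2,
                cv_r2_average=float(np.mean(list(r2.values()))),
                robustness=rob,
                retention=md.retained_n / n_t,
            )
        weights = composite_weight(quality, dimension_weights=config.dimension_weights)
    else:
        weights = {"unmatched": 1.0}
    log.info("ensemble weights: %s", {k: round(v, 4) for k, v in weights.items()})

    # --- counterfactual effects
    rows = []
    ite_tables: dict[str, pd.DataFrame] = {}
    analysis_sets = (
        {"unmatched": np.arange(len(df))}
        if matching_skipped
        else {name: md.all_indices for name, md in matched.items()}
    )
    importances: dict[str, pd.DataFrame] = {}
    for name, idx in analysis_sets.items():
        Xm, tm = X.iloc[idx].to_numpy(dtype=float), t[idx]
        ite_rows = {"id": df.iloc[idx]["id"].to_numpy(), "arm": df.iloc[idx]["arm"].to_numpy()}
        imp_rows = {}
        for m in OUTCOME_METRICS:
            ym = df.iloc[idx][m].to_numpy(dtype=float)
            seed_mo = _child_seed(ss, "tlearner", name, m)
            learner = TLearner(n_estimators=config.forest_size, random_state=seed_mo).fit(Xm, tm, ym)
            triple = effects(learner.ite_vector_)
            dr = DoubleResidualEstimator(
                k=config.folds, n_estimators=config.dr_forest_size,
                random_state=_child_seed(ss, "dr", name, m),
            ).fit(Xm, tm, ym).effect_
            rows.append({"outcome": m, "method": name, "ate": triple.ate,
                         "att": triple.att, "atc": triple.atc, "dr_effect": dr})
            ite_rows[f"ite_{m}"] = learner.ite_vector_.ite
            imp_rows[m] = learner.feature_importances_
        ite_tables[name] = pd.DataFrame(ite_rows)
        importances[name] = pd.DataFrame(imp_rows, index=list(X.columns)).T
        log.info("effects estimated for %s", name)

    eff = pd.DataFrame(rows)
    weighted_rows = []
    for m in OUTCOME_METRICS:
        sub = eff[eff["outcome"] == m].set_index("method")
        wrow = {"outcome": m, "method": "weighted_average"}
        for col in ("ate", "att", "atc", "dr_effect"):
            wrow[col] = weighted_aggregate(sub[col].to_dict(), weights)
        weighted_rows.append(wrow)
    effects_table = pd.concat([eff, pd.DataFrame(weighted_rows)], ignore_index=True)
    effects_table = effects_table.sort_values(["outcome", "method"]).reset_index(drop=True)

    # --- sensitivity sweep
    sens_rows = []
    if not matching_skipped:
        for name, md in matched.items():
            curves = sensitivity_sweep(_pair_diffs(df, md), method=name, gamma_grid=config.gamma_grid)
            for m, c in curves.items():
                for g, pl, pu, a in zip(c.gamma_grid, c.p_lower, c.p_upper, c.attenuated):
                    sens_rows.append({"outcome": m, "method": name, "gamma": g,
                                      "p_lower": pl, "p_upper": pu, "attenuated_effect": a})
    sensitivity_table = pd.DataFrame(
        sens_rows, columns=["outcome", "method", "gamma", "p_lower", "p_upper", "attenuated_effect"]
    )

    # --- correlation network
    if config.network_scope != "cohort" and config.network_scope in matched:
        net_df = df.iloc[matched[config.network_scope].all_indices]
    else:
        net_df = df
    net_vars = [c for c in config.covariates] + list(OUTCOME_METRICS)
    net_input = pd.concat(
        [covariate_matrix(net_df, config.covariates), net_df[list(OUTCOME_METRICS)]], axis=1
    )
    corr = correlation_matrix(net_input, net_vars, method=config.network_method)
    node_classes = {v: ("outcome" if v in OUTCOME_METRICS else "baseline") for v in net_vars}
    imp = next(iter(importances.values())) if importances else None
    net = build_network(corr, threshold=config.network_threshold,
                        node_classes=node_classes, importance=imp)

    config_hash = hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()
    from cavsat import __version__ as _version

    provenance = {"seed": config.seed, "config_hash": config_hash, "version": _version}

    return RunReport(
        cohort=df,
        exclusions=exclusions,
        matched=matched,
        balance=balance,
        quality=quality,
        weights=weights,
        effects_table=effects_table,
        ite_tables=ite_tables,
        sensitivity=sensitivity_table,
        network_edges=net.edges_dataframe(),
        network=net,
        provenance=provenance,
        matching_skipped=matching_skipped,
    )


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write every artifact as deterministic CSV/JSON files; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path: Path, text: str):
        path.write_text(text)
        written.append(path)

    write_cohort(report.cohort, out / "cohort_analysed.csv")
    written.append(out / "cohort_analysed.csv")
    _w(out / "exclusions.jsonl",
       "".join(json.dumps({"id": e.id, "reason": e.reason}) + "\n" for e in report.exclusions))
    for name, md in report.matched.items():
        ids = report.cohort["id"]
        pairs = pd.DataFrame(
            [
                {"method": name, "pair_index": k, "treated_id": ids.iloc[p[0]], "control_id": ids.iloc[p[1]]}
                for k, p in enumerate(md.pairs)
            ],
            columns=["method", "pair_index", "treated_id", "control_id"],
        )
        pairs.to_csv(out / f"pairs_{name}.csv", index=False)
        written.append(out / f"pairs_{name}.csv")
    for name, bt in report.balance.items():
        bt.table.rename_axis("covariate").to_csv(out / f"balance_{name}.csv", float_format="%.10g")
        written.append(out / f"balance_{name}.csv")
    _w(out / "quality.json", json.dumps(
        {
            name: {
                "mean_smd": q.mean_smd, "max_smd": q.max_smd, "cv_r2": q.cv_r2,
                "cv_r2_average": q.cv_r2_average, "robustness": q.robustness,
                "retention": q.retention,
            }
            for name, q in report.quality.items()
        }, indent=2, sort_keys=True))
    _w(out / "weights.json", json.dumps(report.weights, indent=2, sort_keys=True))
    report.effects_table.to_csv(out / "effects.csv", index=False, float_format="%.10g")
    written.append(out / "effects.csv")
    for name, table in report.ite_tables.items():
        table.to_csv(out / f"ite_{name}.csv", index=False, float_format="%.10g")
        written.append(out / f"ite_{name}.csv")
    report.sensitivity.to_csv(out / "sensitivity.csv", index=False, float_format="%.10g")
    written.append(out / "sensitivity.csv")
    report.network_edges.to_csv(out / "network_edges.csv", index=False, float_format="%.10g")
    written.append(out / "network_edges.csv")
    report.network.to_graphml(out / "network.graphml")
    written.append(out / "network.graphml")
    _w(out / "provenance.json", json.dumps(report.provenance, indent=2, sort_keys=True))
    return written
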