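"""End-to-end orchestration: raw cohort records to averaged networks, fitted
CPTs and cohort summaries, under one declarative, fully seeded configuration.

``run_pipeline`` is the single entry point the analysis scripts drive.  Every
stage logs record counts in and out, every random choice is derived from a
seed recorded in the manifest, and rerunning the same configuration
reproduces the same artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .averaging import (ArcStrengthTable, averaged_network, bootstrap_arcs,
                        compare_networks)
from .bayesnet import BayesianNetwork, fit_mle
from .discretize import CASE_COLUMNS, Thresholds, binarize, impute_gaf
from .graphs import CPDAG, DAG, write_arc_csv
from .sentiment import THEMES, aggregate_sentiment
from .synthetic import (ehr_ground_truth, render_ehr, sample_cases,
                        write_ground_truth)
from .trajectories import (AD_CLASSES, CO_MED_CLASSES, DoseTable,
                           assemble_trajectories, attach_patient_data,
                           derive_outcomes, filter_doses, switch_flow_table)
from .discretize import DX_FLAGS

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "results/run"
    cohort_dir: str | None = None        # read an existing cohort, or...
    synthetic: bool = True               # ...generate one from the ground truth
    n_cases: int = 4808
    cpt_seed: int = 11
    sample_seed: int = 12
    render_seed: int = 13
    impute_seed: int = 14
    bootstrap_seed: int = 15
    effect_floor: float = 0.25
    corruption_rate: float = 0.02
    gaf_missing_rate: float = 0.15
    dose_table_path: str | None = None
    alpha: float = 0.05
    strength_threshold: float = 0.85
    age_cut: float = 48.0
    gaf_cut: float = 50.0
    duration_cut: int = 35
    learners: tuple[str, ...] = ("pc_stable", "tabu")
    bootstrap_replicates: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.strength_threshold <= 1:
            raise ValueError("strength threshold must lie in [0, 1]")
        for name in ("corruption_rate", "gaf_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cohort_dir is None and not self.synthetic:
            raise ValueError("need either a cohort_dir or synthetic=True")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "learners" in raw:
            raw["learners"] = tuple(raw["learners"])
        return cls(**raw)

    def manifest(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["learners"] = list(self.learners)
        return d


def orient_for_fitting(cpdag: CPDAG,
                       strengths: ArcStrengthTable | None = None) -> DAG:
    """Resolve an averaged network's undirected edges into a DAG for fitting.

    Compelled arcs are kept; each undirected edge is oriented by its bootstrap
    direction majority when that keeps the graph acyclic, otherwise reversed
    (and the fallback logged).  The averaged model is fitted on the result.
    """
    dag = DAG(cpdag.nodes, cpdag.arcs)
    pending = sorted(cpdag.edges)
    if strengths is not None:
        pending.sort(key=lambda e: -(strengths.strength.get(e, 0.0)))
    for a, b in pending:
        if strengths is not None and strengths.direction.get((b, a), 0.5) > 0.5:
            a, b = b, a
        try:
            dag.add_arc(a, b)
        except Exception:
            log.info("orienting %s->%s would close a cycle; reversed", a, b)
            dag.add_arc(b, a)
    return dag


def summarize_cohort(trajectories) -> pd.DataFrame:
    """Cohort characteristics table: means/SDs for continuous variables and
    proportions for flags, one row per variable."""
    def num(values):
        s = pd.Series([float(v) for v in values], dtype=float)
        return {"mean_or_proportion": round(s.mean(), 4),
                "sd": round(s.std(ddof=1), 4) if len(s) > 1 else 0.0}

    def prop(flags):
        s = pd.Series([bool(v) for v in flags])
        return {"mean_or_proportion": round(s.mean(), 4), "sd": ""}

    rows: dict[str, dict] = {}
    rows["Age"] = num(t.age for t in trajectories)
    rows["Sex: female"] = prop(t.sex_female for t in trajectories)
    for c in AD_CLASSES:
        rows[f"Prescription group: {c}"] = prop(
            t.ad_class == c for t in trajectories)
    for c in CO_MED_CLASSES:
        rows[f"Co-medication: {c}"] = prop(
            t.co_medication.get(c, False) for t in trajectories)
    for d in DX_FLAGS:
        rows[f"DSM: {d.removeprefix('dx_')}"] = prop(
            t.dx.get(d, False) for t in trajectories)
    rows["GAF score at start"] = num(t.gaf for t in trajectories)
    rows["Trajectory duration (days)"] = num(
        t.duration_days for t in trajectories)
    rows["Continuation of antidepressant"] = prop(
        t.continued for t in trajectories)
    for th in THEMES:
        rows[f"Mean change sentiment: {th}"] = num(
            t.sentiment_means.get(th, 0.0) for t in trajectories)
    table = pd.DataFrame(rows).T
    table.index.name = "variable"
    return table


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run cohort -> trajectories -> case table -> learned averaged networks
    -> comparison -> fitted CPTs, writing all artifacts under
    ``config.out_dir`` and returning them in memory.

    With ``config.synthetic`` a ground-truth network generates the cohort and
    a truth-versus-learned comparison is included.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dose_table = (DoseTable.from_csv(config.dose_table_path)
                  if config.dose_table_path else DoseTable.default())

    truth = None
    truth_cases = None
    if config.cohort_dir is not None:
        from .synthetic import read_cohort
        cohort = _stage("read_cohort")(read_cohort)(config.cohort_dir)
    else:
        truth = _stage("ground_truth")(ehr_ground_truth)(
            cpt_seed=config.cpt_seed, effect_floor=config.effect_floor,
            n_cases=config.n_cases)
        truth_cases = _stage("sample_cases")(sample_cases)(
            truth, config.n_cases, config.sample_seed)
        cohort = _stage("render_ehr")(render_ehr)(
            truth_cases, config.render_seed, dose_table,
            corruption_rate=config.corruption_rate,
            gaf_missing_rate=config.gaf_missing_rate)
        write_ground_truth(truth, out)
        cohort.write(out / "cohort")

    n_raw = len(cohort.prescriptions)
    records = _stage("filter_doses")(filter_doses)(
        cohort.prescriptions, dose_table)
    log.info("dose filter: %d records in, %d out", n_raw, len(records))

    trajectories = _stage("assemble_trajectories")(assemble_trajectories)(
        records, dose_table)
    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for t in trajectories:
        _stage("derive_outcomes")(derive_outcomes)(
            t, by_patient[t.patient_id], dose_table)
    trajectories = _stage("attach_patient_data")(attach_patient_data)(
        trajectories, cohort.patients, cohort.gaf)
    for t in trajectories:
        aggregate_sentiment(cohort.sentiment_events, t)
    log.info("assembled %d first trajectories", len(trajectories))

    flows = _stage("switch_flow_table")(switch_flow_table)(
        trajectories, records, dose_table)
    flows.to_csv(out / "switch_flows.csv")

    trajectories = _stage("impute_gaf")(impute_gaf)(
        trajectories, seed=config.impute_seed)
    thresholds = Thresholds(config.age_cut, config.gaf_cut, config.duration_cut)
    case_table = _stage("binarize")(binarize)(trajectories, thresholds)
    case_table.to_csv(out / "case_table.csv", index=False)

    summary = summarize_cohort(trajectories)
    summary.to_csv(out / "cohort_summary.csv")

    traj_rows = pd.DataFrame([{
        "patient_id": t.patient_id, "ad_class": t.ad_class,
        "start": t.start, "end": t.end, "duration_days": t.duration_days,
        "continued": int(bool(t.continued)), "final_class": t.final_class,
        "sex_female": int(bool(t.sex_female)), "age": t.age, "gaf": t.gaf,
        "gaf_imputed": int(t.gaf_imputed),
        **{c: int(t.co_medication.get(c, False)) for c in CO_MED_CLASSES},
        **{d: int(t.dx.get(d, False)) for d in DX_FLAGS},
        **{f"sent_{th}": t.sentiment_means.get(th, 0.0) for th in THEMES},
    } for t in trajectories])
    traj_rows.to_csv(out / "trajectories.csv", index=False)

    networks: dict[str, CPDAG] = {}
    strengths: dict[str, ArcStrengthTable] = {}
    fitted: dict[str, BayesianNetwork] = {}
    for i, learner in enumerate(config.learners):
        st = _stage(f"bootstrap[{learner}]")(bootstrap_arcs)(
            case_table, learner, R=config.bootstrap_replicates,
            seed=config.bootstrap_seed + i)
        st.write_csv(out / f"arc_strengths_{learner}.csv")
        net = averaged_network(st, config.strength_threshold)
        (out / f"averaged_network_{learner}.dot").write_text(
            net.to_dot(learner))
        write_arc_csv(net, out / f"averaged_network_{learner}.csv")
        dag = orient_for_fitting(net, st)
        bn = _stage(f"fit[{learner}]")(fit_mle)(dag, case_table)
        (out / f"cpts_{learner}.json").write_text(bn.to_json())
        networks[learner], strengths[learner], fitted[learner] = net, st, bn

    comparison: dict[str, Any] = {}
    if len(config.learners) == 2:
        a, b = config.learners
        comparison[f"{a}_vs_{b}"] = compare_networks(networks[a], networks[b])
    if truth is not None:
        truth_dag_expanded = _expanded_truth_cpdag(truth)
        for learner, net in networks.items():
            comparison[f"{learner}_vs_truth"] = compare_networks(
                net, truth_dag_expanded)
    (out / "network_comparison.json").write_text(
        json.dumps(comparison, indent=2, sort_keys=True))

    manifest = {
        "config": config.manifest(),
        "n_prescriptions_raw": n_raw,
        "n_prescriptions_filtered": len(records),
        "n_trajectories": len(trajectories),
        "case_columns": list(CASE_COLUMNS),
        "arc_counts": {k: len(v.arcs) + len(v.edges) for k, v in networks.items()},
        "strengths_in_01": {
            k: sorted({round(s, 6) for s in v.strength.values()})[:8]
            for k, v in strengths.items()},
        "comparison": comparison,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "trajectories": trajectories, "case_table": case_table,
        "summary": summary, "flows": flows, "networks": networks,
        "strengths": strengths, "fitted": fitted, "comparison": comparison,
        "manifest": manifest, "truth": truth, "truth_cases": truth_cases,
    }


def _expanded_truth_cpdag(truth: BayesianNetwork) -> CPDAG:
    """Project the ground truth onto the analysis columns: the categorical
    class node is replaced by its six indicators, arcs fanning out/in to all
    of them, and the indicators form an undirected clique (they are logically
    dependent through mutual exclusivity)."""
    from .discretize import CASE_COLUMNS
    from .synthetic import CLASS_NODE

    indicators = [f"ad_{c}" for c in AD_CLASSES]
    arcs: set[tuple[str, str]] = set()
    for a, b in truth.dag.arcs:
        if a == CLASS_NODE:
            arcs.update((ind, b) for ind in indicators)
        elif b == CLASS_NODE:
            arcs.update((a, ind) for ind in indicators)
        else:
            arcs.add((a, b))
    clique = {tuple(sorted((x, y)))
              for i, x in enumerate(indicators) for y in indicators[i + 1:]}
    return CPDAG(tuple(CASE_COLUMNS), frozenset(arcs), frozenset(clique))
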