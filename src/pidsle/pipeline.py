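"""End-to-end orchestration of the synthetic reproduction.

Runs simulate -> overlap -> cluster -> de -> score -> stratify -> classify
in dependency order from a single nested configuration, writing each
stage's outputs as plain-text files plus a JSON manifest with parameter
hashes, seeds and output checksums.  Any stage failure aborts with a
stage-tagged error; a disabled stage is marked skipped and downstream
stages that need it abort cleanly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de as de_mod
from . import ml as ml_mod
from .overlap import monte_carlo_overlap, overlap as overlap_sets
from . import ppi as ppi_mod
from . import scoring as scoring_mod
from . import synthetic as syn_mod
from .cohort import ExpressionCohort
from .gene_db import GeneSet, read_gmt, write_gene_table, write_gmt, write_symbol_list

log = logging.getLogger("pidsle.pipeline")

STAGES = ["simulate", "overlap", "cluster", "de", "score", "stratify", "classify"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "pipeline_out",
    "stages": {s: True for s in STAGES},
    "simulate": {
        "n_genes": 1200,
        "n_pid": 120,
        "n_categories": 10,
        "n_patients": 120,
        "n_controls": 40,
        "module_sizes": [15, 15, 15],
        "effect_size_per_module": [1.0, 0.5, 0.0],
        "noise_sd": 1.0,
        "activity_mixture": 0.5,
        "risk_set_size": 200,
        "pid_enrichment_odds": 3.0,
        "p_within": 0.9,
        "p_between": 0.01,
    },
    "overlap": {"n_iterations": 10000},
    "cluster": {
        "degree_cutoff": 2,
        "node_score_cutoff": 0.2,
        "k_core": 2,
        "max_depth": 100,
        "haircut": True,
        "fluff": False,
    },
    "de": {
        "p_threshold": 0.05,
        "p_adj_threshold": 0.2,
        "overlap_iterations": 10000,
    },
    "score": {
        "kernel_bandwidth_factor": 0.25,
        "tau": 1.0,
        "statistic": "diff_of_extremes",
    },
    "stratify": {"k": 3, "standardize_rows": False},
    "classify": {
        "n_folds": 10,
        "split": 0.7,
        "families": ["LR", "SVM", "RF"],
        "contrast": "cohort",  # or "activity_class"
    },
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    data: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "PipelineConfig":
        return cls(_merge(DEFAULT_CONFIG, overrides or {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.data[key]

    def param_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order; return (and write) the manifest."""
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "seed": seed,
        "param_hash": config.param_hash(),
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def record(stage: str, status: str, seconds: float | None = None, **extra) -> None:
        manifest["stages"][stage] = {"status": status, **extra}
        if seconds is not None:
            manifest["stages"][stage]["seconds"] = round(seconds, 3)
        log.info("[%s] %s", stage, status)

    for stage in STAGES:
        if not config["stages"].get(stage, True):
            record(stage, "skipped")
            continue
        t0 = time.monotonic()
        try:
            _STAGE_FUNCS[stage](config, seed, outdir, state)
        except PipelineError:
            raise
        except Exception as exc:  # tag errors with the failing stage
            raise PipelineError(stage, str(exc)) from exc
        record(stage, "completed", seconds=time.monotonic() - t0)

    for path in sorted(outdir.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _checksum(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    p = config["simulate"]
    sim = syn_mod.SimulationConfig(
        n_genes=p["n_genes"], n_pid=p["n_pid"], n_categories=p["n_categories"],
        n_patients=p["n_patients"], n_controls=p["n_controls"],
        module_sizes=list(p["module_sizes"]),
        effect_size_per_module=list(p["effect_size_per_module"]),
        noise_sd=p["noise_sd"], activity_mixture=p["activity_mixture"],
        pid_enrichment_odds=p["pid_enrichment_odds"],
        p_within=p["p_within"], p_between=p["p_between"], seed=seed,
    )
    universe = syn_mod.generate_gene_universe(sim)
    risk = syn_mod.generate_risk_set(
        universe, p["risk_set_size"], p["pid_enrichment_odds"], seed=seed
    )
    pid_symbols = sorted(universe.pid_genes().symbols)
    modules: list[GeneSet] = []
    assignment: dict[str, object] = {g: None for g in pid_symbols}
    cursor = 0
    for mi, size in enumerate(sim.module_sizes):
        members = pid_symbols[cursor : cursor + size]
        cursor += size
        modules.append(GeneSet.from_symbols(f"module_{mi + 1}", members))
        for g in members:
            assignment[g] = f"module_{mi + 1}"
    graph = syn_mod.generate_ppi_graph(
        universe, assignment, sim.p_within, sim.p_between, seed=seed
    )
    cohort = syn_mod.generate_expression_cohort(sim, modules)
    write_gene_table(universe, outdir / "universe.tsv")
    write_symbol_list(risk, outdir / "risk_set.txt")
    write_gmt(modules, outdir / "planted_modules.gmt")
    ppi_mod.write_edge_list(graph, outdir / "ppi_edges.tsv")
    cohort.write(outdir / "expression.tsv", outdir / "samples.tsv")
    state.update(
        sim=sim, universe=universe, risk=risk, modules=modules,
        graph=graph, cohort=cohort,
    )


def _stage_overlap(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    universe = need("overlap", "universe", state)
    risk = state["risk"]
    markers = universe.pid_genes()
    uni_set = universe.as_gene_set()
    counted = overlap_sets(markers, risk, uni_set)
    result = monte_carlo_overlap(
        uni_set, markers, draw_size=counted.size_b, observed=counted.k,
        n_iterations=int(config["overlap"]["n_iterations"]), seed=seed,
        overlap_members=counted.members,
    )
    pd.DataFrame([{
        "universe_size": result.universe_size,
        "marker_count": result.marker_count,
        "draw_size": result.draw_size,
        "observed": result.observed,
        "null_mean": result.null_mean,
        "null_sd": result.null_sd,
        "z": result.z,
        "empirical_p": result.empirical_p,
        "analytic_mean": result.analytic_mean,
        "analytic_sd": result.analytic_sd,
        "analytic_z": result.analytic_z,
        "analytic_tail_p": result.analytic_tail_p,
    }]).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    state["overlap_result"] = result


def _stage_cluster(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    graph = need("cluster", "graph", state)
    universe = state["universe"]
    p = config["cluster"]
    params = ppi_mod.MCODEParams(
        degree_cutoff=p["degree_cutoff"], node_score_cutoff=p["node_score_cutoff"],
        k_core=p["k_core"], max_depth=p["max_depth"],
        haircut=p["haircut"], fluff=p["fluff"],
    )
    clusters = ppi_mod.find_complexes(graph, params)
    rows = [
        {"cluster": c.id, "size": len(c), "score": c.score,
         "flagged_singleton": c.flagged, "members": ",".join(sorted(c.members))}
        for c in clusters
    ]
    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    graph_nodes = GeneSet.from_symbols("graph", graph.nodes)
    cells = []
    for c in clusters:
        if c.flagged:
            continue
        cells.extend(
            ppi_mod.fisher_enrichment(c, universe, graph_nodes, scheme="functional")
        )
    ppi_mod.enrichment_table(cells).to_csv(
        outdir / "cluster_enrichment.tsv", sep="\t", index=False
    )
    cluster_sets = [c.as_gene_set() for c in clusters if not c.flagged]
    write_gmt(cluster_sets, outdir / "mcode_clusters.gmt")
    state["clusters"] = clusters
    state["cluster_sets"] = cluster_sets


def _stage_de(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    cohort: ExpressionCohort = need("de", "cohort", state)
    universe = state["universe"]
    p = config["de"]
    result = de_mod.moderated_t(
        cohort, ("SLE", "control"), column="cohort",
        p_threshold=p["p_threshold"], p_adj_threshold=p["p_adj_threshold"],
    )
    result.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    markers = universe.pid_genes()
    array_universe = GeneSet.from_symbols("array", cohort.genes)
    overlap_result = de_mod.de_overlap_test(
        result, markers, array_universe,
        n_iterations=int(p["overlap_iterations"]), seed=seed,
    )
    pd.DataFrame([{
        "draw_size": overlap_result.draw_size,
        "observed": overlap_result.observed,
        "z": overlap_result.z,
        "empirical_p": overlap_result.empirical_p,
        "analytic_tail_p": overlap_result.analytic_tail_p,
    }]).to_csv(outdir / "de_overlap.tsv", sep="\t", index=False)
    state["de_result"] = result


def _stage_score(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    cohort: ExpressionCohort = need("score", "cohort", state)
    modules = need("score", "cluster_sets", state)
    if not modules:
        raise PipelineError("score", "no non-singleton clusters to score")
    p = config["score"]
    params = scoring_mod.ScoringParams(
        kernel_bandwidth_factor=p["kernel_bandwidth_factor"],
        tau=p["tau"], statistic=p["statistic"],
    )
    scores = scoring_mod.gsva_scores(cohort, modules, params)
    scores.write(outdir / "module_scores.tsv")
    sle = cohort.group_samples("SLE", "cohort")
    controls = cohort.group_samples("control", "cohort")
    effects = scoring_mod.effect_sizes(scores, (sle, controls))
    effects.to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
    state["scores"] = scores
    state["effects"] = effects


def _stage_stratify(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    scores: scoring_mod.ModuleScoreMatrix = need("stratify", "scores", state)
    cohort: ExpressionCohort = state["cohort"]
    p = config["stratify"]
    sle = cohort.group_samples("SLE", "cohort")
    sub = scoring_mod.ModuleScoreMatrix(scores.scores[sle], scores.provenance)
    strat = scoring_mod.hierarchical_stratify(
        sub, k=int(p["k"]), standardize_rows=p["standardize_rows"]
    )
    strat.labels.rename("cluster").to_csv(outdir / "strata.tsv", sep="\t")
    tables = scoring_mod.clinical_anova(strat.labels, cohort.clinical)
    tables["anova"].to_csv(outdir / "strata_anova.tsv", sep="\t", index=False)
    tables["cluster_stats"].to_csv(outdir / "strata_stats.tsv", sep="\t", index=False)
    tables["tukey"].to_csv(outdir / "strata_tukey.tsv", sep="\t", index=False)
    state["stratification"] = strat


def _stage_classify(config: PipelineConfig, seed: int, outdir: Path, state: dict) -> None:
    scores: scoring_mod.ModuleScoreMatrix = need("classify", "scores", state)
    cohort: ExpressionCohort = state["cohort"]
    p = config["classify"]
    labels = cohort.clinical[p["contrast"]]
    features = ml_mod.build_features([scores], labels)
    plan = ml_mod.make_folds(
        features.y, n_folds=int(p["n_folds"]), seed=seed, split=p["split"]
    )
    report = ml_mod.evaluate(features, plan, families=list(p["families"]))
    report.per_fold.to_csv(outdir / "classifier_folds.tsv", sep="\t", index=False)
    agg = report.aggregate.copy()
    agg.columns = ["_".join(c) for c in agg.columns]
    agg.to_csv(outdir / "classifier_aggregate.tsv", sep="\t")
    auc_rows = [
        {"family": name, "auroc": c["auroc"], "aupr": c["aupr"]}
        for name, c in report.curves.items()
    ]
    pd.DataFrame(auc_rows).to_csv(outdir / "classifier_auc.tsv", sep="\t", index=False)
    state["report"] = report


def need(stage: str, key: str, state: dict):
    if key not in state:
        raise PipelineError(stage, f"missing upstream output {key!r}")
    return state[key]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "overlap": _stage_overlap,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "score": _stage_score,
    "stratify": _stage_stratify,
    "classify": _stage_classify,
}
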