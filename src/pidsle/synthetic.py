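"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates every input the analysis consumes, so the whole
chain is testable without downloads:

* a gene universe with PID membership, functional categories and optional
  cell-type tags (the curated-database surrogate);
* risk-gene sets drawn by weighted sampling with a tunable PID enrichment
  odds parameter (at odds = 1 the overlap is exactly hypergeometric);
* planted-partition PPI graphs (edge probability ``p_within`` inside a
  module, ``p_between`` otherwise) for cluster-recovery tests;
* patient x gene log2 matrices in which module-level over-expression
  scales with a latent disease-activity variable a in [0, 1] that also
  drives the clinical traits: SLEDAI up, anti-dsDNA up, C3 and C4 down.

Latent activity: controls a = 0; inactive patients a ~ U(0, 0.4); active
patients a ~ U(0.5, 1), so SLEDAI-threshold classes are realizable and
separable at large effect size.  Each generator draws from its own stream,
seeded from ``config.seed`` by a fixed offset, so adding a generator call
never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, activity_class
from .gene_db import GeneSet, GeneTable

__all__ = ["SimulationConfig", "generate_gene_universe", "generate_risk_set",
           "generate_ppi_graph", "generate_expression_cohort"]

# fixed per-generator stream offsets (design: one stream per generator)
_STREAM_UNIVERSE = 11
_STREAM_RISK_SET = 23
_STREAM_PPI = 37
_STREAM_COHORT = 53

CELL_TYPE_TAGS = [
    "Monocyte", "Myeloid", "B cell", "T cell", "NK cell",
    "Plasma cell", "Dendritic cell", "Neutrophil",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs for all synthetic generators.

    Defaults are a demonstration scale that preserves the qualitative
    structure of the emulated cohorts (hundreds of samples, planted
    modules of a few dozen genes, unit log2 effects at full activity).
    """

    n_genes: int = 2000
    n_pid: int = 150
    n_categories: int = 10
    n_patients: int = 200
    n_controls: int = 50
    module_sizes: list[int] = field(default_factory=lambda: [20, 20, 20])
    effect_size_per_module: list[float] = field(default_factory=lambda: [1.0, 0.5, 0.0])
    noise_sd: float = 1.0
    activity_mixture: float = 0.5
    pid_enrichment_odds: float = 1.0
    p_within: float = 0.9
    p_between: float = 0.01
    seed: int = 0
    # clinical link functions: trait = intercept + slope * a + N(0, sd)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    sledai_scale: float = 12.0
    sledai_noise_sd: float = 0.8
    anti_dsdna_intercept: float = 20.0
    anti_dsdna_slope: float = 180.0
    anti_dsdna_noise_sd: float = 15.0
    c3_intercept: float = 1.1
    c3_slope: float = -0.5
    c3_noise_sd: float = 0.08
    c4_intercept: float = 0.28
    c4_slope: float = -0.12
    c4_noise_sd: float = 0.03
    cell_type_tag_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_pid < 0 or self.n_categories <= 0:
            raise ValueError("counts must be positive")
        if self.n_pid > self.n_genes:
            raise ValueError(f"n_pid {self.n_pid} > n_genes {self.n_genes}")
        if sum(self.module_sizes) > self.n_pid:
            raise ValueError("sum(module_sizes) exceeds n_pid")
        if not 0.0 <= self.activity_mixture <= 1.0:
            raise ValueError("activity_mixture must lie in [0, 1]")
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pid_enrichment_odds <= 0:
            raise ValueError("pid_enrichment_odds must be positive")
        if len(self.effect_size_per_module) < len(self.module_sizes):
            raise ValueError("one effect size per module required")

    def to_dict(self) -> dict:
        return asdict(self)


def _stream(config_seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, config_seed])


def generate_gene_universe(config: SimulationConfig) -> GeneTable:
    """Synthetic gene universe with PID flags, categories and cell-type tags.

    PID genes are a uniformly drawn subset of the symbols; their category
    distribution is mildly skewed toward the first (immune-like)
    categories, so category-profile comparisons show the expected contrast
    between a disease set and its background.
    """
    rng = _stream(config.seed, _STREAM_UNIVERSE)
    width = max(5, len(str(config.n_genes)))
    symbols = np.array([f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)])
    pid_idx = rng.choice(config.n_genes, size=config.n_pid, replace=False)
    is_pid = np.zeros(config.n_genes, dtype=bool)
    is_pid[pid_idx] = True
    categories = np.array([f"C{i + 1:02d}" for i in range(config.n_categories)])
    cat_assign = rng.integers(0, config.n_categories, size=config.n_genes)
    n_immune = max(1, config.n_categories // 3)
    skew = rng.random(config.n_genes) < 0.5
    cat_assign[is_pid & skew] = rng.integers(0, n_immune, size=int((is_pid & skew).sum()))
    tagged = rng.random(config.n_genes) < config.cell_type_tag_fraction
    tag_choice = rng.integers(0, len(CELL_TYPE_TAGS), size=config.n_genes)
    cell_tags = np.where(
        tagged, np.array(CELL_TYPE_TAGS, dtype=object)[tag_choice], None
    )
    chrom = rng.integers(1, 23, size=config.n_genes)
    start = rng.integers(1, 2_000_000, size=config.n_genes)
    length = rng.integers(1_000, 100_000, size=config.n_genes)
    df = pd.DataFrame(
        {
            "symbol": symbols,
            "functional_category": categories[cat_assign],
            "cell_type_tag": cell_tags,
            "chromosome": [f"chr{c}" for c in chrom],
            "start": start,
            "end": start + length,
            "is_pid": is_pid,
        }
    )
    return GeneTable(df, universe_name=f"synthetic_universe_seed{config.seed}")


def generate_risk_set(
    universe: GeneTable,
    set_size: int,
    pid_enrichment_odds: float = 1.0,
    seed: int = 0,
    name: str = "risk_set",
) -> GeneSet:
    """Weighted sample without replacement: PID genes weighted by the odds.

    Uses exponential-key successive sampling (key = Exp(1)/weight, keep the
    ``set_size`` smallest), which reduces to a uniform draw at odds = 1 so
    the PID overlap is exactly hypergeometric under the null.
    """
    if set_size > len(universe):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(universe)}")
    if pid_enrichment_odds <= 0:
        raise ValueError("pid_enrichment_odds must be positive")
    rng = _stream(seed, _STREAM_RISK_SET)
    symbols = np.array(universe.symbols)
    weights = np.where(universe.records["is_pid"].to_numpy(), pid_enrichment_odds, 1.0)
    keys = rng.exponential(1.0, size=len(symbols)) / weights
    chosen = symbols[np.argsort(keys, kind="stable")[:set_size]]
    return GeneSet.from_symbols(name, chosen)


def generate_ppi_graph(
    universe: GeneTable,
    module_assignment: dict[str, object],
    p_within: float,
    p_between: float,
    seed: int = 0,
) -> nx.Graph:
    """Planted-partition interaction graph over the assigned genes.

    Genes mapped to the same (non-None) module are connected with
    probability ``p_within``; every other pair with ``p_between``.  Only
    genes present in ``module_assignment`` become nodes, mirroring a
    network built over a curated gene list.
    """
    if not 0.0 <= p_between <= 1.0 or not 0.0 <= p_within <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    known = set(universe.symbols)
    unknown = [g for g in module_assignment if g not in known]
    if unknown:
        raise ValueError(f"genes outside universe: {sorted(unknown)[:5]}")
    rng = _stream(seed, _STREAM_PPI)
    nodes = sorted(module_assignment)
    labels = [module_assignment[n] for n in nodes]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        u = rng.random(n - i - 1)
        for off, j in enumerate(range(i + 1, n)):
            same = labels[i] is not None and labels[i] == labels[j]
            p = p_within if same else p_between
            if u[off] < p:
                g.add_edge(nodes[i], nodes[j])
    return g


def generate_expression_cohort(
    config: SimulationConfig,
    modules: list[GeneSet],
    name: str | None = None,
) -> ExpressionCohort:
    """Patient x gene log2 matrix driven by latent disease activity.

    expression(g, s) = baseline_g + a_s * effect(module(g)) + N(0, noise_sd)

    with a = 0 for controls, a ~ U(0, 0.4) for inactive and a ~ U(0.5, 1)
    for active patients.  SLEDAI = round(sledai_scale * a + noise) clipped
    at 0 (controls exactly 0); anti-dsDNA rises and C3/C4 fall linearly in
    a with additive Gaussian noise, clipped positive.
    """
    universe_symbols: set[str] | None = None
    effect_of_gene: dict[str, float] = {}
    for module, effect in zip(modules, config.effect_size_per_module):
        for sym in module.symbols:
            effect_of_gene[sym] = effect
    rng = _stream(config.seed, _STREAM_COHORT)

    n_active = int(round(config.activity_mixture * config.n_patients))
    n_inactive = config.n_patients - n_active
    a = np.concatenate(
        [
            np.zeros(config.n_controls),
            rng.uniform(0.0, 0.4, size=n_inactive),
            rng.uniform(0.5, 1.0, size=n_active),
        ]
    )
    cohort_label = np.array(
        ["control"] * config.n_controls + ["SLE"] * config.n_patients
    )
    n_samples = config.n_controls + config.n_patients
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]

    width = max(5, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for sym in effect_of_gene:
        if sym not in gene_index:
            raise ValueError(f"module gene {sym!r} not in universe of {config.n_genes} genes")
    effects = np.zeros(config.n_genes)
    for sym, eff in effect_of_gene.items():
        effects[gene_index[sym]] = eff
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    matrix = baseline[:, None] + np.outer(effects, a) + noise

    sledai = np.rint(
        config.sledai_scale * a + rng.normal(0.0, config.sledai_noise_sd, n_samples)
    ).astype(int)
    sledai = np.clip(sledai, 0, None)
    sledai[cohort_label == "control"] = 0
    anti_dsdna = np.clip(
        config.anti_dsdna_intercept
        + config.anti_dsdna_slope * a
        + rng.normal(0.0, config.anti_dsdna_noise_sd, n_samples),
        0.5, None,
    )
    c3 = np.clip(
        config.c3_intercept + config.c3_slope * a + rng.normal(0.0, config.c3_noise_sd, n_samples),
        0.01, None,
    )
    c4 = np.clip(
        config.c4_intercept + config.c4_slope * a + rng.normal(0.0, config.c4_noise_sd, n_samples),
        0.005, None,
    )
    clinical = pd.DataFrame(
        {
            "cohort": cohort_label,
            "sledai": sledai,
            "anti_dsdna": anti_dsdna,
            "c3": c3,
            "c4": c4,
            "latent_activity": a,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    clinical["activity_class"] = activity_class(clinical["sledai"])
    clinical.loc[clinical["cohort"] == "control", "activity_class"] = "inactive"
    return ExpressionCohort(
        matrix=pd.DataFrame(matrix, index=genes, columns=sample_ids),
        clinical=clinical,
        name=name or f"synthetic_cohort_seed{config.seed}",
    )
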