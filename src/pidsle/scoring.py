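"""Single-sample module enrichment scoring and patient stratification.

The scoring routine follows the GSVA recipe for microarray-style data:

1. each expression value is scored against its gene's cross-sample
   distribution with a Gaussian-kernel ECDF (bandwidth = per-gene sd x
   ``kernel_bandwidth_factor``, default sd/4);
2. within each sample, genes are ranked by that ECDF score and converted
   to the symmetric rank statistic |r - (G + 1)/2|;
3. a Kolmogorov-Smirnov-like random walk descends the ranked gene list,
   stepping up by the (tau-powered) rank statistic at module genes and
   down uniformly at the rest;
4. the enrichment score is the sum of the maximum positive and maximum
   negative deviations of the walk (``diff_of_extremes``, the reference
   default) or the single largest-magnitude deviation
   (``max_deviation``).  Scores always lie in [-1, 1].

Downstream, module-score contrasts are summarized with Hedges' g
(small-sample corrected standardized mean difference) and Welch's t, and
patients are stratified by Euclidean/complete-linkage hierarchical
clustering with one-way ANOVA + Tukey HSD over clinical traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .cohort import ExpressionCohort
from .gene_db import GeneSet

__all__ = [
    "ScoringParams",
    "ModuleScoreMatrix",
    "gsva_scores",
    "hedges_g",
    "effect_sizes",
    "hierarchical_stratify",
    "clinical_anova",
    "StratificationResult",
]


@dataclass(frozen=True)
class ScoringParams:
    kernel_bandwidth_factor: float = 0.25
    tau: float = 1.0
    statistic: str = "diff_of_extremes"  # or "max_deviation"

    def __post_init__(self) -> None:
        if self.kernel_bandwidth_factor <= 0:
            raise ValueError("kernel_bandwidth_factor must be positive")
        if self.statistic not in {"diff_of_extremes", "max_deviation"}:
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class ModuleScoreMatrix:
    """Modules x samples enrichment scores with provenance."""

    scores: pd.DataFrame  # modules x samples
    provenance: str = ""

    @property
    def modules(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.scores.columns.tolist()

    def write(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="module")

    @classmethod
    def read(cls, path, provenance: str = "") -> "ModuleScoreMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), provenance)


def _kernel_ecdf(matrix: np.ndarray, bandwidth_factor: float, chunk: int = 64) -> np.ndarray:
    """Gaussian-kernel ECDF score of each value against its gene's row.

    score[i, j] = sum_k Phi((x[i, j] - x[i, k]) / h_i), h_i = sd_i * factor.
    Degenerate rows (sd 0) fall back to a sharp kernel so equal values tie.
    """
    g, s = matrix.shape
    sd = matrix.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd * bandwidth_factor, 1e-12)
    out = np.empty((g, s))
    for lo in range(0, g, chunk):
        hi = min(lo + chunk, g)
        block = matrix[lo:hi]
        diff = (block[:, :, None] - block[:, None, :]) / h[lo:hi, None, None]
        out[lo:hi] = special.ndtr(diff).sum(axis=2)
    return out


def gsva_scores(
    cohort: ExpressionCohort,
    modules: list[GeneSet],
    params: ScoringParams = ScoringParams(),
) -> ModuleScoreMatrix:
    """Per-module, per-sample enrichment scores in [-1, 1].

    Module genes absent from the matrix are dropped with a warning; a
    module covering every gene in the matrix is degenerate (the walk has
    no background) and is rejected.
    """
    matrix = cohort.matrix
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for kernel-ECDF scoring")
    genes = np.array(matrix.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = matrix.shape

    ecdf = _kernel_ecdf(matrix.to_numpy(dtype=float), params.kernel_bandwidth_factor)
    # symmetric rank statistic from average ranks of the ECDF score (1 = top)
    rank_stat = np.empty_like(ecdf)
    orders = np.empty((n_samples, n_genes), dtype=int)
    for j in range(n_samples):
        r = stats.rankdata(-ecdf[:, j], method="average")
        rank_stat[:, j] = np.abs(r - (n_genes + 1) / 2.0)
        # walk order: decreasing ECDF score, ties broken by gene symbol
        orders[j] = np.lexsort((genes, -ecdf[:, j]))

    module_masks: list[np.ndarray] = []
    names: list[str] = []
    for module in modules:
        present = [g for g in sorted(module.symbols) if g in gene_pos]
        missing = len(module) - len(present)
        if missing:
            warnings.warn(
                f"module {module.name!r}: {missing} gene(s) absent from matrix"
            )
        if not present:
            raise ValueError(f"module {module.name!r} has no genes in the matrix")
        if len(present) >= n_genes:
            raise ValueError(f"module {module.name!r} covers every gene (degenerate)")
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in present]] = True
        module_masks.append(mask)
        names.append(module.name)

    scores = np.empty((len(modules), n_samples))
    stat_tau = rank_stat**params.tau
    for j in range(n_samples):
        order = orders[j]
        w = stat_tau[order, j]
        for mi, mask in enumerate(module_masks):
            in_set = mask[order]
            m = int(in_set.sum())
            pos = np.where(in_set, w, 0.0)
            pos_total = pos.sum()
            steps = np.where(
                in_set,
                pos / pos_total if pos_total > 0 else 0.0,
                -1.0 / (n_genes - m),
            )
            walk = np.cumsum(steps)
            if params.statistic == "diff_of_extremes":
                scores[mi, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                peak = walk.max()
                trough = walk.min()
                scores[mi, j] = peak if peak >= -trough else trough
    return ModuleScoreMatrix(
        scores=pd.DataFrame(scores, index=names, columns=matrix.columns),
        provenance=cohort.name,
    )


# ---------------------------------------------------------------------------
# Effect sizes


def hedges_g(group1: np.ndarray, group2: np.ndarray) -> float:
    """Hedges' g: J * (mean1 - mean2) / s_pooled, J = 1 - 3/(4(n1+n2)-9)."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    s_pooled_sq = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s_pooled_sq == 0:
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(j * (x1.mean() - x2.mean()) / np.sqrt(s_pooled_sq))


def effect_sizes(
    scores: ModuleScoreMatrix,
    groups: tuple[list[str], list[str]],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-module Hedges' g and Welch's t contrasting two sample groups."""
    cols1, cols2 = groups
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("both groups need >= 2 samples")
    x1 = scores.scores[list(cols1)].to_numpy(dtype=float)
    x2 = scores.scores[list(cols2)].to_numpy(dtype=float)
    rows = []
    for i, module in enumerate(scores.modules):
        g = hedges_g(x1[i], x2[i])
        degenerate = not np.isfinite(g)
        if degenerate:
            t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(x1[i], x2[i], equal_var=False)
        rows.append(
            {
                "module": module,
                "hedges_g": g,
                "welch_t": float(t),
                "welch_p": float(p),
                "significant": bool(p < p_threshold) if np.isfinite(p) else False,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stratification


@dataclass
class StratificationResult:
    labels: pd.Series  # sample -> cluster id (1..k)
    k: int
    linkage_matrix: np.ndarray


def hierarchical_stratify(
    matrix: "ModuleScoreMatrix | pd.DataFrame",
    k: int,
    standardize_rows: bool = False,
) -> StratificationResult:
    """Cluster samples (columns) by Euclidean distance and complete linkage.

    The tree is cut to exactly ``k`` groups; cluster ids are relabelled
    1..k by first appearance in column order so results are deterministic.
    ``standardize_rows`` z-scores each feature row first (off by default).
    """
    df = matrix.scores if isinstance(matrix, ModuleScoreMatrix) else matrix
    n = df.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    data = df.to_numpy(dtype=float)
    if standardize_rows:
        sd = data.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=1)[:, None]) / sd[:, None]
    x = data.T  # samples as observations
    if n == 1:
        return StratificationResult(
            labels=pd.Series([1], index=df.columns), k=1, linkage_matrix=np.empty((0, 4))
        )
    z = linkage(pdist(x, metric="euclidean"), method="complete")
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel by first appearance
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return StratificationResult(
        labels=pd.Series(labels, index=df.columns), k=len(remap), linkage_matrix=z
    )


def clinical_anova(
    labels: pd.Series,
    clinical: pd.DataFrame,
    traits: list[str] = ("sledai", "anti_dsdna", "c3", "c4"),
) -> dict[str, pd.DataFrame]:
    """One-way ANOVA + Tukey HSD of clinical traits across patient clusters.

    Control samples (``cohort == 'control'``) are excluded when the
    clinical table marks them.  Returns three tables: per-trait ANOVA
    (``anova``), per-cluster mean +/- sd (``cluster_stats``) and Tukey
    pairwise adjusted p-values (``tukey``).  A trait constant everywhere
    yields F = 0, p = 1 and is flagged.
    """
    clin = clinical.loc[labels.index]
    if "cohort" in clin.columns:
        keep = clin["cohort"] != "control"
        clin = clin.loc[keep]
        labels = labels.loc[keep]
    cluster_ids = sorted(labels.unique())
    if len(cluster_ids) < 2:
        raise ValueError("need >= 2 clusters for ANOVA")
    anova_rows, stats_rows, tukey_rows = [], [], []
    for trait in traits:
        groups = [
            clin.loc[labels == cid, trait].to_numpy(dtype=float) for cid in cluster_ids
        ]
        for cid, vals in zip(cluster_ids, groups):
            if len(vals) < 2:
                raise ValueError(f"cluster {cid} has < 2 samples with {trait}")
            stats_rows.append(
                {"trait": trait, "cluster": cid, "n": len(vals),
                 "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
            )
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            anova_rows.append(
                {"trait": trait, "F": 0.0, "p": 1.0, "constant": True}
            )
            for i in range(len(cluster_ids)):
                for j in range(i + 1, len(cluster_ids)):
                    tukey_rows.append(
                        {"trait": trait, "cluster_a": cluster_ids[i],
                         "cluster_b": cluster_ids[j], "p_adj": 1.0}
                    )
            continue
        f, p = stats.f_oneway(*groups)
        anova_rows.append({"trait": trait, "F": float(f), "p": float(p), "constant": False})
        hsd = stats.tukey_hsd(*groups)
        for i in range(len(cluster_ids)):
            for j in range(i + 1, len(cluster_ids)):
                tukey_rows.append(
                    {
                        "trait": trait,
                        "cluster_a": cluster_ids[i],
                        "cluster_b": cluster_ids[j],
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
    return {
        "anova": pd.DataFrame(anova_rows),
        "cluster_stats": pd.DataFrame(stats_rows),
        "tukey": pd.DataFrame(tukey_rows),
    }
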