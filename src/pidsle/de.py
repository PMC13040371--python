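"""Differential expression: empirical-Bayes moderated t, BH adjustment,
probe dedup / list-merge rules, and the DE-overlap Monte Carlo test.

The moderated t-statistic follows the standard empirical-Bayes treatment of
microarray linear models: per-gene residual variances s_g^2 (d_g residual
df) are shrunk toward a prior s_0^2 with prior df d_0,

    s_tilde_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),
    t_g = (mean_1 - mean_2) / (s_tilde_g sqrt(1/n_1 + 1/n_2)),

with p-values from the t distribution on d_0 + d_g df.  The hyperparameters
(d_0, s_0^2) are estimated by method of moments from the scaled-F
distribution of log s_g^2, i.e. the closed-form fit used throughout the
moderated-t literature.

A DE gene is called significant by the disjunction rule
(p <= alpha) or (adjusted p < fdr), both thresholds configurable with
defaults alpha = 0.05 and fdr = 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionCohort
from .gene_db import GeneSet
from .overlap import OverlapResult, monte_carlo_overlap

__all__ = [
    "moderated_t",
    "bh_adjust",
    "dedup_probes",
    "merge_significant_lists",
    "apply_significance",
    "de_overlap_test",
    "fit_f_dist",
    "trigamma_inverse",
]

P_THRESHOLD = 0.05
P_ADJ_THRESHOLD = 0.2

RESULT_COLUMNS = ["symbol", "probe_id", "log_fc", "t_mod", "p", "p_adj", "significant"]


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Models s_g^2 ~ s_0^2 F(d_g, d_0); on the log scale
    e_g = log s_g^2 - psi(d_g/2) + log(d_g/2) has mean
    log s_0^2 + psi(d_0/2) - log(d_0/2) and variance
    psi'(d_g/2) + psi'(d_0/2), giving closed-form moment equations.
    Returns (inf, exp(mean)) when the excess variance is non-positive.
    """
    v = np.asarray(variances, dtype=float)
    ok = np.isfinite(v) & (v > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive finite variances")
    z = np.log(v[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = float("inf")
        s0_sq = float(v[ok].mean())
    return d0, s0_sq


def moderated_t(
    cohort: ExpressionCohort,
    contrast: tuple[str, str],
    column: str | None = None,
    p_threshold: float = P_THRESHOLD,
    p_adj_threshold: float = P_ADJ_THRESHOLD,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated-t differential expression (group1 - group2).

    Returns a per-gene table with log_fc, t_mod, p, BH-adjusted p and the
    significance flag; hyperparameters are attached as ``.attrs['d0']`` and
    ``.attrs['s0_sq']``.  ``prior_df`` forces d0 (0 recovers the ordinary
    pooled two-sample t; numpy.inf the common-variance statistic).
    """
    g1, g2 = contrast
    cols1 = cohort.group_samples(g1, column)
    cols2 = cohort.group_samples(g2, column)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError(f"each group needs >= 2 samples ({g1}: {len(cols1)}, {g2}: {len(cols2)})")
    x1 = cohort.matrix[cols1].to_numpy(dtype=float)
    x2 = cohort.matrix[cols2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df_resid
    if prior_df is None:
        try:
            d0, s0_sq = fit_f_dist(s_sq, df_resid)
        except ValueError:
            warnings.warn("variance prior fit failed; using pooled variance")
            d0, s0_sq = float("inf"), float(s_sq.mean())
    elif prior_df == 0:
        d0, s0_sq = 0.0, float("nan")
    elif np.isinf(prior_df):
        # forced common-variance limit: every gene shares the pooled variance
        d0, s0_sq = float("inf"), float(s_sq.mean())
    else:
        d0 = float(prior_df)
        s0_sq = float(s_sq.mean())
    if d0 == 0:
        s_post = s_sq
        df_total = float(df_resid)
    elif np.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = float("inf")
    else:
        s_post = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
        df_total = d0 + df_resid
    # cap the moderated df at the total pooled residual df
    df_total = min(df_total, len(s_sq) * df_resid)
    log_fc = m1 - m2
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log_fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "symbol": cohort.genes,
            "probe_id": cohort.genes,
            "log_fc": log_fc,
            "t_mod": t_mod,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    out = apply_significance(out, p_threshold, p_adj_threshold)
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_total"] = df_total
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_significance(
    results: pd.DataFrame,
    p_threshold: float = P_THRESHOLD,
    p_adj_threshold: float = P_ADJ_THRESHOLD,
) -> pd.DataFrame:
    """Flag significance by (p <= alpha) or (p_adj < fdr)."""
    out = results.copy()
    out["significant"] = (out["p"] <= p_threshold) | (out["p_adj"] < p_adj_threshold)
    return out


def dedup_probes(results: pd.DataFrame) -> pd.DataFrame:
    """One row per symbol, keeping the minimal (p, p_adj, probe_id) tuple."""
    out = results.sort_values(
        ["p", "p_adj", "probe_id"], kind="mergesort"
    ).drop_duplicates(subset="symbol", keep="first")
    return out.sort_values("symbol", kind="mergesort").reset_index(drop=True)


def merge_significant_lists(list_a: pd.DataFrame, list_b: pd.DataFrame) -> pd.DataFrame:
    """Union of significant rows from two DE lists, deduped by the probe rule."""
    for name, lst in (("A", list_a), ("B", list_b)):
        if "significant" not in lst.columns:
            raise ValueError(f"list {name} lacks a 'significant' column")
    merged = pd.concat(
        [list_a[list_a["significant"]], list_b[list_b["significant"]]],
        ignore_index=True,
    )
    return dedup_probes(merged)


def de_overlap_test(
    de: pd.DataFrame,
    markers: GeneSet,
    array_universe: GeneSet,
    n_iterations: int = 100_000,
    seed: int = 0,
) -> OverlapResult:
    """Monte Carlo test of marker enrichment among significant DE genes.

    The draw size is the number of significant DE genes on the array and
    the observed count is |significant ∩ markers|, both after restriction
    to the array universe.
    """
    sig = GeneSet.from_symbols("significant", de.loc[de["significant"], "symbol"])
    sig = sig.intersect(array_universe)
    restricted_markers = markers.intersect(array_universe)
    observed_members = frozenset(sig.symbols & restricted_markers.symbols)
    if len(sig) == 0:
        warnings.warn("no significant genes; degenerate overlap result")
        return OverlapResult(
            universe_size=len(array_universe),
            marker_count=len(restricted_markers),
            draw_size=0, observed=0,
            null_mean=0.0, null_sd=0.0, z=float("nan"), empirical_p=1.0,
            analytic_mean=0.0, analytic_sd=0.0, analytic_z=float("nan"),
            analytic_tail_p=1.0, n_iterations=0, seed=seed, degenerate=True,
        )
    return monte_carlo_overlap(
        universe=array_universe,
        markers=markers,
        draw_size=len(sig),
        observed=len(observed_members),
        n_iterations=n_iterations,
        seed=seed,
        overlap_members=observed_members,
    )
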