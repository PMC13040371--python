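"""Independent oracle implementations used by the test suite.

Everything here is deliberately written as literal, loop-based
transcriptions of the definitions (no shared code with the package), so
each serves as an independent cross-check of the optimized implementation.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def gsva_oracle(matrix, module_symbols, bw_factor=0.25, tau=1.0,
                statistic="diff_of_extremes"):
    """Literal transcription of the kernel-ECDF / rank / random-walk score."""
    genes = list(matrix.index)
    samples = list(matrix.columns)
    G, S = len(genes), len(samples)
    # (1) per-gene Gaussian-kernel ECDF of each sample's value
    z = [[0.0] * S for _ in range(G)]
    for i in range(G):
        vals = [float(matrix.iat[i, k]) for k in range(S)]
        mean = sum(vals) / S
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (S - 1))
        h = sd * bw_factor if sd > 0 else 1e-12
        for j in range(S):
            z[i][j] = sum(
                0.5 * (1.0 + math.erf((vals[j] - vals[k]) / (h * math.sqrt(2.0))))
                for k in range(S)
            ) / S
    member = [g in module_symbols for g in genes]
    scores = []
    for j in range(S):
        col = [z[i][j] for i in range(G)]
        # (2) average ranks (descending) -> symmetric rank statistic
        ranks = []
        for i in range(G):
            higher = sum(1 for i2 in range(G) if col[i2] > col[i])
            ties = sum(1 for i2 in range(G) if col[i2] == col[i])
            ranks.append(higher + (ties + 1) / 2.0)
        stat = [abs(r - (G + 1) / 2.0) for r in ranks]
        order = sorted(range(G), key=lambda i: (-col[i], genes[i]))
        # (3) KS-like random walk down the ranked list
        w = [stat[i] ** tau for i in order]
        in_set = [member[i] for i in order]
        m = sum(in_set)
        pos_total = sum(wi for wi, s in zip(w, in_set) if s)
        walk, cum = [], 0.0
        for wi, s in zip(w, in_set):
            cum += (wi / pos_total) if s else (-1.0 / (G - m))
            walk.append(cum)
        # (4) enrichment statistic
        if statistic == "diff_of_extremes":
            scores.append(max(max(walk), 0.0) + min(min(walk), 0.0))
        else:
            peak, trough = max(walk), min(walk)
            scores.append(peak if peak >= -trough else trough)
    return scores


def kcore_peel(graph: nx.Graph, k: int) -> set:
    """Brute-force iterative pruning oracle for the k-core."""
    nodes = set(graph.nodes)
    changed = True
    while changed:
        changed = False
        for v in sorted(nodes):
            deg = sum(1 for u in graph.neighbors(v) if u in nodes)
            if deg < k:
                nodes.discard(v)
                changed = True
    return nodes


def bh_step_up(p_values) -> np.ndarray:
    """Textbook BH step-up: sort, scale by m/rank, cumulative min, unsort."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating the hypergeometric support.

    Sums P(table) over all tables with the observed margins whose
    probability is <= the observed table's (with the customary relative
    tolerance for float ties).
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_comb(nn, kk):
        return (math.lgamma(nn + 1) - math.lgamma(kk + 1)
                - math.lgamma(nn - kk + 1))

    def prob(aa):
        return math.exp(
            log_comb(col1, aa) + log_comb(n - col1, row1 - aa) - log_comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric pmf via log-gamma (enumeration oracle)."""
    if k < max(0, n + K - N) or k > min(K, n):
        return 0.0
    return math.exp(
        math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1)
        + math.lgamma(N - K + 1) - math.lgamma(n - k + 1)
        - math.lgamma(N - K - n + k + 1)
        + math.lgamma(n + 1) + math.lgamma(N - n + 1) - math.lgamma(N + 1)
    )


def best_match_jaccard(planted: set, clusters) -> float:
    """Best Jaccard similarity of a planted module to any recovered cluster."""
    return max(
        (len(planted & set(c.members)) / len(planted | set(c.members))
         for c in clusters),
        default=0.0,
    )
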