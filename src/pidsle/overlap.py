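"""Gene-set overlap enrichment by Monte Carlo simulation.

Given a universe of N symbols containing K marker genes (e.g. the curated
PID genes), and an observed overlap of k markers inside a set of n drawn
genes (e.g. a GWAS-predicted risk-gene list), the null distribution of the
overlap under uniform draws without replacement is hypergeometric.  The
Monte Carlo routine estimates the null mean/sd empirically — mirroring the
published procedure of drawing 10,000 random gene sets — and the closed
form is always computed alongside it as an analytic oracle:

    E[X]   = n K / N
    Var[X] = n (K/N) (1 - K/N) (N - n) / (N - 1)
    z      = (k - E[X]) / sd[X]

All sets are intersected with the declared universe before any computation,
and the restricted sizes are reported, so mismatched list provenance is
auditable rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gene_db import GeneSet

__all__ = [
    "OverlapCount",
    "OverlapResult",
    "overlap",
    "hypergeometric_overlap",
    "monte_carlo_overlap",
]


@dataclass(frozen=True)
class OverlapCount:
    """Universe-restricted intersection of two gene sets."""

    k: int
    members: frozenset[str]
    size_a: int  # |A ∩ U|
    size_b: int  # |B ∩ U|
    universe_size: int

    @property
    def percent_of_a(self) -> float:
        return 100.0 * self.k / self.size_a if self.size_a else float("nan")


@dataclass(frozen=True)
class HypergeomSummary:
    mean: float
    sd: float
    z: float
    tail_p: float  # upper-tail P(X >= k)


@dataclass(frozen=True)
class OverlapResult:
    """Monte Carlo overlap test result with the analytic closed form."""

    universe_size: int
    marker_count: int
    draw_size: int
    observed: int
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    analytic_mean: float
    analytic_sd: float
    analytic_z: float
    analytic_tail_p: float
    n_iterations: int
    seed: int
    overlap_members: frozenset[str] = field(default_factory=frozenset)
    degenerate: bool = False


def overlap(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> OverlapCount:
    """|A ∩ B ∩ U| with members, after restricting both sets to the universe."""
    if len(universe) == 0:
        raise ValueError("empty universe")
    a = set_a.symbols & universe.symbols
    b = set_b.symbols & universe.symbols
    members = frozenset(a & b)
    return OverlapCount(
        k=len(members),
        members=members,
        size_a=len(a),
        size_b=len(b),
        universe_size=len(universe),
    )


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> HypergeomSummary:
    """Exact null mean/sd/z and upper-tail P(X >= k) for the overlap count."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    mean = n * K / N
    if N > 1:
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    else:
        var = 0.0
    sd = float(np.sqrt(var))
    hi = min(K, n)
    lo = max(0, n + K - N)
    if k > hi:
        tail_p = 0.0
    elif k <= lo:
        tail_p = 1.0
    else:
        tail_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    z = (k - mean) / sd if sd > 0 else float("nan")
    return HypergeomSummary(mean=mean, sd=sd, z=z, tail_p=tail_p)


def _simulate_overlap_counts(
    universe_size: int,
    marker_flags: np.ndarray,
    draw_size: int,
    n_iterations: int,
    rng: np.random.Generator,
    chunk: int = 512,
) -> np.ndarray:
    """Null overlap counts for uniform draws without replacement.

    Each iteration ranks i.i.d. uniform keys over the universe and takes the
    ``draw_size`` smallest — an exact uniform subset draw — then counts the
    markers hit.  Chunked to bound memory at chunk x N floats.
    """
    counts = np.empty(n_iterations, dtype=np.int64)
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        keys = rng.random((m, universe_size))
        idx = np.argpartition(keys, draw_size - 1, axis=1)[:, :draw_size]
        counts[done : done + m] = marker_flags[idx].sum(axis=1)
        done += m
    return counts


def monte_carlo_overlap(
    universe: GeneSet,
    markers: GeneSet,
    draw_size: int,
    observed: int,
    n_iterations: int = 10_000,
    seed: int = 0,
    overlap_members: frozenset[str] = frozenset(),
) -> OverlapResult:
    """Monte Carlo null for the marker overlap of a size-``draw_size`` set.

    ``null_mean``/``null_sd`` are the sample mean and sd (ddof=1) of the
    simulated counts; ``empirical_p`` uses the add-one correction
    (#{count >= observed} + 1)/(n_iterations + 1) so it can never be 0.
    Analytic fields are always filled from the hypergeometric closed form.
    """
    restricted = markers.intersect(universe)
    N, K = len(universe), len(restricted)
    if draw_size > N:
        raise ValueError(f"draw_size {draw_size} exceeds universe size {N}")
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    symbols = np.array(sorted(universe.symbols))
    marker_flags = np.isin(symbols, sorted(restricted.symbols))
    rng = np.random.default_rng(seed)
    counts = _simulate_overlap_counts(N, marker_flags, draw_size, n_iterations, rng)
    null_mean = float(counts.mean())
    null_sd = float(counts.std(ddof=1))
    empirical_p = (int((counts >= observed).sum()) + 1) / (n_iterations + 1)
    analytic = hypergeometric_overlap(N, K, draw_size, observed)
    degenerate = null_sd == 0.0
    z = (observed - null_mean) / null_sd if not degenerate else float("nan")
    return OverlapResult(
        universe_size=N,
        marker_count=K,
        draw_size=draw_size,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        empirical_p=empirical_p,
        analytic_mean=analytic.mean,
        analytic_sd=analytic.sd,
        analytic_z=analytic.z,
        analytic_tail_p=analytic.tail_p,
        n_iterations=n_iterations,
        seed=seed,
        overlap_members=overlap_members,
        degenerate=degenerate,
    )
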