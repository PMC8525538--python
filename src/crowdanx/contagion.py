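"""Anxiety contagion over the community relation matrix.

The cascade iterates

    a_k = a_{k-1} + R . delta(a_{k-1}),      delta(x) = eps * exp((x - UB) / UB)

where R is the symmetric binary relation matrix and delta is the propagation
power of an anxiety level.  Each iteration transmits influence one hop
further, so after K iterations a member has been reached by its K-th-degree
neighborhood.  The community-level score is a normalized *sum* of member
scores (community size matters by design):

    A(C) = norm(sum_i a_K(u_i))

with a saturating norm 1 - exp(-s / tau) by default, or s / (N_max * UB).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.stats import linregress

__all__ = [
    "ContagionParams", "build_relation_matrix", "propagation_power",
    "iterate_anxiety", "run_cascade", "collective_anxiety",
    "default_iteration_depth", "CollectiveAnxietySeries",
    "PolarizationResult", "polarization_assessment", "daily_series",
]

MAX_ITERATION_DEPTH = 6


@dataclass(frozen=True)
class ContagionParams:
    """Parameters of the cascade and of the community-level normalization.

    ``k=None`` means "use min(graph diameter, 6)" which exhausts reachable
    influence on typical community graphs.  ``norm_mode`` is ``saturating``
    (requires ``tau`` > 0) or ``global_max`` (requires ``n_max``, the largest
    community size in the run).
    """

    lam: float = 0.5
    epsilon: float = 0.002
    ub: float = 1.0
    k: int | None = None
    clip_to_ub: bool = True
    norm_mode: str = "saturating"
    tau: float | None = None
    n_max: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0,1], got {self.lam}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be a small positive real")
        if self.ub <= 0:
            raise ValueError("UB must be positive")
        if self.k is not None and self.k < 0:
            raise ValueError("iteration depth K must be >= 0")
        if self.norm_mode not in ("saturating", "global_max"):
            raise ValueError(f"unknown norm mode {self.norm_mode!r}")

    def with_norm(self, *, tau=None, n_max=None) -> "ContagionParams":
        return replace(self, tau=tau if tau is not None else self.tau,
                       n_max=n_max if n_max is not None else self.n_max)


def build_relation_matrix(members, edges) -> np.ndarray:
    """Symmetric binary relation matrix from directed or undirected edges.

    ``members`` is the ordered member id sequence; ``edges`` an iterable of
    (src, dst) id pairs (follow/repost/comment links).  Any directed edge
    sets both r_ij and r_ji; self-edges are dropped so the diagonal stays 0.
    Edges whose endpoints are not members are an error.
    """
    members = list(members)
    index = {u: i for i, u in enumerate(members)}
    if len(index) != len(members):
        raise ValueError("duplicate member ids")
    n = len(members)
    R = np.zeros((n, n), dtype=float)
    offenders = []
    for src, dst in edges:
        i, j = index.get(src), index.get(dst)
        if i is None or j is None:
            offenders.append((src, dst))
            continue
        if i == j:
            continue
        R[i, j] = R[j, i] = 1.0
    if offenders:
        raise ValueError(f"edges reference non-members: {offenders[:10]}")
    return R


def propagation_power(x, params: ContagionParams):
    """delta(x) = eps * exp((x - UB) / UB); strictly increasing, positive."""
    x = np.asarray(x, dtype=float)
    out = params.epsilon * np.exp((x - params.ub) / params.ub)
    return float(out) if out.ndim == 0 else out


def iterate_anxiety(prev: np.ndarray, R: np.ndarray,
                    params: ContagionParams) -> np.ndarray:
    """One cascade round: a_i += sum_j r_ij * delta(a_j), then optional clip."""
    prev = np.asarray(prev, dtype=float)
    if R.shape != (prev.size, prev.size):
        raise ValueError(f"dimension mismatch: |a|={prev.size}, R is {R.shape}")
    nxt = prev + R @ propagation_power(prev, params)
    if params.clip_to_ub:
        nxt = np.clip(nxt, 0.0, params.ub)
    return nxt


def run_cascade(a0: np.ndarray, R: np.ndarray, params: ContagionParams,
                k: int | None = None) -> np.ndarray:
    """Apply ``iterate_anxiety`` K times (K=0 returns a copy of a0).

    K is taken from the argument, else from params, else from the graph
    diameter capped at 6.
    """
    if k is None:
        k = params.k if params.k is not None else default_iteration_depth(R)
    if k < 0:
        raise ValueError("iteration depth K must be >= 0")
    a = np.array(a0, dtype=float)
    for _ in range(k):
        a = iterate_anxiety(a, R, params)
    return a


def default_iteration_depth(R: np.ndarray, cap: int = MAX_ITERATION_DEPTH) -> int:
    """min(diameter of the largest connected component, cap)."""
    n = R.shape[0]
    if n <= 1 or not R.any():
        return 0
    graph = sparse.csr_matrix(R)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        largest = np.bincount(labels).argmax()
        keep = np.flatnonzero(labels == largest)
        graph = graph[np.ix_(keep, keep)]
    dist = shortest_path(graph, method="D", directed=False, unweighted=True)
    return int(min(int(dist.max()), cap))


def collective_anxiety(final: np.ndarray, params: ContagionParams) -> float:
    """A(C): normalized sum of post-cascade member scores, in [0,1]."""
    s = float(np.sum(final))
    if params.norm_mode == "saturating":
        if params.tau is None or params.tau <= 0:
            raise ValueError("saturating norm requires tau > 0")
        return 1.0 - np.exp(-s / params.tau)
    if params.n_max is None or params.n_max <= 0:
        raise ValueError("global_max norm requires N_max (largest community size)")
    return min(s / (params.n_max * params.ub), 1.0)


@dataclass
class CollectiveAnxietySeries:
    """Daily collective anxiety of one community."""

    community_id: object
    days: np.ndarray                  # day indices with any activity so far
    a: np.ndarray                     # daily A(C) in [0,1]
    n_active: np.ndarray              # members active (any message) by day t
    trend_slope: float | None = None
    trend_p: float | None = None
    polarized: bool | None = None
    fluctuation: float | None = None

    def assess(self) -> "CollectiveAnxietySeries":
        res = polarization_assessment(self.a)
        self.trend_slope = res.trend_slope
        self.trend_p = res.trend_p
        self.polarized = res.polarized
        # a community observed on a single active day never fluctuated
        self.fluctuation = 0.0 if self.a.size == 1 else res.fluctuation
        return self


@dataclass(frozen=True)
class PolarizationResult:
    trend_slope: float | None
    trend_p: float | None
    polarized: bool | None
    fluctuation: float | None


def polarization_assessment(a_series) -> PolarizationResult:
    """Trend, polarization flag and fluctuation of a daily A(C) series.

    The community is flagged as affectively polarized when the daily series
    shows a significant accumulation trend (least-squares slope > 0 with
    p < 0.05).  Fluctuation is the sample standard deviation (ddof=1) of
    the daily values.  With too few points the flags are reported as None,
    not fabricated.
    """
    a = np.asarray(a_series, dtype=float)
    fluct = float(np.std(a, ddof=1)) if a.size >= 2 else None
    if a.size < 3:
        return PolarizationResult(None, None, None, fluct)
    t = np.arange(a.size, dtype=float)
    if np.allclose(a, a[0]):
        return PolarizationResult(0.0, None, False, fluct)
    fit = linregress(t, a)
    polarized = bool(fit.slope > 0 and fit.pvalue < 0.05)
    return PolarizationResult(float(fit.slope), float(fit.pvalue), polarized, fluct)


def daily_series(corpus, community_id, scorer, params: ContagionParams | None = None,
                 **kwargs) -> CollectiveAnxietySeries:
    """Daily collective-anxiety series for one community of a corpus.

    Convenience wrapper over the vectorized engine in
    :mod:`crowdanx.pipeline`; see
    :func:`crowdanx.pipeline.community_daily_series`.
    """
    from . import pipeline  # pipeline depends on this module

    return pipeline.community_daily_series(corpus, community_id, scorer,
                                           params=params, **kwargs)
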