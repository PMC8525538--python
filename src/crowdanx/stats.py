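"""Community features, ordinal-rating validation and the hypothesis battery.

Validation uses *directional* precision/recall: comparing a model's ordinal
anxiety rating with ground truth, a case counts as tp when consistent, fp
when the model is more severe, fn when less severe, so tp+fp+fn always
equals the number of rated communities and

    precision = tp / (tp + fp),    recall = tp / (tp + fn).

The hypothesis battery mirrors the study design: Pearson correlations of
collective anxiety with topic familiarity/proximity (H1a/H1b), a simple
regression on community declarative knowledge (H2), a Spearman correlation
of influencer ratio with anxiety fluctuation (H3), and a 10-predictor OLS
for the full feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RATING_LEVELS", "RATING_ORDER", "rate_community", "ValidationCounts",
    "precision_recall", "influencer_ratio", "GraphMetrics", "graph_metrics",
    "StatResult", "test_h1", "test_h2", "test_h3", "REGRESSION_PREDICTORS",
    "anxiety_regression", "hypothesis_battery",
]

RATING_LEVELS = ("no", "little", "medium", "high", "extreme")
RATING_ORDER = {name: i for i, name in enumerate(RATING_LEVELS)}

DEFAULT_RATING_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def rate_community(a: float, edges=DEFAULT_RATING_EDGES) -> str:
    """Map a collective anxiety score A in [0,1] to one of 5 ordinal levels.

    Bands are half-open [lo, hi) with the last band closed, so band edges
    map to the upper band.  Default bands are equal quintiles.
    """
    if not edges[0] <= a <= edges[-1]:
        raise ValueError(f"A={a} outside [{edges[0]}, {edges[-1]}]")
    for i in range(len(RATING_LEVELS)):
        if edges[i] <= a < edges[i + 1]:
            return RATING_LEVELS[i]
    return RATING_LEVELS[-1]


@dataclass(frozen=True)
class ValidationCounts:
    """Directional confusion counts over ordinal ratings.

    Undefined ratios (empty denominator) are reported as NaN.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")


def _to_ordinal(ratings, order) -> np.ndarray:
    vals = []
    for r in ratings:
        if isinstance(r, str):
            if r not in order:
                raise ValueError(f"unknown rating label {r!r}")
            vals.append(order[r])
        else:
            vals.append(int(r))
    return np.asarray(vals)


def precision_recall(model_ratings, truth_ratings, order=RATING_ORDER) -> ValidationCounts:
    """Directional confusion counts: tp (equal), fp (model more severe),
    fn (model less severe)."""
    model = _to_ordinal(model_ratings, order)
    truth = _to_ordinal(truth_ratings, order)
    if model.size != truth.size:
        raise ValueError(f"length mismatch: {model.size} model vs {truth.size} truth")
    return ValidationCounts(tp=int(np.sum(model == truth)),
                            fp=int(np.sum(model > truth)),
                            fn=int(np.sum(model < truth)))


def influencer_ratio(profiles: pd.DataFrame) -> float:
    """Yellow-"V" personal accounts / personal accounts (organizational
    accounts excluded)."""
    personal = profiles[~profiles["is_organizational"].astype(bool)]
    if personal.empty:
        raise ValueError("community has no personal accounts")
    return float(personal["is_influencer"].astype(bool).mean())


@dataclass(frozen=True)
class GraphMetrics:
    edge_density: float          # repost/comment edge density, NaN for n<2
    diameter: int                # largest-component diameter of the relation graph
    interaction_frequency: float  # (reposts+comments) / members / day


def _undirected_pairs(members, edges) -> set[tuple]:
    index = {u: i for i, u in enumerate(members)}
    pairs = set()
    for src, dst in edges:
        i, j = index[src], index[dst]
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def graph_diameter(members, edges) -> int:
    """Longest shortest path on the largest connected component."""
    members = list(members)
    n = len(members)
    pairs = _undirected_pairs(members, edges)
    if n <= 1 or not pairs:
        return 0
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    graph = sparse.coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n)).tocsr()
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        keep = np.flatnonzero(labels == np.bincount(labels).argmax())
        graph = graph[np.ix_(keep, keep)]
    dist = shortest_path(graph, method="D", directed=False, unweighted=True)
    return int(dist.max())


def graph_metrics(members, relation_edges, interaction_edges,
                  n_reposts: int, n_comments: int, n_days: int,
                  diameter: int | None = None) -> GraphMetrics:
    """Edge density of repost/comment links, relation-graph diameter, and
    interaction frequency per member per day.

    ``diameter`` may be supplied when the caller has already computed it
    for the same relation edges.
    """
    members = list(members)
    n = len(members)
    if n < 2:
        density = float("nan")
    else:
        density = 2.0 * len(_undirected_pairs(members, interaction_edges)) / (n * (n - 1))
    diam = graph_diameter(members, relation_edges) if diameter is None else diameter
    freq = (n_reposts + n_comments) / n / n_days if n and n_days else float("nan")
    return GraphMetrics(density, diam, freq)


@dataclass(frozen=True)
class StatResult:
    """One test outcome: the headline estimate, its p-value and context."""

    estimate: float
    p: float
    n: int
    method: str
    aux: dict = field(default_factory=dict)
    note: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)

    def to_dict(self) -> dict:
        d = {"estimate": self.estimate, "p": self.p, "n": self.n, "method": self.method}
        d.update(self.aux)
        if self.note:
            d["note"] = self.note
        return d


def _na_result(method: str, n: int, note: str) -> StatResult:
    return StatResult(float("nan"), float("nan"), n, method, note=note)


def _pearson(x, y, method: str) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return _na_result(method, x.size, "fewer than 3 communities")
    if np.std(x) == 0 or np.std(y) == 0:
        return _na_result(method, x.size, "zero variance in a variable")
    r, p = pearsonr(x, y)
    return StatResult(float(r), float(p), x.size, method)


def test_h1(features: pd.DataFrame) -> tuple[StatResult, StatResult]:
    """H1: Pearson r of collective anxiety with topic familiarity (H1a)
    and topic proximity (H1b), both coded 0/1."""
    fam = _pearson(features["familiarity"], features["avg_collective_anxiety"],
                   "pearson avg_collective_anxiety ~ familiarity")
    prox = _pearson(features["proximity"], features["avg_collective_anxiety"],
                    "pearson avg_collective_anxiety ~ proximity")
    return fam, prox


def test_h2(features: pd.DataFrame) -> StatResult:
    """H2: simple OLS of collective anxiety on community declarative
    knowledge; reports beta with R^2 and F."""
    method = "ols avg_collective_anxiety ~ dk_level"
    x = features["dk_level"].to_numpy(dtype=float)
    y = features["avg_collective_anxiety"].to_numpy(dtype=float)
    if x.size < 3:
        return _na_result(method, x.size, "fewer than 3 communities")
    if np.std(x) == 0:
        return _na_result(method, x.size, "degenerate predictor (zero variance)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return StatResult(float(model.params[1]), float(model.pvalues[1]), x.size, method,
                      aux={"r2": float(model.rsquared), "F": float(model.fvalue),
                           "t": float(model.tvalues[1])})


def test_h3(features: pd.DataFrame) -> StatResult:
    """H3: Spearman rho of influencer ratio with the SD of daily collective
    anxiety (fluctuation)."""
    method = "spearman anxiety_sd ~ influencer_ratio"
    x = features["influencer_ratio"].to_numpy(dtype=float)
    y = features["anxiety_sd"].to_numpy(dtype=float)
    if x.size < 3:
        return _na_result(method, x.size, "fewer than 3 communities")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return _na_result(method, x.size, "ties-only data")
    rho, p = spearmanr(x, y)
    return StatResult(float(rho), float(p), x.size, method)


REGRESSION_PREDICTORS = (
    "familiarity", "proximity", "dk_level", "influencer_ratio",
    "n_posts", "n_comments", "n_members", "interaction_frequency",
    "edge_density", "diameter",
)


def anxiety_regression(features: pd.DataFrame,
                       predictors=REGRESSION_PREDICTORS) -> dict[str, StatResult]:
    """OLS of collective anxiety on the full community feature set.

    Returns one StatResult (beta, SD, t, p) per predictor.  Degenerate or
    collinear predictors are an error naming the offending columns.
    """
    predictors = list(predictors)
    if len(features) < len(predictors) + 2:
        raise ValueError(f"need at least {len(predictors) + 2} communities, "
                         f"got {len(features)}")
    X = features[predictors].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        bad = [p for i, p in enumerate(predictors) if not np.isfinite(X[:, i]).all()]
        raise ValueError(f"non-finite values in predictor(s): {bad}")
    degenerate = [p for i, p in enumerate(predictors) if np.std(X[:, i]) == 0]
    if degenerate:
        raise ValueError(f"degenerate (constant) predictor(s): {degenerate}")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        offenders = _collinear_columns(X, predictors)
        raise ValueError(f"perfectly collinear predictor(s): {offenders}")
    y = features["avg_collective_anxiety"].to_numpy(dtype=float)
    model = sm.OLS(y, Xc).fit()
    out = {}
    for i, name in enumerate(predictors, start=1):
        out[name] = StatResult(float(model.params[i]), float(model.pvalues[i]),
                               len(features), "ols avg_collective_anxiety ~ features",
                               aux={"sd": float(model.bse[i]), "t": float(model.tvalues[i])})
    out["_model"] = StatResult(float(model.rsquared), float(model.f_pvalue),
                               len(features), "ols model fit",
                               aux={"F": float(model.fvalue)})
    return out


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    offenders = []
    for i in range(X.shape[1]):
        others = np.delete(X, i, axis=1)
        resid = X[:, i] - others @ np.linalg.lstsq(others, X[:, i], rcond=None)[0]
        denom = np.linalg.norm(X[:, i]) or 1.0
        if np.linalg.norm(resid) / denom < 1e-10:
            offenders.append(names[i])
    return offenders


def hypothesis_battery(features: pd.DataFrame, holm: bool = False) -> dict:
    """Run H1a/H1b/H2/H3 and the full regression on a features table.

    p-values are reported raw by default, matching the study's analysis;
    ``holm=True`` additionally reports Holm-adjusted p-values for the four
    headline tests.
    """
    h1a, h1b = test_h1(features)
    h2 = test_h2(features)
    h3 = test_h3(features)
    report = {"h1a_familiarity": h1a.to_dict(), "h1b_proximity": h1b.to_dict(),
              "h2_dk": h2.to_dict(), "h3_influencers": h3.to_dict()}
    if holm:
        ps = [h1a.p, h1b.p, h2.p, h3.p]
        if np.isfinite(ps).all():
            adj = multipletests(ps, method="holm")[1]
            for key, p_adj in zip(["h1a_familiarity", "h1b_proximity", "h2_dk",
                                   "h3_influencers"], adj):
                report[key]["p_holm"] = float(p_adj)
    try:
        reg = anxiety_regression(features)
        report["regression"] = {k: v.to_dict() for k, v in reg.items()}
    except ValueError as exc:
        report["regression"] = {"error": str(exc)}
    return report
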