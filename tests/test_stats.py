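"""Community features, directional validation and the hypothesis battery."""

import numpy as np
import pandas as pd
import pytest

from crowdanx.stats import (anxiety_regression, graph_metrics,
                            influencer_ratio, precision_recall, rate_community)
from crowdanx.stats import test_h1 as h1_test
from crowdanx.stats import test_h2 as h2_test
from crowdanx.stats import test_h3 as h3_test

from conftest import make_profiles


class TestRating:
    @pytest.mark.parametrize("a,level", [
        (0.05, "no"), (0.95, "extreme"), (0.5, "medium"),
        (0.2, "little"), (0.4, "medium"), (0.8, "extreme"),  # edges go up
        (1.0, "extreme"), (0.0, "no"),
    ])
    def test_quintile_bands(self, a, level):
        assert rate_community(a) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rate_community(1.2)


class TestDirectionalPrecisionRecall:
    def test_worked_example(self):
        truth = ["medium", "medium", "high"]
        model = ["medium", "high", "little"]
        c = precision_recall(model, truth)
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)
        assert c.precision == 0.5 and c.recall == 0.5

    def test_identical_vectors(self):
        c = precision_recall(["no", "high"], ["no", "high"])
        assert c.precision == 1.0 and c.recall == 1.0

    def test_uniform_over_rating_yields_undefined_recall(self):
        c = precision_recall([1, 2, 3], [0, 1, 2])
        assert c.precision == 0.0 and np.isnan(c.recall)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            precision_recall([1], [1, 2])

    def test_matches_brute_force_on_random_ordinals(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(1, 60))
            model = rng.integers(0, 5, n)
            truth = rng.integers(0, 5, n)
            c = precision_recall(model, truth)
            tp = sum(1 for a, b in zip(model, truth) if a == b)
            fp = sum(1 for a, b in zip(model, truth) if a > b)
            fn = sum(1 for a, b in zip(model, truth) if a < b)
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
            assert c.tp + c.fp + c.fn == n


class TestInfluencerRatio:
    def test_fraction_of_personal_accounts(self):
        prof = make_profiles(10)
        prof.loc[:1, "is_influencer"] = True
        assert influencer_ratio(prof) == pytest.approx(0.2)

    def test_extremes(self):
        assert influencer_ratio(make_profiles(5)) == 0.0
        assert influencer_ratio(make_profiles(5, is_influencer=True)) == 1.0

    def test_organizational_accounts_do_not_count(self):
        prof = make_profiles(10)
        prof.loc[:4, "is_organizational"] = True
        prof.loc[5, "is_influencer"] = True
        assert influencer_ratio(prof) == pytest.approx(0.2)

    def test_empty_community_is_an_error(self):
        with pytest.raises(ValueError, match="personal"):
            influencer_ratio(make_profiles(3, is_organizational=True))


def brute_force_diameter(n, edges):
    """Floyd-Warshall over the largest connected component."""
    inf = float("inf")
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for a, b in edges:
        d[a][b] = d[b][a] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    comps, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if d[i][j] < inf}
        seen |= comp
        comps.append(comp)
    comp = max(comps, key=len)
    return max(int(d[i][j]) for i in comp for j in comp)


class TestGraphMetrics:
    def test_complete_graph(self):
        members = list(range(4))
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        gm = graph_metrics(members, edges, edges, n_reposts=3, n_comments=1,
                          n_days=2)
        assert gm.edge_density == 1.0
        assert gm.diameter == 1
        assert gm.interaction_frequency == pytest.approx(4 / 4 / 2)

    def test_path_graph_diameter(self):
        edges = [(0, 1), (1, 2), (2, 3)]
        gm = graph_metrics(range(4), edges, [], 0, 0, 1)
        assert gm.diameter == 3
        assert gm.edge_density == 0.0

    def test_diameter_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(2, 11))
            edges = list({(min(int(a), int(b)), max(int(a), int(b)))
                          for a, b in rng.integers(0, n, (n + 2, 2)) if a != b})
            if not edges:
                continue
            gm = graph_metrics(range(n), edges, edges, 0, 0, 1)
            assert gm.diameter == brute_force_diameter(n, edges)

    def test_single_member_density_is_undefined(self):
        gm = graph_metrics([0], [], [], 0, 0, 1)
        assert np.isnan(gm.edge_density)


def features_frame(**cols):
    n = len(next(iter(cols.values())))
    base = {"avg_collective_anxiety": np.linspace(0.2, 0.8, n),
            "familiarity": np.resize([0, 1], n), "proximity": np.resize([0, 1], n),
            "dk_level": np.linspace(0, 1, n), "influencer_ratio": np.linspace(0, 0.4, n),
            "anxiety_sd": np.linspace(0.01, 0.05, n)}
    base.update(cols)
    return pd.DataFrame(base)


class TestHypothesisBattery:
    def test_perfectly_anticorrelated_binary_predictor(self):
        f = features_frame(proximity=np.resize([1, 0], 8),
                           avg_collective_anxiety=np.resize([0.2, 0.8], 8))
        _, prox = h1_test(f)
        assert prox.estimate == pytest.approx(-1.0)

    def test_zero_variance_predictor_reported_as_na(self):
        f = features_frame(familiarity=np.ones(6))
        fam, _ = h1_test(f)
        assert np.isnan(fam.estimate) and fam.note

    def test_exact_line_regression(self):
        x = np.linspace(0, 1, 12)
        f = features_frame(dk_level=x, avg_collective_anxiety=1 - x)
        res = h2_test(f)
        assert res.estimate == pytest.approx(-1.0, abs=1e-10)
        assert res.aux["r2"] == pytest.approx(1.0)

    def test_h2_beta_matches_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.random(15)
        y = 0.3 - 0.4 * x + rng.normal(0, 0.05, 15)
        f = features_frame(dk_level=x, avg_collective_anxiety=y)
        res = h2_test(f)
        beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert res.estimate == pytest.approx(beta, abs=1e-10)

    def test_h3_monotone_decreasing_is_minus_one(self):
        f = features_frame(influencer_ratio=np.linspace(0, 0.5, 9),
                           anxiety_sd=np.linspace(0.08, 0.01, 9))
        res = h3_test(f)
        assert res.estimate == pytest.approx(-1.0)

    def test_h3_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        x, y = rng.random(14), rng.random(14)
        f = features_frame(influencer_ratio=x, anxiety_sd=y)
        res = h3_test(f)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        rho = np.corrcoef(rx, ry)[0, 1]
        assert res.estimate == pytest.approx(rho, abs=1e-10)

    def test_h3_ties_only_is_na(self):
        f = features_frame(influencer_ratio=np.full(6, 0.2))
        assert np.isnan(h3_test(f).estimate)


class TestFullRegression:
    def _noiseless_frame(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        cols = {name: rng.random(n) for name in
                ("familiarity", "proximity", "dk_level", "influencer_ratio",
                 "n_posts", "n_comments", "n_members", "interaction_frequency",
                 "edge_density", "diameter")}
        betas = {"familiarity": 0.0, "proximity": -0.2, "dk_level": -0.5,
                 "influencer_ratio": -0.1, "n_posts": 0.01, "n_comments": 0.0,
                 "n_members": 0.02, "interaction_frequency": 0.0,
                 "edge_density": 0.3, "diameter": -0.04}
        f = pd.DataFrame(cols)
        f["avg_collective_anxiety"] = 0.1 + sum(betas[k] * f[k] for k in betas)
        return f, betas

    def test_noiseless_coefficients_recovered(self):
        f, betas = self._noiseless_frame()
        res = anxiety_regression(f)
        for name, beta in betas.items():
            assert res[name].estimate == pytest.approx(beta, abs=1e-8)

    def test_all_zero_predictor_is_an_error(self):
        f, _ = self._noiseless_frame()
        f["n_posts"] = 0.0
        with pytest.raises(ValueError, match="n_posts"):
            anxiety_regression(f)

    def test_collinear_predictors_are_named(self):
        f, _ = self._noiseless_frame()
        f["n_comments"] = 2.0 * f["n_posts"]
        with pytest.raises(ValueError, match="n_comments"):
            anxiety_regression(f)

    def test_too_few_communities(self):
        f, _ = self._noiseless_frame(n=8)
        with pytest.raises(ValueError, match="communities"):
            anxiety_regression(f)
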