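import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist, pdist, squareform

from phylocomm.inference import (
    LmeResult,
    confidence_ellipse,
    fit_lme_tree_type,
    nmds,
    permanova,
)


def planar_config(n=8, seed=1):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    return pts, squareform(pdist(pts))


def procrustes_error(a, b):
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(a, b)
    return disparity


class TestNmds:
    def test_planar_distances_recovered(self):
        pts, d = planar_config()
        res = nmds(d, seed=0)
        assert res.stress < 1e-3
        assert procrustes_error(pts, res.coordinates.to_numpy()) < 1e-3

    def test_three_clusters_separate(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [40, 0], [0, 40]], dtype=float)
        pts = np.vstack([c + rng.normal(scale=1.0, size=(6, 2)) for c in centers])
        labels = np.repeat([0, 1, 2], 6)
        res = nmds(squareform(pdist(pts)), seed=4)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(res.coordinates.to_numpy(), labels) > 0.5

    def test_deterministic_given_seed(self):
        _, d = planar_config(n=10, seed=7)
        a = nmds(d, seed=42)
        b = nmds(d, seed=42)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_degenerate_and_small_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            nmds(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="at least 4"):
            nmds(np.eye(3))


class TestEllipse:
    def test_circle_points(self):
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.c_[np.cos(theta), np.sin(theta)]
        (es,) = confidence_ellipse(pts, ["g"] * 60)
        assert np.allclose(es.center, 0, atol=1e-12)
        # circular: covariance is isotropic
        assert es.covariance[0, 0] == pytest.approx(es.covariance[1, 1], rel=1e-9)
        assert es.covariance[0, 1] == pytest.approx(0, abs=1e-12)

    def test_monte_carlo_coverage(self):
        rng = np.random.default_rng(12)
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=10_000)
        (es,) = confidence_ellipse(pts, ["g"] * len(pts), level=0.95)
        coverage = es.contains(pts).mean()
        assert abs(coverage - 0.95) < 0.01

    def test_disjoint_clusters_disjoint_ellipses(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2)) + 50
        specs = confidence_ellipse(np.vstack([a, b]), ["a"] * 30 + ["b"] * 30)
        ea, eb = specs
        assert not ea.contains(eb.boundary()).any()
        assert not eb.contains(ea.boundary()).any()

    def test_small_group_skipped_with_warning(self):
        pts = np.array([[0, 0], [1, 1], [2, 0], [0, 1]])
        with pytest.warns(UserWarning, match="skipped"):
            specs = confidence_ellipse(pts, ["a", "a", "a", "b"])
        assert [s.group for s in specs] == ["a"]


def toy_distance_data(n_per=3, spread=0.5, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    groups = ["x"] * n_per + ["y"] * n_per
    pts = rng.normal(scale=spread, size=(2 * n_per, 3))
    pts[n_per:, 0] += separation
    d = squareform(pdist(pts))
    factors = pd.DataFrame(
        {"tree_type": groups, "year": [2000, 2001] * n_per},
        index=[f"c{i}" for i in range(2 * n_per)],
    )
    return pd.DataFrame(d, index=factors.index, columns=factors.index), factors


class TestPermanova:
    def test_r2_partition_sums_to_one(self):
        d, factors = toy_distance_data(n_per=6, seed=2)
        res = permanova(d, factors, permutations=99, seed=0)
        total_r2 = sum(t.r2 for t in res.terms) + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_exact_enumeration_single_term(self):
        # n = 6, one two-level factor: exact p over all 6! row orders
        from _oracles import permanova_exact_p

        d, factors = toy_distance_data(n_per=3, seed=8, separation=1.5)
        res = permanova(d, factors, terms=("tree_type",), permutations=999, seed=3)

        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ (d.to_numpy() ** 2) @ j
        ones = np.ones((n, 1))
        x = np.hstack([ones, pd.get_dummies(factors["tree_type"], drop_first=True)
                       .to_numpy(float)])
        h0 = ones @ np.linalg.pinv(ones.T @ ones) @ ones.T
        h1 = x @ np.linalg.pinv(x.T @ x) @ x.T
        p_exact = permanova_exact_p(
            g, [h1 - h0], np.eye(n) - h1, np.array([1.0]), 4,
            np.array([res.terms[0].pseudo_f]),
        )[0]
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.terms[0].p_value - p_exact) <= 2 * se + 2 / 999

    def test_saturation_two_separated_clusters(self):
        d, factors = toy_distance_data(n_per=8, spread=0.05, separation=100, seed=4)
        res = permanova(d, factors, terms=("tree_type",), permutations=99, seed=1)
        assert res.terms[0].r2 > 0.99
        assert res.terms[0].p_value < 0.05

    def test_matches_skbio_one_way(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        d, factors = toy_distance_data(n_per=5, seed=6, separation=1.0)
        res = permanova(d, factors, terms=("tree_type",), permutations=999, seed=2)
        sk = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=factors["tree_type"].to_numpy(), permutations=999,
        )
        assert res.terms[0].pseudo_f == pytest.approx(sk["test statistic"], abs=1e-8)
        assert abs(res.terms[0].p_value - sk["p-value"]) < 0.05

    def test_joint_permutation_invariance(self):
        d, factors = toy_distance_data(n_per=5, seed=9, separation=1.0)
        res = permanova(d, factors, permutations=99, seed=0)
        perm = np.random.default_rng(1).permutation(len(d))
        d2 = d.iloc[perm, perm]
        res2 = permanova(d2, factors.iloc[perm], permutations=99, seed=0)
        for t1, t2 in zip(res.terms, res2.terms):
            assert t1.r2 == pytest.approx(t2.r2, abs=1e-9)

    def test_single_level_factor_error(self):
        d, factors = toy_distance_data()
        factors["tree_type"] = "x"
        with pytest.raises(ValueError, match="single level"):
            permanova(d, factors, permutations=99)

    def test_misaligned_ids_error(self):
        d, factors = toy_distance_data()
        bad = factors.copy()
        bad.index = [f"z{i}" for i in range(len(bad))]
        with pytest.raises(ValueError, match="match"):
            permanova(d, bad, permutations=99)


def lme_sim_data(rng, n_types=3, years=2, trees=4, realizations=3,
                 type_effects=(0.0, 0.0, 0.0), sd=1.0):
    types = ["hybrid", "Fremont", "narrowleaf"][:n_types]
    year_eff = {2000 + y: rng.normal(scale=0.5) for y in range(years)}
    real_eff = {f"r{k}": rng.normal(scale=0.5) for k in range(realizations)}
    rows = []
    for ti, tt in enumerate(types):
        for tr in range(trees):
            tree_eff = rng.normal(scale=0.5)
            for y, ye in year_eff.items():
                for rk, re in real_eff.items():
                    rows.append({
                        "value": 10 + type_effects[ti] + ye + re + tree_eff
                        + rng.normal(scale=sd),
                        "tree_type": tt, "year": y, "realization": rk,
                        "tree_id": f"{tt}_{tr}",
                    })
    return pd.DataFrame(rows)


class TestLme:
    def test_degenerate_collapses_to_ols(self):
        rng = np.random.default_rng(0)
        df = lme_sim_data(rng, years=1, trees=3, realizations=1)
        df = df.drop(columns=["tree_id"])
        df["year"] = 2000
        df["realization"] = "r0"
        res = fit_lme_tree_type(df, pooled=True)
        assert res.method == "OLS"
        x = pd.get_dummies(
            pd.Categorical(df["tree_type"],
                           categories=["hybrid", "Fremont", "narrowleaf"]),
            drop_first=True,
        ).to_numpy(float)
        x = np.hstack([np.ones((len(df), 1)), x])
        beta = np.linalg.lstsq(x, df["value"].to_numpy(), rcond=None)[0]
        est = [res.effect("Intercept (hybrid)").estimate,
               res.effect("Fremont").estimate,
               res.effect("narrowleaf").estimate]
        np.testing.assert_allclose(est, beta, atol=1e-6)

    def test_reml_with_crossed_random_effects(self):
        rng = np.random.default_rng(1)
        df = lme_sim_data(rng, type_effects=(0.0, -3.0, 0.0), sd=0.6)
        res = fit_lme_tree_type(df, pooled=False)
        assert res.method == "REML" and res.converged
        fe = res.effect("Fremont")
        assert fe.significant and fe.estimate < 0
        assert set(res.variance_components) == {"realization", "year", "tree_id"}
        assert fe.ci_low < fe.estimate < fe.ci_high

    def test_contrast_coding_invariance(self):
        rng = np.random.default_rng(2)
        df = lme_sim_data(rng, type_effects=(0.0, -1.5, 0.7), sd=0.8)
        res_h = fit_lme_tree_type(df, reference="hybrid")
        res_f = fit_lme_tree_type(df, reference="Fremont")
        np.testing.assert_allclose(res_h.fitted, res_f.fitted, atol=1e-8)
        # Fremont-vs-narrowleaf gap is the same under either coding
        gap_h = res_h.effect("Fremont").estimate - res_h.effect("narrowleaf").estimate
        gap_f = -res_f.effect("narrowleaf").estimate
        assert gap_h == pytest.approx(gap_f, abs=1e-8)

    def test_richness_covariate_included(self):
        rng = np.random.default_rng(3)
        df = lme_sim_data(rng)
        df["richness"] = rng.integers(5, 30, size=len(df))
        df["value"] = df["value"] + 2.0 * df["richness"]
        res = fit_lme_tree_type(df, include_richness=True)
        rich = res.effect("richness")
        assert rich.significant
        assert rich.estimate == pytest.approx(2.0, abs=0.1)

    def test_requires_two_types(self):
        df = pd.DataFrame({"value": [1.0, 2.0], "tree_type": ["hybrid", "hybrid"],
                           "year": [2000, 2001], "realization": ["r0", "r0"]})
        with pytest.raises(ValueError, match="two tree types"):
            fit_lme_tree_type(df)


def test_ordination_plot_smoke(tmp_path):
    rng = np.random.default_rng(1)
    pts = pd.DataFrame(rng.normal(size=(12, 2)), columns=["NMDS1", "NMDS2"])
    groups = ["Fremont", "hybrid", "narrowleaf"] * 4
    from phylocomm.plotting import plot_ordination

    out = tmp_path / "ord.png"
    plot_ordination(pts, groups, path=out, title="demo")
    assert out.exists() and out.stat().st_size > 0
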