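"""Mixed models, d-separation basis sets and Fisher's C."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from marshcarbon import pathsem, synthdata
from marshcarbon.pathsem import (
    PathDAG,
    basis_set,
    fishers_c,
    fit_lmm,
    r2_nakagawa,
    simplify_and_fit_sem,
    standardize_paths,
)


def _ols(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class TestFitLmm:
    def test_zero_group_variance_reduces_to_ols(self, rng):
        n = 150
        x = rng.standard_normal(n)
        groups = np.repeat(np.arange(5), 30)
        # zero realised site effects: noise centred within every group so the
        # profiled likelihood peaks exactly at the theta = 0 boundary
        eps = 0.5 * rng.standard_normal(n)
        for g in range(5):
            eps[groups == g] -= eps[groups == g].mean()
        y = 1.0 + 2.0 * x + eps
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, groups, names=("(intercept)", "x"))
        beta_ols = _ols(y, X)
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        assert fit.sigma_b2 == pytest.approx(0.0, abs=1e-4)

    def test_parameter_recovery_with_site_intercepts(self, rng):
        n_sites, per = 10, 20
        n = n_sites * per
        x = rng.standard_normal(n)
        b_site = 0.8 * rng.standard_normal(n_sites)
        y = 2.0 * x + np.repeat(b_site, per) + 0.5 * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, np.repeat(np.arange(n_sites), per), ("(intercept)", "x"))
        slope_i = fit.names.index("x")
        assert abs(fit.beta[slope_i] - 2.0) < 3 * fit.se[slope_i]
        assert fit.sigma_b2 == pytest.approx(0.64, rel=0.6)
        assert fit.sigma_e2 == pytest.approx(0.25, rel=0.3)

    def test_loglik_is_at_the_optimum(self, rng):
        from marshcarbon.pathsem import _profiled_ml

        n = 120
        x = rng.standard_normal(n)
        groups = np.repeat(np.arange(6), 20)
        y = x + np.repeat(rng.standard_normal(6), 20) + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, groups, ("(intercept)", "x"))
        gidx = [np.where(groups == g)[0] for g in range(6)]
        for theta in rng.uniform(0, 10, size=50):
            assert fit.loglik >= _profiled_ml(y, X, gidx, theta)[2] - 1e-8

    def test_matches_statsmodels_ml_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n_sites, per = 8, 25
        n = n_sites * per
        x = rng.standard_normal(n)
        groups = np.repeat(np.arange(n_sites), per)
        y = 1.5 * x + np.repeat(0.7 * rng.standard_normal(n_sites), per) + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_lmm(y, X, groups, ("(intercept)", "x"))
        oracle = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        assert np.allclose(fit.beta, np.asarray(oracle.fe_params), atol=1e-4)
        assert fit.sigma_b2 == pytest.approx(float(np.asarray(oracle.cov_re)[0, 0]), abs=1e-3)
        assert fit.loglik == pytest.approx(float(oracle.llf), abs=1e-6)

    def test_rank_deficiency_names_column(self, rng):
        n = 60
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="dup"):
            fit_lmm(rng.standard_normal(n), X, np.repeat([0, 1], 30),
                    ("(intercept)", "x", "dup"))

    def test_single_group_warns(self, rng, caplog):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        with caplog.at_level("WARNING", logger="marshcarbon"):
            fit_lmm(rng.standard_normal(n), X, np.zeros(n), ("(intercept)", "x"))
        assert "ordinary least squares" in caplog.text


class TestStandardize:
    def test_equals_pearson_correlation_for_simple_regression(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        data = pd.DataFrame({"x": x, "y": y, "g": np.repeat([0, 1], 100)})
        fit = fit_lmm(y, np.column_stack([np.ones(n), x]), data["g"],
                      ("(intercept)", "x"), response="y")
        std = standardize_paths(fit, data)
        r = sps.pearsonr(x, y).statistic
        assert std["x"] == pytest.approx(r, abs=0.02)

    def test_equal_sds_leave_beta_unchanged(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 1.0, 2.0, 3.0],
                             "g": [0, 0, 1, 1]})
        fit = fit_lmm(data["y"], np.column_stack([np.ones(4), data["x"]]), data["g"],
                      ("(intercept)", "x"), response="y")
        std = standardize_paths(fit, data)
        assert std["x"] == pytest.approx(fit.coef("x"))

    def test_zero_variance_predictor_rejected(self, rng):
        n = 40
        data = pd.DataFrame({"x": np.ones(n), "y": rng.standard_normal(n),
                             "g": np.repeat([0, 1], 20)})
        fit = fit_lmm(data["y"], data[["x"]].to_numpy(), data["g"], ("x",), response="y")
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_paths(fit, data)


def _brute_force_basis(dag: PathDAG):
    """Independent enumeration of Shipley claims for oracle comparison."""
    g = nx.DiGraph(dag.edges)
    g.add_nodes_from(dag.nodes)
    claims = set()
    for u, v in itertools.combinations(dag.nodes, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        # order so the second is not an ancestor of the first
        if u in nx.ancestors(g, v):
            x, y = u, v
        elif v in nx.ancestors(g, u):
            x, y = v, u
        else:
            x, y = u, v  # incomparable: either order valid; one claim per pair
        cond = frozenset(set(g.predecessors(x)) | set(g.predecessors(y)))
        claims.add((frozenset((x, y)), cond))
    return claims


class TestBasisSet:
    def test_chain(self):
        dag = PathDAG(("X", "Y", "Z"), (("X", "Y"), ("Y", "Z")))
        assert basis_set(dag) == [("X", "Z", ("Y",))]

    def test_collider(self):
        dag = PathDAG(("X", "Y", "Z"), (("X", "Z"), ("Y", "Z")))
        assert basis_set(dag) == [("X", "Y", ())]

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathDAG(("A", "B"), (("A", "B"), ("B", "A")))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        nodes = tuple("ABCDEFGH")
        edges = tuple(
            (nodes[i], nodes[j])
            for i in range(8)
            for j in range(i + 1, 8)
            if rng.random() < 0.3
        )
        dag = PathDAG(nodes, edges)
        got = {(frozenset((x, y)), frozenset(cond)) for x, y, cond in basis_set(dag)}
        assert got == _brute_force_basis(dag)


class TestFishersC:
    def test_all_ones(self):
        c, df, p = fishers_c([1.0, 1.0, 1.0])
        assert c == 0.0 and df == 6 and p == pytest.approx(1.0)

    def test_single_claim_identity(self):
        c, df, p = fishers_c([0.3])
        assert df == 2
        assert p == pytest.approx(0.3, abs=1e-12)  # exp(-C/2) with C = -2 ln 0.3

    def test_printed_statistic(self):
        assert sps.chi2.sf(125.794, 124) == pytest.approx(0.438, abs=5e-4)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])

    def test_permutation_invariance_and_monotonicity(self):
        ps = [0.1, 0.4, 0.9]
        assert fishers_c(ps)[0] == pytest.approx(fishers_c(ps[::-1])[0])
        c_hi = fishers_c([0.05, 0.4, 0.9])[0]
        assert c_hi > fishers_c(ps)[0]


class TestR2Nakagawa:
    def test_perfect_fit_limit(self):
        fit = pathsem.LmmFit("y", ("x",), (1.0,), (0.1,), (0.0,), 0.0, 0.0, 0.0,
                             10, 2, fitted_fixed=tuple(np.arange(10.0)))
        assert r2_nakagawa(fit) == (1.0, 1.0)

    def test_intercept_only_gives_icc(self):
        fit = pathsem.LmmFit("y", ("(intercept)",), (0.5,), (0.1,), (0.0,), 0.3, 0.7,
                             0.0, 10, 2, fitted_fixed=(0.5,) * 10)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == 0.0
        assert r2c == pytest.approx(0.3 / (0.3 + 0.7))

    def test_hand_formula_on_synthetic_fit(self, rng):
        n = 400
        x = rng.standard_normal(n)
        groups = np.repeat(np.arange(10), 40)
        y = x + np.repeat(rng.standard_normal(10), 40) + rng.standard_normal(n)
        fit = fit_lmm(y, np.column_stack([np.ones(n), x]), groups, ("(intercept)", "x"))
        var_f = np.var(fit.fitted_fixed, ddof=1)
        expected_m = var_f / (var_f + fit.sigma_b2 + fit.sigma_e2)
        assert r2_nakagawa(fit)[0] == pytest.approx(expected_m)

    def test_all_zero_variance_undefined(self):
        fit = pathsem.LmmFit("y", ("x",), (0.0,), (0.1,), (1.0,), 0.0, 0.0, 0.0,
                             10, 2, fitted_fixed=(0.0,) * 10)
        with pytest.raises(ValueError):
            r2_nakagawa(fit)


class TestSimplifyAndFit:
    DAG = synthdata.DEFAULT_METAMODEL
    COEFS = synthdata.DEFAULT_PATH_COEFFICIENTS

    def test_structure_and_coefficient_recovery(self):
        data, truth = synthdata.gen_sem_dataset(2024, self.DAG, self.COEFS,
                                                n_sites=10, plots_per_site=30)
        res = simplify_and_fit_sem(self.DAG, data)
        assert sorted(res.dag.edges) == sorted(self.DAG.edges)
        assert res.dsep_ok
        for edge, beta in self.COEFS.items():
            fit = res.fits[edge[1]]
            i = fit.names.index(edge[0])
            assert abs(fit.beta[i] - beta) < 3 * fit.se[i]

    def test_pure_noise_removes_all_paths(self):
        zero = {e: 0.0 for e in self.DAG.edges}
        data, _ = synthdata.gen_sem_dataset(3, self.DAG, zero, site_intercept_sd=0.0,
                                            n_sites=10, plots_per_site=30)
        res = simplify_and_fit_sem(self.DAG, data)
        assert res.dag.edges == ()
        assert res.dsep_ok

    def test_forced_keep_retains_path(self):
        zero = {e: 0.0 for e in self.DAG.edges}
        data, _ = synthdata.gen_sem_dataset(7, self.DAG, zero, site_intercept_sd=0.0,
                                            n_sites=10, plots_per_site=30)
        keep = (("grain_size", "belowground_oc_stock"),)
        res = simplify_and_fit_sem(self.DAG, data, keep=keep)
        assert ("grain_size", "belowground_oc_stock") in res.dag.edges

    def test_transforms_applied(self):
        data = pd.DataFrame(
            {
                "site_id": np.repeat(["a", "b", "c", "d"], 25),
                "x": np.random.default_rng(0).uniform(1, 2, 100),
            }
        )
        data["belowground_oc_stock"] = 10 ** (0.8 * data["x"])
        dag = PathDAG(("x", "belowground_oc_stock"), (("x", "belowground_oc_stock"),))
        res = simplify_and_fit_sem(dag, data, transforms=pathsem.DEFAULT_TRANSFORMS)
        fit = res.fits["belowground_oc_stock"]
        assert fit.coef("x") == pytest.approx(0.8, abs=1e-6)  # exact after log10


def test_read_dag(tmp_path):
    p = tmp_path / "meta.dag"
    p.write_text("# metamodel\na -> b\nb -> c\nisolated\n")
    dag = pathsem.read_dag(p)
    assert set(dag.nodes) == {"a", "b", "c", "isolated"}
    assert dag.edges == (("a", "b"), ("b", "c"))
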