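import numpy as np
import pytest

from cattlegp.benchmarks import (
    bayesb_quadrature_check,
    enet_kkt_violation,
    gblup_ridge_equivalence,
    gbm_stump_check,
)
from cattlegp.predictors import (
    GBLUP,
    BayesB,
    ElasticNetSearch,
    GBMSearch,
    StackingEnsemble,
)


def _geno(n, m, seed=0):
    return np.random.default_rng(seed).integers(0, 3, size=(n, m)).astype(float)


# ----------------------------------------------------------------------
# GBLUP
# ----------------------------------------------------------------------
def test_gblup_no_signal_predicts_training_mean():
    X = _geno(30, 20)
    y = np.random.default_rng(1).standard_normal(30)
    m = GBLUP(variance_ratio=1e-12).fit(X, y)
    pred = m.predict(_geno(5, 20, seed=2))
    assert np.allclose(pred, pred[0])
    assert pred[0] == pytest.approx(m.mu_)


def test_gblup_equivalent_to_matched_ridge():
    assert gblup_ridge_equivalence(seed=3, n_fixtures=10) >= 1 - 1e-8


def test_gblup_duplicate_validation_individual_gets_fitted_value():
    X = _geno(40, 30, seed=4)
    y = np.random.default_rng(5).standard_normal(40)
    m = GBLUP(variance_ratio=1.0).fit(X, y)
    pred = m.predict(X[:3])
    assert np.allclose(pred, m.fitted_values_[:3], atol=1e-8)


def test_gblup_learns_additive_signal():
    rng = np.random.default_rng(6)
    X = _geno(300, 100, seed=6)
    beta = rng.standard_normal(100) * 0.2
    g = (X - X.mean(0)) @ beta
    y = g + rng.standard_normal(300) * 0.3 * g.std()
    m = GBLUP().fit(X[:250], y[:250])
    r = np.corrcoef(m.predict(X[250:]), y[250:])[0, 1]
    assert r > 0.7


# ----------------------------------------------------------------------
# BayesB
# ----------------------------------------------------------------------
def test_bayesb_retention_arithmetic():
    assert BayesB(n_iter=200_000, burn_in=50_000, thin=10).n_retained == 15_000


def test_bayesb_pi_one_gives_intercept_only_model():
    X = _geno(25, 10)
    y = np.random.default_rng(2).standard_normal(25)
    with pytest.warns(UserWarning, match="pi = 1"):
        m = BayesB(pi=1.0, n_iter=100, burn_in=10).fit(X, y)
    pred = m.predict(X)
    assert np.allclose(pred, np.mean(y))


def test_bayesb_single_marker_matches_quadrature():
    res = bayesb_quadrature_check(seed=11)
    assert res["abs_diff_in_mcse"] <= 3.0


def test_bayesb_finds_sparse_signal():
    rng = np.random.default_rng(7)
    X = _geno(200, 60, seed=7)
    y = 1.5 * (X[:, 5] - X[:, 5].mean()) + rng.standard_normal(200) * 0.5
    m = BayesB(pi=0.9, n_iter=1_500, burn_in=300, thin=3, seed=1).fit(X, y)
    assert m.inclusion_prob_[5] > 0.9
    assert np.argmax(np.abs(m.beta_mean_)) == 5


# ----------------------------------------------------------------------
# Elastic net
# ----------------------------------------------------------------------
def test_enet_lambda_zero_matches_ols():
    rng = np.random.default_rng(8)
    X = _geno(20, 3, seed=8)
    y = rng.standard_normal(20)
    m = ElasticNetSearch(alpha_grid=(0.5,), lambda_grid=(0.0,), n_splits=3).fit(X, y)
    Xc = X - X.mean(0)
    beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    assert np.allclose(m.coef_, beta_ols, atol=1e-6)


def test_enet_pure_ridge_matches_closed_form():
    rng = np.random.default_rng(9)
    X = _geno(30, 5, seed=9)
    y = rng.standard_normal(30)
    lam = 1.0
    m = ElasticNetSearch(
        alpha_grid=(0.0,), lambda_grid=(lam,), max_iter=200_000, tol=1e-14
    ).fit(X, y)
    Xc = X - X.mean(0)
    n = len(y)
    # loss (1/2n)||yc - Xc b||^2 + lam ||b||^2  ->  (Xc'Xc + 2 n lam I) b = Xc'yc
    beta = np.linalg.solve(Xc.T @ Xc + 2 * n * lam * np.eye(5), Xc.T @ (y - y.mean()))
    assert np.allclose(m.coef_, beta, atol=1e-6)


def test_enet_full_shrinkage_gives_intercept_only():
    X = _geno(25, 8, seed=10)
    y = np.random.default_rng(10).standard_normal(25)
    m = ElasticNetSearch(alpha_grid=(1.0,), lambda_grid=(1e6,)).fit(X, y)
    assert np.all(m.coef_ == 0.0)
    assert np.allclose(m.predict(X), y.mean())


def test_enet_satisfies_kkt_conditions():
    assert enet_kkt_violation(seed=12, n_fixtures=5) <= 1e-6


def test_enet_grid_validation():
    X = _geno(20, 4)
    y = np.zeros(20) + np.random.default_rng(0).standard_normal(20)
    with pytest.raises(ValueError):
        ElasticNetSearch(alpha_grid=(1.5,), lambda_grid=(0.1,)).fit(X, y)
    with pytest.raises(ValueError):
        ElasticNetSearch(lambda_grid=(-0.1,)).fit(X, y)


# ----------------------------------------------------------------------
# GBM
# ----------------------------------------------------------------------
def test_gbm_printed_default_grids():
    m = GBMSearch()
    assert m.ntree_grid == (100, 200, 300, 500, 750, 1000, 1250, 1500, 2000, 2500, 3000)
    assert m.learning_rate_grid[0] == 0.01 and m.learning_rate_grid[-1] == 1.0
    assert np.allclose(np.diff(m.learning_rate_grid[:-1]), 0.05)
    assert m.max_depth_grid == tuple(range(0, 51, 5))
    assert m.node_size_grid == (5, 20, 35, 50)


def test_gbm_single_stump_matches_bruteforce_split():
    assert gbm_stump_check(seed=0) == 0.0


def test_gbm_zero_trees_predicts_training_mean():
    X = _geno(30, 6, seed=13)
    y = np.random.default_rng(13).standard_normal(30)
    m = GBMSearch(ntree_grid=(0,), learning_rate_grid=(0.1,), max_depth_grid=(1,),
                  node_size_grid=(5,), n_draws=1, n_splits=2).fit(X, y)
    assert np.allclose(m.predict(X), y.mean())
    assert np.all(m.relative_influence_ == 0.0)


def test_gbm_relative_influence_sums_to_100():
    rng = np.random.default_rng(14)
    X = _geno(120, 25, seed=14)
    y = (X[:, 3] - 1.0) + 0.1 * rng.standard_normal(120)
    m = GBMSearch(ntree_grid=(50,), learning_rate_grid=(0.2,), max_depth_grid=(2,),
                  node_size_grid=(5,), n_draws=1, n_splits=2).fit(X, y)
    assert m.relative_influence_.sum() == pytest.approx(100.0, abs=1e-6)
    assert np.argmax(m.relative_influence_) == 3


def test_gbm_empty_training_rejected():
    with pytest.raises(ValueError):
        GBMSearch(n_draws=1).fit(np.empty((0, 3)), np.empty(0))


# ----------------------------------------------------------------------
# Stacking
# ----------------------------------------------------------------------
class _FixedPredictor:
    """Test double: ignores X, returns preset values by row index."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self._offset = 0

    def get_params(self, deep=True):
        return {"values": self.values}

    def set_params(self, **kw):
        return self

    def fit(self, X, y):
        return self

    def predict(self, X):
        # the single feature carries the row index, so out-of-fold
        # subsets receive their own preset values
        return self.values[np.asarray(X[:, 0], dtype=int)]


def test_stack_identical_bases_reproduce_common_prediction():
    rng = np.random.default_rng(15)
    X = _geno(60, 10, seed=15)
    y = (X[:, 0] - 1.0) + 0.2 * rng.standard_normal(60)
    m = StackingEnsemble(
        base_estimators={"a": GBLUP(variance_ratio=1.0), "b": GBLUP(variance_ratio=1.0)},
        n_splits=3, seed=0,
    ).fit(X, y)
    common = GBLUP(variance_ratio=1.0).fit(X, y).predict(X)
    diff = m.predict(X) - common
    # equal up to a small intercept re-centering from the OOF means
    assert np.ptp(diff) < 1e-8
    assert abs(diff.mean()) < 0.05
    assert np.all(m.weights_ >= 0)
    assert m.weights_.sum() == pytest.approx(1.0)


def test_stack_downweights_noise_learner():
    kept = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 120
        truth = rng.standard_normal(n)
        y = truth + 0.05 * rng.standard_normal(n)
        perfect = _FixedPredictor(truth)
        noise = _FixedPredictor(rng.standard_normal(n))
        X = np.arange(n, dtype=float)[:, None]
        m = StackingEnsemble(
            base_estimators={"perfect": perfect, "noise": noise}, n_splits=4, seed=seed
        ).fit(X, y)
        w = m.weights_ / max(m.weights_.sum(), 1e-12)
        pred = m.predict(X)
        r_stack = np.corrcoef(pred, y)[0, 1]
        r_perfect = np.corrcoef(truth, y)[0, 1]
        kept.append((w[1], r_stack / r_perfect))
    w_noise = np.mean([k[0] for k in kept])
    ratio = np.mean([k[1] for k in kept])
    assert w_noise <= 0.1
    assert ratio >= 0.95


def test_stack_weights_nonnegative_and_failure_propagates():
    class _Boom:
        def get_params(self, deep=True):
            return {}

        def set_params(self, **kw):
            return self

        def fit(self, X, y):
            raise RuntimeError("synthetic failure")

    X = _geno(30, 5, seed=16)
    y = np.random.default_rng(16).standard_normal(30)
    with pytest.raises(RuntimeError, match="bad_learner"):
        StackingEnsemble(base_estimators={"bad_learner": _Boom()}, n_splits=3).fit(X, y)
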