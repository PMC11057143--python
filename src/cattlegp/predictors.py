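"""Whole-genome prediction models.

Five predictors trained on adjusted phenotypes ``y*`` with marker
dosages as features:

* :class:`GBLUP` — mixed model with genomic kernel G (VanRaden),
  validation individuals predicted by the conditional expectation
  ``G_vt G_tt^{-1} g_hat``;
* :class:`BayesB` — Gibbs sampler with a point-mass/scaled-t mixture
  prior on marker effects;
* :class:`ElasticNetSearch` — elastic-net loss
  ``(1/2N) sum (y_i - b0 - x_i'b)^2 + lambda((1-alpha)||b||_2^2 +
  alpha ||b||_1)`` with an inner 5-fold grid search over (alpha, lambda);
* :class:`GBMSearch` — gradient tree boosting with a random
  hyperparameter search (inner 5-fold CV by MSE) and per-marker
  relative influence on a percentage scale;
* :class:`StackingEnsemble` — non-negative linear meta-learner over
  out-of-fold ENET and GBM predictions.

All estimators follow the scikit-learn fit/predict contract; marker
centering statistics are computed on the training data and reused at
prediction time, so no validation-side information enters training.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold, ParameterSampler
from sklearn.utils.validation import check_array, check_X_y

__all__ = [
    "GBLUP",
    "BayesB",
    "ElasticNetSearch",
    "GBMSearch",
    "StackingEnsemble",
    "DEFAULT_MODELS",
]


# ----------------------------------------------------------------------
# GBLUP
# ----------------------------------------------------------------------
class GBLUP(RegressorMixin, BaseEstimator):
    """Genomic BLUP: y* = 1 mu + Z g + e with g ~ N(0, G sigma2_g).

    ``variance_ratio`` is gamma = sigma2_g / sigma2_e; when None it is
    estimated on the training data by maximising the marginal (REML-type)
    likelihood over the eigenvalues of the training kernel.
    """

    def __init__(self, variance_ratio: float | None = None, jitter_rtol: float = 1e-8):
        self.variance_ratio = variance_ratio
        self.jitter_rtol = jitter_rtol

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n = X.shape[0]
        p = X.mean(axis=0) / 2.0
        self.freq_ = p
        self.denom_ = 2.0 * np.sum(p * (1.0 - p))
        if self.denom_ <= 0:
            raise ValueError("all training markers monomorphic")
        M = X - 2.0 * p
        self.M_train_ = M
        G = M @ M.T / self.denom_

        lam, U = np.linalg.eigh(G)
        lam = np.maximum(lam, 0.0)
        yt = U.T @ y
        ones_t = U.T @ np.ones(n)

        if self.variance_ratio is None:
            gamma = _profile_ml_ratio(lam, yt, ones_t)
        else:
            gamma = float(self.variance_ratio)
        self.gamma_ = gamma

        d = gamma * lam + 1.0
        mu = (ones_t / d) @ yt / ((ones_t / d) @ ones_t)
        self.mu_ = float(mu)
        if gamma <= 0:
            self.w_ = np.zeros(n)
            self.fitted_values_ = np.full(n, self.mu_)
            return self
        # w = (G + I/gamma)^{-1} (y - mu), via the spectral factors
        lam_solve = lam + 1.0 / gamma
        if lam_solve.min() <= self.jitter_rtol * max(np.trace(G) / n, 1.0):
            lam_solve = lam_solve + self.jitter_rtol * np.trace(G) / n
        self.w_ = U @ ((yt - mu * ones_t) / lam_solve)
        self.fitted_values_ = G @ self.w_ + self.mu_
        return self

    def predict(self, X):
        X = check_array(X)
        Mv = X - 2.0 * self.freq_
        G_vt = Mv @ self.M_train_.T / self.denom_
        return G_vt @ self.w_ + self.mu_


def _profile_ml_ratio(lam: np.ndarray, yt: np.ndarray, ones_t: np.ndarray) -> float:
    """Maximise the profiled Gaussian log-likelihood over gamma >= 0."""
    n = len(yt)

    def negll(log_gamma: float) -> float:
        g = np.exp(log_gamma)
        d = g * lam + 1.0
        w1 = ones_t / d
        mu = (w1 @ yt) / (w1 @ ones_t)
        resid = yt - mu * ones_t
        quad = np.sum(resid * resid / d)
        return float(np.sum(np.log(d)) + n * np.log(quad / n))

    res = optimize.minimize_scalar(negll, bounds=(-10.0, 10.0), method="bounded")
    gamma = float(np.exp(res.x))
    # no-signal guard: compare against the boundary gamma -> 0
    ss0 = max(np.sum(yt * yt) - (ones_t @ yt) ** 2 / n, 1e-300)
    d0 = n * np.log(ss0 / n)
    return 0.0 if d0 < res.fun - 1e-9 else gamma


# ----------------------------------------------------------------------
# BayesB
# ----------------------------------------------------------------------
class BayesB(RegressorMixin, BaseEstimator):
    """BayesB: mixture prior pi * (u_w = 0) + (1 - pi) * t(u_w | df, S_B).

    The scaled-t slab is represented hierarchically: u_w | s2_w ~
    N(0, s2_w) with s2_w ~ scaled-inv-chi2(df, S_B).  ``scale=None``
    solves S_B so the slab explains half of var(y*) a priori:
    (1 - pi) * E[u^2] * 2 sum p(1-p) = var(y*) / 2.
    """

    def __init__(
        self,
        pi: float = 0.95,
        df: float = 5.0,
        scale: float | None = None,
        n_iter: int = 200_000,
        burn_in: int = 50_000,
        thin: int = 10,
        fit_intercept: bool = True,
        resid_var: float | None = None,
        store_chain: bool = False,
        seed: int = 0,
    ):
        self.pi = pi
        self.df = df
        self.scale = scale
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.fit_intercept = fit_intercept
        self.resid_var = resid_var
        self.store_chain = store_chain
        self.seed = seed

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if not (0.0 <= self.pi <= 1.0):
            raise ValueError("pi must be in [0, 1]")
        n, m = X.shape
        rng = np.random.default_rng(self.seed)
        self.center_ = X.mean(axis=0)
        Xc = np.asfortranarray(X - self.center_)
        xtx = np.einsum("ij,ij->j", Xc, Xc)

        vary = float(np.var(y))
        if self.scale is None:
            p = self.center_ / 2.0
            sum2pq = max(2.0 * np.sum(p * (1.0 - p)), 1e-12)
            e_u2 = self.df / max(self.df - 2.0, 1e-6)  # E[u^2]/S_B for the t slab
            S_B = 0.5 * vary / (max(1.0 - self.pi, 1e-12) * e_u2 * sum2pq)
        else:
            S_B = float(self.scale)
        self.scale_used_ = S_B

        if self.pi >= 1.0:
            warnings.warn("pi = 1: all marker effects are null; intercept-only model")
            self.beta_mean_ = np.zeros(m)
            self.mu_mean_ = float(np.mean(y)) if self.fit_intercept else 0.0
            self.inclusion_prob_ = np.zeros(m)
            return self

        nu_e = self.df
        S_e = 0.5 * vary * (nu_e + 2.0) / nu_e
        mu = float(np.mean(y)) if self.fit_intercept else 0.0
        beta = np.zeros(m)
        s2w = np.full(m, S_B * self.df / (self.df + 2.0))
        sig2e = self.resid_var if self.resid_var is not None else 0.5 * vary
        r = y - mu

        log_odds_prior = np.log(self.pi) - np.log1p(-self.pi)
        beta_sum = np.zeros(m)
        incl_sum = np.zeros(m)
        mu_sum = 0.0
        sig2e_samples = []
        beta_samples = [] if self.store_chain else None
        kept = 0
        cols = [np.ascontiguousarray(Xc[:, w]) for w in range(m)]

        for it in range(self.n_iter):
            if self.fit_intercept:
                rmu = r + mu
                mu = rmu.mean() + np.sqrt(sig2e / n) * rng.standard_normal()
                r = rmu - mu
            for w in range(m):
                xw = cols[w]
                bw = beta[w]
                rhs = xw @ r + xtx[w] * bw
                c = xtx[w] / sig2e + 1.0 / s2w[w]
                mean_b = rhs / (sig2e * c)
                log_bf = 0.5 * (-np.log(s2w[w] * c) + mean_b * mean_b * c)
                p_incl = 1.0 / (1.0 + np.exp(np.clip(log_odds_prior - log_bf, -700, 700)))
                if rng.random() < p_incl:
                    b_new = mean_b + rng.standard_normal() / np.sqrt(c)
                    s2w[w] = (self.df * S_B + b_new * b_new) / rng.chisquare(self.df + 1.0)
                else:
                    b_new = 0.0
                    s2w[w] = self.df * S_B / rng.chisquare(self.df)
                if b_new != bw:
                    r += xw * (bw - b_new)
                    beta[w] = b_new
            if self.resid_var is None:
                sig2e = (r @ r + nu_e * S_e) / rng.chisquare(n + nu_e)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                beta_sum += beta
                incl_sum += beta != 0.0
                mu_sum += mu
                sig2e_samples.append(sig2e)
                if beta_samples is not None:
                    beta_samples.append(beta.copy())
                kept += 1

        kept = max(kept, 1)
        self.beta_mean_ = beta_sum / kept
        self.mu_mean_ = mu_sum / kept if self.fit_intercept else 0.0
        self.inclusion_prob_ = incl_sum / kept
        self.sig2e_samples_ = np.asarray(sig2e_samples)
        if beta_samples is not None:
            self.beta_samples_ = np.asarray(beta_samples)
        self.n_retained_ = kept
        return self

    def predict(self, X):
        X = check_array(X)
        return (X - self.center_) @ self.beta_mean_ + self.mu_mean_


# ----------------------------------------------------------------------
# Elastic net with inner-CV grid search
# ----------------------------------------------------------------------
class ElasticNetSearch(RegressorMixin, BaseEstimator):
    """Elastic net on the loss
    (1/2N)||y - b0 - Xb||^2 + lambda((1-alpha)||b||_2^2 + alpha||b||_1).

    ``alpha_grid`` defaults to 0.0 ... 1.0 step 0.1.  ``lambda_grid``
    is either "auto" (50 log-spaced values from lambda_max down to
    lambda_max * 1e-4, lambda_max the smallest lambda zeroing all
    coefficients at alpha = 1) or "unit" (0.0 ... 1.0 step 0.1) or an
    explicit array.  The winner maximises inner-CV Pearson accuracy,
    ties broken by lower MSE, then smaller lambda, then smaller alpha.
    """

    def __init__(
        self,
        alpha_grid=None,
        lambda_grid="auto",
        n_lambda: int = 50,
        n_splits: int = 5,
        max_iter: int = 5_000,
        tol: float = 1e-4,
        seed: int = 0,
    ):
        self.alpha_grid = alpha_grid
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.n_splits = n_splits
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # sklearn's penalty is a*l1*||b||_1 + (a/2)(1-l1)||b||_2^2; matching
    # coefficients gives a = lambda*(2-alpha), l1 = alpha/(2-alpha)
    @staticmethod
    def _to_sklearn(lam: float, alpha: float) -> tuple[float, float]:
        a = lam * (2.0 - alpha)
        l1 = alpha / (2.0 - alpha) if a > 0 else 0.0
        return a, l1

    def _grids(self, Xc, yc):
        alphas = (
            np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
            if self.alpha_grid is None
            else np.asarray(self.alpha_grid, dtype=float)
        )
        if isinstance(self.lambda_grid, str) and self.lambda_grid == "auto":
            lam_max = np.max(np.abs(Xc.T @ yc)) / len(yc)
            lam_max = max(lam_max, 1e-12)
            lams = np.geomspace(lam_max, lam_max * 1e-4, self.n_lambda)
        elif isinstance(self.lambda_grid, str) and self.lambda_grid == "unit":
            lams = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
        else:
            lams = np.asarray(self.lambda_grid, dtype=float)
        if np.any(lams < 0) or np.any((alphas < 0) | (alphas > 1)):
            raise ValueError("alpha must be in [0,1] and lambda >= 0")
        return alphas, np.sort(lams)[::-1]  # descending for warm-started paths

    def _solve(self, Xc, yc, lam, alpha):
        """Coefficients for one (lambda, alpha) on centered data."""
        if lam == 0.0:
            return np.linalg.lstsq(Xc, yc, rcond=None)[0]
        a, l1 = self._to_sklearn(lam, alpha)
        _, coefs, _ = enet_path(
            Xc, yc, l1_ratio=l1, alphas=[a], max_iter=self.max_iter, tol=self.tol
        )
        return coefs[:, 0]

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.center_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xc, yc = X - self.center_, y - self.y_mean_
        alphas, lams = self._grids(Xc, yc)

        kf = KFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        splits = list(kf.split(Xc))
        acc = np.zeros((len(alphas), len(lams)))
        mse = np.zeros((len(alphas), len(lams)))
        for tr, va in splits:
            xm = Xc[tr].mean(axis=0)
            ym = yc[tr].mean()
            xtr, ytr = Xc[tr] - xm, yc[tr] - ym
            xva = Xc[va] - xm
            for ia, alpha in enumerate(alphas):
                pred = self._path_predict(xtr, ytr, xva, lams, alpha) + ym
                obs = yc[va]
                for il in range(len(lams)):
                    p = pred[:, il]
                    if np.std(p) > 0 and np.std(obs) > 0:
                        acc[ia, il] += np.corrcoef(obs, p)[0, 1]
                    mse[ia, il] += np.mean((obs - p) ** 2)
        acc /= len(splits)
        mse /= len(splits)

        # winner: max accuracy -> min MSE -> smaller lambda -> smaller alpha
        order = []
        for ia, alpha in enumerate(alphas):
            for il, lam in enumerate(lams):
                order.append((-acc[ia, il], mse[ia, il], lam, alpha, ia, il))
        order.sort()
        _, _, lam_best, alpha_best, ia, il = order[0]
        self.best_alpha_, self.best_lambda_ = float(alpha_best), float(lam_best)
        self.cv_accuracy_, self.cv_mse_ = acc, mse
        self.alpha_grid_, self.lambda_grid_ = alphas, lams

        self.coef_ = self._solve(Xc, yc, self.best_lambda_, self.best_alpha_)
        self.intercept_ = self.y_mean_ - 0.0  # Xc already centered
        return self

    def _path_predict(self, xtr, ytr, xva, lams, alpha):
        nz = lams > 0
        preds = np.empty((xva.shape[0], len(lams)))
        if nz.any():
            a_list = lams[nz] * (2.0 - alpha)
            l1 = alpha / (2.0 - alpha)
            _, coefs, _ = enet_path(
                xtr, ytr, l1_ratio=l1, alphas=a_list, max_iter=self.max_iter, tol=self.tol
            )
            preds[:, nz] = xva @ coefs
        if (~nz).any():
            b = np.linalg.lstsq(xtr, ytr, rcond=None)[0]
            preds[:, ~nz] = np.repeat((xva @ b)[:, None], (~nz).sum(), axis=1)
        return preds

    def predict(self, X):
        X = check_array(X)
        return (X - self.center_) @ self.coef_ + self.intercept_


# ----------------------------------------------------------------------
# Gradient boosting with random hyperparameter search
# ----------------------------------------------------------------------
class _ConstantMean:
    """Degenerate boosting model with zero trees: predicts the mean."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        self.feature_importances_ = np.zeros(X.shape[1])
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.mean_)


NTREE_GRID = (100, 200, 300, 500, 750, 1000, 1250, 1500, 2000, 2500, 3000)
LEARNING_RATE_GRID = tuple(np.round(np.arange(0.01, 0.97, 0.05), 2)) + (1.0,)
MAX_DEPTH_GRID = tuple(range(0, 51, 5))  # 0 means "no depth limit"
NODE_SIZE_GRID = (5, 20, 35, 50)


class GBMSearch(RegressorMixin, BaseEstimator):
    """Gradient tree boosting (squared-error loss) with random search.

    Hyperparameters are drawn from the grids (number of trees, learning
    rate, max depth with 0 = unlimited, minimum observations per leaf)
    and scored by inner K-fold CV mean squared error.  After refitting
    the winner, ``relative_influence_`` holds each marker's share of the
    total squared-error reduction over all splits, on a percentage scale
    (sums to 100).
    """

    def __init__(
        self,
        ntree_grid=NTREE_GRID,
        learning_rate_grid=LEARNING_RATE_GRID,
        max_depth_grid=MAX_DEPTH_GRID,
        node_size_grid=NODE_SIZE_GRID,
        n_draws: int = 36,
        n_splits: int = 5,
        seed: int = 0,
    ):
        self.ntree_grid = ntree_grid
        self.learning_rate_grid = learning_rate_grid
        self.max_depth_grid = max_depth_grid
        self.node_size_grid = node_size_grid
        self.n_draws = n_draws
        self.n_splits = n_splits
        self.seed = seed

    def _make(self, params):
        if params["n_estimators"] == 0:
            return _ConstantMean()  # zero boosting steps: training-mean model
        depth = params["max_depth"]
        return GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=params["n_estimators"],
            learning_rate=params["learning_rate"],
            max_depth=None if depth == 0 else depth,
            min_samples_leaf=params["min_samples_leaf"],
            random_state=self.seed,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if len(y) == 0:
            raise ValueError("empty training set")
        grid = {
            "n_estimators": list(self.ntree_grid),
            "learning_rate": list(self.learning_rate_grid),
            "max_depth": list(self.max_depth_grid),
            "min_samples_leaf": list(self.node_size_grid),
        }
        n_total = int(np.prod([len(v) for v in grid.values()]))
        sampler = ParameterSampler(
            grid, n_iter=min(self.n_draws, n_total), random_state=self.seed
        )
        kf = KFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        splits = list(kf.split(X))
        results = []
        for k, params in enumerate(sampler):
            cv_mse = 0.0
            for tr, va in splits:
                est = self._make(params)
                est.fit(X[tr], y[tr])
                cv_mse += np.mean((y[va] - est.predict(X[va])) ** 2)
            results.append((cv_mse / len(splits), k, params))
        results.sort(key=lambda t: (t[0], t[1]))
        self.cv_results_ = results
        self.best_params_ = results[0][2]
        self.model_ = self._make(self.best_params_).fit(X, y)
        imp = self.model_.feature_importances_
        tot = imp.sum()
        self.relative_influence_ = 100.0 * imp / tot if tot > 0 else imp * 0.0
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = check_array(X)
        return self.model_.predict(X)


# ----------------------------------------------------------------------
# Stacking ensemble
# ----------------------------------------------------------------------
class StackingEnsemble(RegressorMixin, BaseEstimator):
    """Stacked prediction f_stack(x) = b0 + sum_i w_i f_i(x), w_i >= 0.

    Base learners (default: elastic net and GBM) are trained on the
    K-fold out-of-fold scheme so the meta-learner sees predictions for
    every training individual that its own base model never saw; the
    meta-weights come from non-negative least squares with intercept.
    """

    def __init__(self, base_estimators=None, n_splits: int = 5, seed: int = 0):
        self.base_estimators = base_estimators
        self.n_splits = n_splits
        self.seed = seed

    def _bases(self):
        if self.base_estimators is not None:
            return list(self.base_estimators.items())
        return [
            ("enet", ElasticNetSearch(seed=self.seed)),
            ("gbm", GBMSearch(seed=self.seed)),
        ]

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        bases = self._bases()
        kf = KFold(n_splits=self.n_splits, shuffle=True, random_state=self.seed)
        oof = np.zeros((len(y), len(bases)))
        for tr, va in kf.split(X):
            for j, (name, est) in enumerate(bases):
                try:
                    model = clone(est).fit(X[tr], y[tr])
                except Exception as err:  # propagate with learner identity
                    raise RuntimeError(f"base learner {name!r} failed: {err}") from err
                oof[va, j] = model.predict(X[va])

        fm = oof.mean(axis=0)
        ym = y.mean()
        w, _ = optimize.nnls(oof - fm, y - ym)
        # weights live on the simplex: a pair of identical base learners
        # then reproduces their common prediction instead of shrinking it
        if w.sum() > 0:
            w = w / w.sum()
        self.weights_ = w
        self.intercept_ = float(ym - fm @ w)
        self.base_names_ = [name for name, _ in bases]
        self.oof_predictions_ = oof
        self.models_ = []
        for name, est in bases:
            try:
                self.models_.append(clone(est).fit(X, y))
            except Exception as err:
                raise RuntimeError(f"base learner {name!r} failed: {err}") from err
        return self

    def predict(self, X):
        X = check_array(X)
        F = np.column_stack([m.predict(X) for m in self.models_])
        return F @ self.weights_ + self.intercept_


def DEFAULT_MODELS(seed: int = 0) -> dict:
    """The five benchmark predictors with production defaults."""
    return {
        "GBLUP": GBLUP(),
        "BayesB": BayesB(seed=seed),
        "ENET": ElasticNetSearch(seed=seed),
        "GBM": GBMSearch(seed=seed),
        "Stack": StackingEnsemble(seed=seed),
    }
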