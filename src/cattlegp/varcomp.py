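"""Bayesian animal model: Gibbs variance components and phenotype adjustment.

The model for one trait is

    y = Xb + Wh + Za + [Zd + Zep_aa] + e

with fixed effects ``b`` (days-in-milk class, parity class, optional PC
covariates; flat prior), i.i.d. batch effects ``h`` ~ N(0, I s2_batch),
correlated genetic effects a ~ N(0, G s2_a) and optionally
d ~ N(0, D s2_d), ep ~ N(0, GG s2_ep), and residual e ~ N(0, I s2_e).
``Z`` is the identity (one record per animal).  Variances carry scaled
inverse chi-square priors.

Correlated effects are sampled in the eigenbasis of their kernel: with
K = U diag(lam) U' and a = U s, the full conditional of ``s`` given the
residual is diagonal, so each sweep costs two n x n matrix-vector
products per kernel.  One spectral decomposition per kernel is done up
front and reused for the whole chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .kinship import RelationshipMatrix

__all__ = [
    "GibbsConfig",
    "GibbsAnimalModel",
    "VarianceComponents",
    "summarize_ratios",
    "geweke_test",
    "adjust_phenotypes",
]


@dataclass
class GibbsConfig:
    """Chain settings; defaults are the full-length production chain."""

    n_iter: int = 500_000
    burn_in: int = 50_000
    thin: int = 10
    prior_df: float = 5.0
    seed: int = 0
    # eigenbasis rotations run in float32 by default (the sampled effects
    # and variances stay float64); the residual is refreshed in float64
    # every `refresh_every` sweeps so rounding cannot accumulate
    rotation_dtype: str = "float32"
    refresh_every: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class VarianceComponents:
    """Posterior summaries of variances and their phenotypic fractions."""

    means: dict
    sds: dict
    ratio_means: dict
    ratio_sds: dict
    include_batch: bool

    def __getitem__(self, key):
        if key in self.ratio_means:
            return self.ratio_means[key]
        return self.means[key]


def build_fixed_design(traits: pd.DataFrame, pcs: np.ndarray | None = None) -> np.ndarray:
    """Intercept + dummy-coded DIM and parity (first level dropped) + PCs."""
    n = len(traits)
    cols = [np.ones(n)]
    for f in ("dim_class", "parity_class"):
        levels = np.sort(traits[f].unique())
        for lev in levels[1:]:  # reference level absorbed in intercept
            cols.append((traits[f].to_numpy() == lev).astype(float))
    X = np.column_stack(cols)
    if pcs is not None:
        X = np.column_stack([X, np.asarray(pcs, dtype=float)])
    return X


def batch_design(traits: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return integer batch index per record and the batch level order."""
    levels, idx = np.unique(traits["batch"].to_numpy(), return_inverse=True)
    return idx, levels


class GibbsAnimalModel(BaseEstimator):
    """Gibbs sampler for the animal model.

    Parameters
    ----------
    config : GibbsConfig
    include_batch : bool
        Include the batch variance in ratio denominators (the default
        treats batch variance as part of phenotypic variance).

    After :meth:`fit`, the retained chain is in ``chain_`` (DataFrame,
    one row per retained sample), posterior-mean solutions in
    ``b_mean_``, ``h_mean_`` and ``effects_mean_``.
    """

    def __init__(self, config: GibbsConfig | None = None, include_batch: bool = True):
        self.config = config
        self.include_batch = include_batch

    # ------------------------------------------------------------------
    def fit(
        self,
        traits: pd.DataFrame,
        kernels: dict[str, RelationshipMatrix],
        pcs: np.ndarray | None = None,
    ) -> "GibbsAnimalModel":
        cfg = self.config or GibbsConfig()
        rng = np.random.default_rng(cfg.seed)
        y = traits["y"].to_numpy(dtype=float)
        n = len(y)

        for name, K in kernels.items():
            if K.n != n:
                raise ValueError(f"kernel {name!r} size {K.n} != {n} records")
            if not np.array_equal(K.sample_ids, traits["sample_id"].to_numpy()):
                raise ValueError(f"kernel {name!r} sample ids not aligned to records")

        X = build_fixed_design(traits, pcs)
        # drop exactly collinear columns (e.g. an unobserved class level)
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
        self.dropped_fixed_cols_ = np.flatnonzero(~keep)
        X = X[:, keep]
        p = X.shape[1]
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        chol_cov_b = np.linalg.cholesky(XtX_inv)

        batch_idx, batch_levels = batch_design(traits)
        B = len(batch_levels)
        n_per_batch = np.bincount(batch_idx, minlength=B).astype(float)

        # spectral decomposition of each kernel, zero modes dropped
        rdt = np.dtype(cfg.rotation_dtype)
        eig = {}
        for name, K in kernels.items():
            lam, U = np.linalg.eigh(K.values)
            floor = -1e-8 * max(np.trace(K.values) / n, 1.0)
            if lam.min() < floor:
                raise ValueError(f"kernel {name!r} is not PSD (min eig {lam.min():.3e})")
            pos = lam > 1e-10 * lam.max()
            Upos = U[:, pos]
            eig[name] = (
                lam[pos].copy(),
                np.ascontiguousarray(Upos, dtype=rdt),
                np.ascontiguousarray(Upos.T, dtype=rdt),
            )
        knames = list(kernels)

        # scaled-inverse-chi-square priors: mode = equal split of var(y)
        nu0 = cfg.prior_df
        n_var = len(knames) + 2  # + batch + residual
        mode = np.var(y) / n_var
        S0 = mode * (nu0 + 2.0) / nu0

        # state
        b = XtX_inv @ (X.T @ y)
        h = np.zeros(B)
        s = {k: np.zeros(eig[k][0].shape) for k in knames}
        a = {k: np.zeros(n) for k in knames}
        sig2 = {k: mode for k in knames}
        sig2_batch = mode
        sig2_e = mode
        r_vec = y - X @ b

        n_ret = cfg.n_retained
        var_cols = [f"sigma2_{k}" for k in knames] + ["sigma2_batch", "sigma2_e"]
        chain = np.empty((n_ret, len(var_cols)))
        b_chain = np.empty((n_ret, p))
        h_sum = np.zeros(B)
        a_sum = {k: np.zeros(n) for k in knames}
        kept = 0

        chi2 = rng.chisquare
        for it in range(cfg.n_iter):
            # fixed effects (flat prior)
            rb = r_vec + X @ b
            mean_b = XtX_inv @ (X.T @ rb)
            b = mean_b + np.sqrt(sig2_e) * (chol_cov_b @ rng.standard_normal(p))
            r_vec = rb - X @ b

            # batch effects (iid normal)
            rh_sums = np.bincount(batch_idx, weights=r_vec, minlength=B) + n_per_batch * h
            denom = n_per_batch + sig2_e / sig2_batch
            h_new = rh_sums / denom + np.sqrt(sig2_e / denom) * rng.standard_normal(B)
            r_vec += (h - h_new)[batch_idx]
            h = h_new
            sig2_batch = (nu0 * S0 + h @ h) / chi2(nu0 + B)

            # correlated genetic effects, one kernel at a time
            for k in knames:
                lam, U, Ut = eig[k]
                t = (Ut @ r_vec.astype(rdt, copy=False)).astype(float) + s[k]
                post_var = 1.0 / (1.0 / sig2_e + 1.0 / (lam * sig2[k]))
                s_new = post_var * t / sig2_e + np.sqrt(post_var) * rng.standard_normal(lam.shape)
                a_new = (U @ s_new.astype(rdt, copy=False)).astype(float)
                r_vec += a[k] - a_new
                s[k], a[k] = s_new, a_new
                ss = np.sum(s_new * s_new / lam)
                sig2[k] = (nu0 * S0 + ss) / chi2(nu0 + len(lam))

            # residual variance
            sig2_e = (nu0 * S0 + r_vec @ r_vec) / chi2(nu0 + n)

            if (it + 1) % cfg.refresh_every == 0:
                r_vec = y - X @ b - h[batch_idx]
                for k in knames:
                    r_vec -= a[k]

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_ret:
                chain[kept, : len(knames)] = [sig2[k] for k in knames]
                chain[kept, len(knames)] = sig2_batch
                chain[kept, len(knames) + 1] = sig2_e
                b_chain[kept] = b
                h_sum += h
                for k in knames:
                    a_sum[k] += a[k]
                kept += 1

        self.config_used_ = cfg
        self.kernel_names_ = knames
        self.chain_ = pd.DataFrame(chain[:kept], columns=var_cols)
        self.b_chain_ = b_chain[:kept]
        self.n_retained_ = kept
        self.X_ = X
        self.batch_idx_ = batch_idx
        self.batch_levels_ = batch_levels
        self.b_mean_ = b_chain[:kept].mean(axis=0)
        self.h_mean_ = h_sum / max(kept, 1)
        self.effects_mean_ = {k: a_sum[k] / max(kept, 1) for k in knames}
        self.sample_ids_ = traits["sample_id"].to_numpy()
        return self

    # ------------------------------------------------------------------
    def summarize(self) -> VarianceComponents:
        return summarize_ratios(self.chain_, include_batch=self.include_batch)

    def convergence_report(self, alpha: float = 0.10) -> pd.DataFrame:
        rows = []
        for col in self.chain_.columns:
            z, pv = geweke_test(self.chain_[col].to_numpy())
            rows.append((col, z, pv, pv > alpha))
        return pd.DataFrame(rows, columns=["parameter", "z", "p", "passed"])


def summarize_ratios(chain: pd.DataFrame, include_batch: bool = True) -> VarianceComponents:
    """Posterior mean/SD of variances and their phenotypic fractions.

    Ratios are computed per retained sample and then averaged (posterior
    mean of the ratio, not ratio of posterior means).  ``include_batch``
    adds sigma2_batch to the denominator of every fraction.
    """
    if len(chain) == 0:
        raise ValueError("empty chain")
    cols = list(chain.columns)
    genetic = [c for c in cols if c not in ("sigma2_batch", "sigma2_e")]
    denom = chain["sigma2_e"].to_numpy().copy()
    for c in genetic:
        denom = denom + chain[c].to_numpy()
    if include_batch and "sigma2_batch" in cols:
        denom = denom + chain["sigma2_batch"].to_numpy()
    if np.any(denom <= 0):
        raise ValueError("non-positive total variance sample")

    ratio_of = {}
    for c in genetic:
        ratio_of[c] = chain[c].to_numpy() / denom
    if "sigma2_batch" in cols:
        ratio_of["sigma2_batch"] = chain["sigma2_batch"].to_numpy() / denom

    name_map = {
        "sigma2_G_additive": "h2",
        "sigma2_D_dominance": "d2",
        "sigma2_GG_epistatic": "ep2",
        "sigma2_batch": "h2_batch",
    }
    ratio_means = {name_map.get(k, k): float(v.mean()) for k, v in ratio_of.items()}
    ratio_sds = {name_map.get(k, k): float(v.std(ddof=1)) for k, v in ratio_of.items()}
    return VarianceComponents(
        means={c: float(chain[c].mean()) for c in cols},
        sds={c: float(chain[c].std(ddof=1)) for c in cols},
        ratio_means=ratio_means,
        ratio_sds=ratio_sds,
        include_batch=include_batch,
    )


def _spectral_density_zero(x: np.ndarray) -> float:
    """Newey-West (Bartlett kernel) long-run variance estimate."""
    n = len(x)
    xc = x - x.mean()
    L = int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    gamma0 = xc @ xc / n
    s = gamma0
    for k in range(1, min(L, n - 1) + 1):
        gk = xc[k:] @ xc[:-k] / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s, 1e-300)


def geweke_test(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> tuple[float, float]:
    """Geweke convergence z-score and two-sided p-value.

    Compares the mean of the first ``first`` fraction of the chain with
    the mean of the last ``last`` fraction, using spectral-density
    variance estimates of each segment.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("chain too short for the Geweke test (need >= 100)")
    if np.var(x) == 0:
        raise ValueError("zero-variance chain")
    a = x[: int(first * n)]
    b = x[n - int(last * n):]
    se2 = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    z = (a.mean() - b.mean()) / np.sqrt(se2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def adjust_phenotypes(traits: pd.DataFrame, model: GibbsAnimalModel) -> pd.DataFrame:
    """y* = y - X b_hat - W h_hat using posterior-mean solutions."""
    if not np.array_equal(model.sample_ids_, traits["sample_id"].to_numpy()):
        raise ValueError("model was fitted on a different record set")
    y = traits["y"].to_numpy(dtype=float)
    y_star = y - model.X_ @ model.b_mean_ - model.h_mean_[model.batch_idx_]
    return pd.DataFrame({"sample_id": traits["sample_id"], "y_star": y_star})
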