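import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from cattlegp.kinship import RelationshipMatrix, vanraden_g
from cattlegp.simdata import SimConfig, simulate_cohort
from cattlegp.varcomp import (
    GibbsAnimalModel,
    GibbsConfig,
    adjust_phenotypes,
    build_fixed_design,
    batch_design,
    geweke_test,
    summarize_ratios,
)


# ----------------------------------------------------------------------
# Bookkeeping
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "n_iter,burn_in,thin,expected",
    [(500_000, 50_000, 10, 45_000), (30_000, 5_000, 10, 2_500),
     (20_000, 0, 1, 20_000), (1_000, 500, 7, 71)],
)
def test_retention_bookkeeping(n_iter, burn_in, thin, expected):
    assert GibbsConfig(n_iter=n_iter, burn_in=burn_in, thin=thin).n_retained == expected


def test_config_validation():
    with pytest.raises(ValueError):
        GibbsConfig(n_iter=100, burn_in=100)
    with pytest.raises(ValueError):
        GibbsConfig(thin=0)


def test_sampler_retains_exactly_n_retained():
    cfg = SimConfig(n_individuals=60, n_markers=40, n_qtl_additive=10,
                    n_qtl_dominance=0, n_qtl_epistatic_pairs=0,
                    target_h2=0.3, target_d2=0, target_ep2=0, target_batch2=0.1,
                    n_batches=4, seed=0)
    g, _, traits = simulate_cohort(cfg)
    gc = GibbsConfig(n_iter=600, burn_in=100, thin=7, seed=0)
    m = GibbsAnimalModel(gc).fit(traits, {"G_additive": vanraden_g(g)})
    assert len(m.chain_) == gc.n_retained
    assert (m.chain_ > 0).all().all()


# ----------------------------------------------------------------------
# Ratio summaries
# ----------------------------------------------------------------------
def test_ratios_constant_chains_exact():
    chain = pd.DataFrame({"sigma2_G_additive": [0.3] * 5, "sigma2_batch": [0.2] * 5,
                          "sigma2_e": [0.5] * 5})
    vc = summarize_ratios(chain, include_batch=True)
    assert vc.ratio_means["h2"] == pytest.approx(0.30)
    assert vc.ratio_means["h2_batch"] == pytest.approx(0.20)


def test_ratios_batch_excluded_denominator():
    chain = pd.DataFrame({
        "sigma2_G_additive": [0.25] * 4, "sigma2_D_dominance": [0.25] * 4,
        "sigma2_GG_epistatic": [0.25] * 4, "sigma2_batch": [9.0] * 4,
        "sigma2_e": [0.25] * 4,
    })
    vc = summarize_ratios(chain, include_batch=False)
    assert vc.ratio_means["d2"] == pytest.approx(0.25)
    assert vc.ratio_means["ep2"] == pytest.approx(0.25)


def test_ratios_are_posterior_mean_of_ratio():
    rng = np.random.default_rng(0)
    chain = pd.DataFrame({
        "sigma2_G_additive": rng.uniform(0.1, 1, 200),
        "sigma2_batch": rng.uniform(0.1, 1, 200),
        "sigma2_e": rng.uniform(0.1, 1, 200),
    })
    vc = summarize_ratios(chain)
    denom = chain.sum(axis=1)
    expected = (chain["sigma2_G_additive"] / denom).mean()
    assert vc.ratio_means["h2"] == pytest.approx(expected, abs=1e-12)


def test_empty_chain_rejected():
    with pytest.raises(ValueError):
        summarize_ratios(pd.DataFrame({"sigma2_e": []}))


# ----------------------------------------------------------------------
# Geweke
# ----------------------------------------------------------------------
def test_geweke_calibrated_on_iid_chains():
    bad = 0
    for seed in range(40):
        x = np.random.default_rng(seed).standard_normal(10_000)
        z, _ = geweke_test(x)
        bad += abs(z) >= 3
    assert bad <= 1


def test_geweke_detects_linear_trend():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(5_000) + np.linspace(0, 3, 5_000)
    _, p = geweke_test(x)
    assert p < 0.01


def test_geweke_degenerate_inputs():
    with pytest.raises(ValueError):
        geweke_test(np.ones(1_000))
    with pytest.raises(ValueError):
        geweke_test(np.random.default_rng(0).standard_normal(50))


# ----------------------------------------------------------------------
# Fitting behaviour
# ----------------------------------------------------------------------
@pytest.fixture(scope="module")
def fitted_model():
    cfg = SimConfig(n_individuals=150, n_markers=120, n_qtl_additive=40,
                    n_qtl_dominance=0, n_qtl_epistatic_pairs=0,
                    target_h2=0.5, target_d2=0, target_ep2=0, target_batch2=0.15,
                    n_batches=6, seed=11)
    g, _, traits = simulate_cohort(cfg)
    m = GibbsAnimalModel(GibbsConfig(n_iter=6_000, burn_in=1_000, thin=5, seed=1)).fit(
        traits, {"G_additive": vanraden_g(g)}
    )
    return g, traits, m


def test_kernel_misalignment_rejected(fitted_model):
    g, traits, _ = fitted_model
    K = vanraden_g(g)
    K.sample_ids = K.sample_ids[::-1].copy()
    with pytest.raises(ValueError, match="aligned"):
        GibbsAnimalModel(GibbsConfig(n_iter=200, burn_in=10, seed=0)).fit(
            traits, {"G_additive": K}
        )


def test_non_psd_kernel_rejected(fitted_model):
    g, traits, _ = fitted_model
    bad = np.eye(g.n_samples)
    bad[0, 0] = -5.0
    K = RelationshipMatrix(bad, "G_additive", g.sample_ids)
    with pytest.raises(ValueError, match="PSD"):
        GibbsAnimalModel(GibbsConfig(n_iter=200, burn_in=10, seed=0)).fit(
            traits, {"G_additive": K}
        )


def test_strong_signal_recovers_genetic_values(fitted_model):
    _, traits, m = fitted_model
    u_hat = m.effects_mean_["G_additive"]
    u_true = traits["true_additive"].to_numpy()
    assert np.corrcoef(u_hat, u_true)[0, 1] > 0.7


def test_adjusted_phenotypes_remove_fixed_and_batch(fitted_model):
    _, traits, m = fitted_model
    adj = adjust_phenotypes(traits, m)
    target = traits["true_additive"] + traits["true_residual"]
    # adjustment leaves genetic + residual signal (up to the intercept)
    resid = adj["y_star"].to_numpy() - target.to_numpy()
    assert np.corrcoef(adj["y_star"], target)[0, 1] > 0.9
    assert np.std(resid) < np.std(traits["y"])


def test_adjust_identity_when_solutions_zero(fitted_model):
    _, traits, m = fitted_model
    model = GibbsAnimalModel()
    model.sample_ids_ = m.sample_ids_
    model.X_ = m.X_
    model.b_mean_ = np.zeros(m.X_.shape[1])
    model.h_mean_ = np.zeros_like(m.h_mean_)
    model.batch_idx_ = m.batch_idx_
    adj = adjust_phenotypes(traits, model)
    assert np.allclose(adj["y_star"], traits["y"])


def test_adjust_mismatched_records_rejected(fitted_model):
    _, traits, m = fitted_model
    shuffled = traits.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="different record"):
        adjust_phenotypes(shuffled, m)


def test_fixed_design_drops_reference_levels():
    traits = pd.DataFrame({
        "dim_class": [0, 1, 2, 0, 1, 2], "parity_class": [0, 0, 1, 1, 0, 1],
        "batch": [0, 0, 1, 1, 2, 2],
    })
    X = build_fixed_design(traits)
    # intercept + 2 DIM dummies + 1 parity dummy
    assert X.shape == (6, 4)
    idx, levels = batch_design(traits)
    assert len(levels) == 3 and idx.max() == 2


# ----------------------------------------------------------------------
# Cross-method checks
# ----------------------------------------------------------------------
def test_identity_kernel_matches_independent_sampler():
    """With K = I the model is iid random effects; an independently
    written scalar Gibbs sampler must agree on the posterior h2."""
    rng = np.random.default_rng(5)
    n = 50
    u = rng.standard_normal(n) * np.sqrt(0.5)
    y = 1.0 + u + rng.standard_normal(n) * np.sqrt(0.5)
    traits = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "y": y,
        "dim_class": 0, "parity_class": 0, "batch": rng.integers(0, 4, n),
    })
    K = RelationshipMatrix(np.eye(n), "G_additive", traits["sample_id"].to_numpy())
    m = GibbsAnimalModel(GibbsConfig(n_iter=20_000, burn_in=4_000, thin=4, seed=2)).fit(
        traits, {"G_additive": K}
    )
    h2_pkg = m.summarize().ratio_means["h2"]

    # brute-force scalar sampler, written independently of the package path
    nu0 = 5.0
    mode = np.var(y) / 3.0
    S0 = mode * (nu0 + 2) / nu0
    bidx = traits["batch"].to_numpy()
    B = bidx.max() + 1
    nb = np.bincount(bidx, minlength=B).astype(float)
    r2 = np.random.default_rng(7)
    mu, uu, hh = y.mean(), np.zeros(n), np.zeros(B)
    s2u = s2b = s2e = mode
    keep = []
    for it in range(20_000):
        resid = y - uu - hh[bidx]
        mu = resid.mean() + np.sqrt(s2e / n) * r2.standard_normal()
        resid = y - mu - hh[bidx]
        v = 1.0 / (1.0 / s2e + 1.0 / s2u)
        uu = v * resid / s2e + np.sqrt(v) * r2.standard_normal(n)
        resid = y - mu - uu
        sums = np.bincount(bidx, weights=resid, minlength=B)
        vb = 1.0 / (nb / s2e + 1.0 / s2b)
        hh = vb * sums / s2e + np.sqrt(vb) * r2.standard_normal(B)
        e = y - mu - uu - hh[bidx]
        s2u = (nu0 * S0 + uu @ uu) / r2.chisquare(nu0 + n)
        s2b = (nu0 * S0 + hh @ hh) / r2.chisquare(nu0 + B)
        s2e = (nu0 * S0 + e @ e) / r2.chisquare(nu0 + n)
        if it >= 4_000 and it % 4 == 0:
            keep.append(s2u / (s2u + s2b + s2e))
    assert h2_pkg == pytest.approx(np.mean(keep), abs=0.06)


def test_model1_h2_close_to_reml():
    cfg = SimConfig(n_individuals=250, n_markers=800, n_qtl_additive=80,
                    n_qtl_dominance=0, n_qtl_epistatic_pairs=0,
                    target_h2=0.35, target_d2=0, target_ep2=0, target_batch2=0.2,
                    seed=5)
    g, _, traits = simulate_cohort(cfg)
    G = vanraden_g(g)
    m = GibbsAnimalModel(GibbsConfig(n_iter=20_000, burn_in=4_000, thin=10, seed=2)).fit(
        traits, {"G_additive": G}
    )
    h2_gibbs = m.summarize().ratio_means["h2"]

    y = traits["y"].to_numpy()
    X = build_fixed_design(traits)
    bidx, _ = batch_design(traits)
    W = np.zeros((len(y), bidx.max() + 1))
    W[np.arange(len(y)), bidx] = 1.0
    n = len(y)

    def reml_negll(logv):
        sa, sb, se = np.exp(logv)
        V = sa * G.values + sb * (W @ W.T) + se * np.eye(n)
        L = np.linalg.cholesky(V)
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        _, ld2 = np.linalg.slogdet(XtViX)
        return 0.5 * (2 * np.log(np.diag(L)).sum() + ld2 + r @ Vi_r)

    res = optimize.minimize(reml_negll, np.log([0.3, 0.2, 0.5]), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 500})
    sa, sb, se = np.exp(res.x)
    h2_reml = sa / (sa + sb + se)
    assert abs(h2_gibbs - h2_reml) < 0.05
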