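"""Synthetic dairy-cattle cohort generator.

Emulates the experimental structure the downstream analysis assumes:
a genotyped cohort (biallelic autosomal SNPs in LD blocks) drawn from
two diverged subpopulations, sampled in herd/date batches, with fixed
days-in-milk (6 levels) and parity (4 levels) classes, and quantitative
trait values composed of additive, dominance, additive-by-additive
epistatic, batch, fixed and residual parts with controllable variance
fractions.

Genotypes use a Balding-Nichols construction: an ancestral frequency is
drawn per marker, each subpopulation's frequency is a Beta draw around
it with divergence ``fst``, and two latent Gaussian haplotypes per
individual are thresholded at the Hardy-Weinberg quantile.  Markers in
the same block share an equicorrelated latent factor (``ld_rho``),
which induces within-block linkage disequilibrium.

True genetic values are rescaled so the realized variance of every
component matches its target fraction exactly on the simulated cohort;
the residual variance absorbs the remainder (targets must sum < 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .kinship import dominance_covariates

__all__ = [
    "SimConfig",
    "TrueArchitecture",
    "simulate_genotypes",
    "simulate_architecture",
    "simulate_phenotypes",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror a field cohort of dairy cows sampled in 21 herd/date
    batches with two genetic subpopulations; scale ``n_individuals`` and
    ``n_markers`` down for unit tests.
    """

    n_individuals: int = 1353
    n_markers: int = 61226
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.6
    n_subpops: int = 2
    fst: float = 0.05
    n_batches: int = 21
    n_dim_classes: int = 6
    n_parity_classes: int = 4
    n_qtl_additive: int = 300
    n_qtl_dominance: int = 100
    n_qtl_epistatic_pairs: int = 100
    target_h2: float = 0.25
    target_d2: float = 0.10
    target_ep2: float = 0.15
    target_batch2: float = 0.20
    fixed_effect_sd: float = 0.3
    # 0 = batches assigned at random; 1 = batch membership follows the
    # genetic value exactly (herd/family confounding, makes batch-out CV
    # genuinely harder than the tenfold design)
    batch_confounding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_individuals", "n_markers", "n_chromosomes", "n_batches",
                     "ld_block_size", "n_subpops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.ld_block_size > self.n_markers:
            raise ValueError("ld_block_size cannot exceed n_markers")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.fst < 0.5):
            raise ValueError("fst must be in [0, 0.5)")
        targets = self.targets()
        if any(t < 0 for t in targets.values()):
            raise ValueError("variance-fraction targets must be >= 0")
        if sum(targets.values()) >= 1.0:
            raise ValueError("variance-fraction targets must sum to < 1")
        if self.n_qtl_epistatic_pairs > 0 and self.n_markers < 2:
            raise ValueError("epistatic pairs need at least two markers")
        for name in ("n_qtl_additive", "n_qtl_dominance"):
            if getattr(self, name) > self.n_markers:
                raise ValueError(f"{name} exceeds n_markers")

    def targets(self) -> dict[str, float]:
        return {
            "h2": self.target_h2,
            "d2": self.target_d2,
            "ep2": self.target_ep2,
            "batch2": self.target_batch2,
        }


@dataclass
class TrueArchitecture:
    """Generative truth underlying one simulated trait."""

    additive_effects: dict = field(repr=False)
    dominance_effects: dict = field(repr=False)
    epistatic_pairs: list = field(repr=False)
    fixed_effect_values: dict = field(repr=False)
    batch_effects: np.ndarray = field(repr=False)
    additive_values: np.ndarray = field(repr=False)
    dominance_values: np.ndarray = field(repr=False)
    epistatic_values: np.ndarray = field(repr=False)

    @property
    def genetic_values(self) -> np.ndarray:
        return self.additive_values + self.dominance_values + self.epistatic_values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "additive": self.additive_values,
                "dominance": self.dominance_values,
                "epistatic": self.epistatic_values,
            }
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw the cohort dosage matrix; deterministic given ``cfg.seed``."""
    rng = _rng(cfg, 0)
    n, m = cfg.n_individuals, cfg.n_markers
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    if cfg.fst > 0 and cfg.n_subpops > 1:
        a = p_anc * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - p_anc) * (1.0 - cfg.fst) / cfg.fst
        p_sub = rng.beta(a, b, size=(cfg.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))
    subpop = rng.integers(0, cfg.n_subpops, size=n)

    # equicorrelated latent Gaussians within LD blocks, iid across blocks;
    # blocks never straddle chromosome boundaries
    chrom_of = np.minimum(np.arange(m) * cfg.n_chromosomes // m, cfg.n_chromosomes - 1)
    block_of = np.arange(m) // cfg.ld_block_size
    block_id = block_of * cfg.n_chromosomes + chrom_of  # distinct per (chrom, block)
    _, block_idx = np.unique(block_id, return_inverse=True)
    n_blocks = block_idx.max() + 1
    sr, so = np.sqrt(cfg.ld_rho), np.sqrt(1.0 - cfg.ld_rho)

    thr = stats.norm.ppf(p_sub)  # haplotype carries counted allele if z < thr
    dosage = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        shared = rng.standard_normal((n, n_blocks))[:, block_idx]
        z = sr * shared + so * rng.standard_normal((n, m))
        dosage += (z < thr[subpop, :]).astype(float)

    meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": [str(c + 1) for c in chrom_of],
            "pos": (np.arange(m) % max(m // cfg.n_chromosomes, 1) + 1) * 1000,
            "a1": ["A"] * m,
            "a2": ["B"] * m,
        }
    )
    g = GenotypeMatrix(dosage, np.array([f"cow{i}" for i in range(n)], dtype=object), meta)
    g.subpop_labels = subpop  # generative labels, carried for validation
    return g


def _scaled(values: np.ndarray, target_var: float, what: str) -> np.ndarray:
    v = values.var()
    if target_var == 0.0:
        return np.zeros_like(values)
    if v <= 0:
        raise ValueError(f"cannot scale {what}: zero realized variance")
    return values * np.sqrt(target_var / v)


def simulate_architecture(cfg: SimConfig, g: GenotypeMatrix) -> TrueArchitecture:
    """Draw QTL effects and rescale components to the target fractions.

    Phenotypic variance (random parts) is normalised to 1, so each
    component's realized cohort variance equals its target fraction.
    """
    rng = _rng(cfg, 1)
    m = g.n_markers
    p = g.allele_freq()
    xc = g.dosages - 2.0 * p

    add_idx = rng.choice(m, size=min(cfg.n_qtl_additive, m), replace=False)
    beta_a = rng.standard_normal(len(add_idx))
    u_a = xc[:, add_idx] @ beta_a if len(add_idx) else np.zeros(g.n_samples)
    if cfg.target_h2 > 0:
        u_a = _scaled(u_a, cfg.target_h2, "additive component")
    else:
        u_a, beta_a, add_idx = np.zeros(g.n_samples), beta_a * 0, add_idx

    if cfg.n_qtl_dominance > 0 and cfg.target_d2 > 0:
        dom_idx = rng.choice(m, size=min(cfg.n_qtl_dominance, m), replace=False)
        beta_d = rng.standard_normal(len(dom_idx))
        w = dominance_covariates(g)
        u_d = w[:, dom_idx] @ beta_d
        u_d = _scaled(u_d, cfg.target_d2, "dominance component")
    else:
        dom_idx, beta_d = np.array([], dtype=int), np.array([])
        u_d = np.zeros(g.n_samples)

    ep_pairs: list[tuple[int, int, float]] = []
    if cfg.n_qtl_epistatic_pairs > 0 and cfg.target_ep2 > 0:
        u_ep = np.zeros(g.n_samples)
        for _ in range(cfg.n_qtl_epistatic_pairs):
            i, j = rng.choice(m, size=2, replace=False)
            eff = rng.standard_normal()
            ep_pairs.append((int(i), int(j), float(eff)))
            u_ep = u_ep + eff * xc[:, i] * xc[:, j]
        u_ep = u_ep - u_ep.mean()
        scale = np.sqrt(cfg.target_ep2 / u_ep.var()) if u_ep.var() > 0 else 0.0
        u_ep = u_ep * scale
        ep_pairs = [(i, j, e * scale) for i, j, e in ep_pairs]
    else:
        u_ep = np.zeros(g.n_samples)

    fixed = {
        "dim": rng.normal(0.0, cfg.fixed_effect_sd, size=cfg.n_dim_classes),
        "parity": rng.normal(0.0, cfg.fixed_effect_sd, size=cfg.n_parity_classes),
    }
    batch_eff = rng.standard_normal(cfg.n_batches)

    marker_ids = g.marker_ids
    return TrueArchitecture(
        additive_effects=dict(zip(marker_ids[add_idx], beta_a)),
        dominance_effects=dict(zip(marker_ids[dom_idx], beta_d)),
        epistatic_pairs=[(marker_ids[i], marker_ids[j], e) for i, j, e in ep_pairs],
        fixed_effect_values=fixed,
        batch_effects=batch_eff,
        additive_values=u_a,
        dominance_values=u_d,
        epistatic_values=u_ep,
    )


def simulate_phenotypes(
    g: GenotypeMatrix, arch: TrueArchitecture, cfg: SimConfig
) -> pd.DataFrame:
    """Assemble the trait table: one record per individual.

    Columns: ``sample_id``, ``y``, ``dim_class``, ``parity_class``,
    ``batch``, ``subpop``, plus the true component columns for
    validation (``true_additive`` etc.).
    """
    rng = _rng(cfg, 2)
    n = g.n_samples
    if len(arch.additive_values) != n:
        raise ValueError("architecture was generated for a different cohort")

    probs = rng.dirichlet(np.full(cfg.n_batches, 5.0))
    if cfg.batch_confounding > 0:
        # contiguous blocks along a noisy ordering of the genetic value:
        # batches become genetically homogeneous as confounding -> 1
        gstd = arch.genetic_values
        sd = gstd.std() if gstd.std() > 0 else 1.0
        c = cfg.batch_confounding
        score = c * gstd / sd + (1.0 - c) * rng.standard_normal(n)
        order = np.argsort(score)
        sizes = np.maximum(np.round(probs * n).astype(int), 1)
        while sizes.sum() > n:
            sizes[sizes.argmax()] -= 1
        while sizes.sum() < n:
            sizes[sizes.argmin()] += 1
        batch = np.empty(n, dtype=int)
        batch[order] = np.repeat(np.arange(cfg.n_batches), sizes)
    else:
        batch = rng.choice(cfg.n_batches, size=n, p=probs)
        # guarantee every batch label occurs
        missing = np.setdiff1d(np.arange(cfg.n_batches), np.unique(batch))
        if len(missing):
            batch[rng.choice(n, size=len(missing), replace=False)] = missing

    dim_class = rng.integers(0, cfg.n_dim_classes, size=n)
    parity = rng.integers(0, cfg.n_parity_classes, size=n)

    batch_vals = arch.batch_effects[batch]
    if cfg.target_batch2 > 0:
        batch_vals = _scaled(batch_vals - batch_vals.mean(), cfg.target_batch2, "batch component")
    else:
        batch_vals = np.zeros(n)

    resid_var = 1.0 - sum(cfg.targets().values())
    e = rng.normal(0.0, np.sqrt(resid_var), size=n) if resid_var > 0 else np.zeros(n)

    fixed_part = (
        arch.fixed_effect_values["dim"][dim_class]
        + arch.fixed_effect_values["parity"][parity]
    )
    y = fixed_part + batch_vals + arch.genetic_values + e

    subpop = getattr(g, "subpop_labels", np.zeros(n, dtype=int))
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "y": y,
            "dim_class": dim_class,
            "parity_class": parity,
            "batch": batch,
            "subpop": subpop,
            "true_additive": arch.additive_values,
            "true_dominance": arch.dominance_values,
            "true_epistatic": arch.epistatic_values,
            "true_batch": batch_vals,
            "true_residual": e,
        }
    )


def simulate_cohort(cfg: SimConfig):
    """Genotypes + architecture + trait table in one call."""
    g = simulate_genotypes(cfg)
    arch = simulate_architecture(cfg, g)
    traits = simulate_phenotypes(g, arch, cfg)
    return g, arch, traits
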