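"""Genomic relationship kernels, genotype PCA, and genomic distances.

Three kernels over individuals:

* additive ``G`` (VanRaden): ``G = MM' / (2 sum_j p_j (1 - p_j))`` with
  ``M`` the allele-frequency-centered dosage matrix;
* dominance ``D`` (Vitezica): HWE-centered heterozygosity covariates
  (-2p^2, 2pq, -2q^2) normalised by ``sum_j (2 p_j q_j)^2``;
* additive-by-additive epistatic ``GG``: the Hadamard (element-wise)
  product of ``G`` with itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "PcaResult",
    "vanraden_g",
    "vitezica_d",
    "hadamard_gg",
    "genotype_pca",
    "genomic_distance",
]

KINDS = ("G_additive", "D_dominance", "GG_epistatic")


@dataclass
class RelationshipMatrix:
    values: np.ndarray
    kind: str
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self, rtol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        floor = -rtol * max(np.trace(self.values) / self.n, 1.0)
        if w.min() < floor:
            raise ValueError(f"matrix not PSD: min eigenvalue {w.min():.3e}")


@dataclass
class PcaResult:
    scores: np.ndarray
    variance_explained: np.ndarray
    loadings: np.ndarray | None = None


def _require_complete(g: GenotypeMatrix) -> None:
    if g.has_missing():
        raise ValueError("genotypes contain missing calls; impute first")


def vanraden_g(g: GenotypeMatrix, freq: np.ndarray | None = None) -> RelationshipMatrix:
    """Additive genomic relationship matrix (VanRaden)."""
    _require_complete(g)
    p = g.allele_freq() if freq is None else np.asarray(freq, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    m = g.dosages - 2.0 * p
    return RelationshipMatrix(m @ m.T / denom, "G_additive", g.sample_ids.copy())


def dominance_covariates(g: GenotypeMatrix, freq: np.ndarray | None = None) -> np.ndarray:
    """Vitezica dominance coding: 0 -> -2p^2, 1 -> 2pq, 2 -> -2q^2."""
    _require_complete(g)
    p = g.allele_freq() if freq is None else np.asarray(freq, dtype=float)
    q = 1.0 - p
    d = g.dosages
    # interpolate linearly for imputed (non-integer) dosages
    w0, w1, w2 = -2.0 * p * p, 2.0 * p * q, -2.0 * q * q
    het = np.clip(1.0 - np.abs(d - 1.0), 0.0, 1.0)
    hom2 = np.clip(d - 1.0, 0.0, 1.0)
    hom0 = np.clip(1.0 - d, 0.0, 1.0)
    return hom0 * w0 + het * w1 + hom2 * w2


def vitezica_d(g: GenotypeMatrix, freq: np.ndarray | None = None) -> RelationshipMatrix:
    """Dominance relationship matrix (Vitezica): D = WW' / sum (2pq)^2."""
    p = g.allele_freq() if freq is None else np.asarray(freq, dtype=float)
    q = 1.0 - p
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero dominance denominator")
    w = dominance_covariates(g, p)
    return RelationshipMatrix(w @ w.T / denom, "D_dominance", g.sample_ids.copy())


def hadamard_gg(G: RelationshipMatrix, rescale: bool = False) -> RelationshipMatrix:
    """Additive-by-additive epistatic kernel GG = G * G (element-wise).

    ``rescale=True`` divides by trace/n so diag averages 1; the default
    keeps the raw Hadamard product.
    """
    if G.kind != "G_additive":
        raise ValueError("hadamard_gg expects the additive kernel")
    v = G.values * G.values
    if rescale:
        v = v / (np.trace(v) / v.shape[0])
    return RelationshipMatrix(v, "GG_epistatic", G.sample_ids.copy())


def genotype_pca(
    g: GenotypeMatrix, n_components: int = 2, standardize: bool = False
) -> PcaResult:
    """PCA of the column-centered dosage matrix.

    Centering uses observed allele frequencies (VanRaden-consistent);
    ``standardize`` additionally scales columns to unit variance.
    """
    _require_complete(g)
    if n_components > min(g.n_samples, g.n_markers):
        raise ValueError("n_components exceeds matrix rank bound")
    x = g.dosages - g.dosages.mean(axis=0)
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = x / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    return PcaResult(scores, pca.explained_variance_ratio_, pca.components_.T)


def genomic_distance(G: RelationshipMatrix) -> np.ndarray:
    """Kernel-induced Euclidean distance d_ij = sqrt(G_ii + G_jj - 2 G_ij)."""
    if G.kind != "G_additive":
        raise ValueError("genomic distance expects the additive kernel")
    diag = np.diag(G.values)
    sq = diag[:, None] + diag[None, :] - 2.0 * G.values
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return d
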