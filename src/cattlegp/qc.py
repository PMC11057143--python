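"""Genotype quality control.

Filter pipeline (in order): drop non-autosomal markers, drop samples by
call rate, drop markers by call rate, drop markers by MAF, drop markers
by a 1-df Hardy-Weinberg chi-square test.  Thresholds follow standard
chip QC for cattle cohorts: MAF < 0.05 removed (strictly below), HWE
p <= 1e-5 removed, call rate < 0.95 removed on both axes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = ["QCReport", "qc_filter", "impute_missing_mean", "compute_allele_freq", "hwe_pvalues"]

# chromosome labels treated as non-autosomal for cattle chips
_NON_AUTOSOMAL = {"X", "Y", "MT", "M", "XY", "chrX", "chrY", "chrM", "0"}


@dataclass
class QCReport:
    n_samples_in: int
    n_markers_in: int
    n_samples_out: int = 0
    n_markers_out: int = 0
    removed_nonautosomal: list = field(default_factory=list)
    removed_by_sample_callrate: list = field(default_factory=list)
    removed_by_marker_callrate: list = field(default_factory=list)
    removed_by_maf: list = field(default_factory=list)
    removed_by_hwe: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        return (
            f"samples {self.n_samples_in} -> {self.n_samples_out}; "
            f"markers {self.n_markers_in} -> {self.n_markers_out} "
            f"(non-autosomal {len(self.removed_nonautosomal)}, "
            f"marker call rate {len(self.removed_by_marker_callrate)}, "
            f"MAF {len(self.removed_by_maf)}, HWE {len(self.removed_by_hwe)})"
        )


def compute_allele_freq(g: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency p_j over observed calls."""
    return g.allele_freq()


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """1-df chi-square Hardy-Weinberg test p-value per marker.

    Observed genotype counts (n0, n1, n2) are compared with expectations
    (q^2, 2pq, p^2) * n from the observed allele frequency; the statistic
    has 1 df because one allele frequency is estimated.
    """
    d = g.dosages
    obs = ~np.isnan(d)
    n = obs.sum(axis=0).astype(float)
    n2 = np.nansum(d == 2, axis=0).astype(float)
    n1 = np.nansum(d == 1, axis=0).astype(float)
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    exp = np.stack([q * q * n, 2 * p * q * n, p * p * n])
    obs_counts = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs_counts - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic markers: test undefined, no deviation
    pvals[np.isclose(p * q, 0.0)] = 1.0
    return pvals


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p: float = 1e-5,
    callrate_min: float = 0.95,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker/sample QC filters and return the kept matrix + report."""
    rep = QCReport(
        n_samples_in=g.n_samples,
        n_markers_in=g.n_markers,
        thresholds={
            "maf_min": maf_min,
            "hwe_p": hwe_p,
            "callrate_min": callrate_min,
            "autosomes_only": autosomes_only,
        },
    )
    cur = g
    if autosomes_only:
        chrom = cur.marker_meta["chrom"].astype(str)
        keep = ~chrom.isin(_NON_AUTOSOMAL)
        rep.removed_nonautosomal = list(cur.marker_ids[~keep.to_numpy()])
        cur = cur.subset(marker_idx=np.flatnonzero(keep.to_numpy()))

    if cur.n_markers:
        cr_samp = 1.0 - np.isnan(cur.dosages).mean(axis=1)
        keep_s = cr_samp >= callrate_min
        rep.removed_by_sample_callrate = list(cur.sample_ids[~keep_s])
        cur = cur.subset(sample_idx=np.flatnonzero(keep_s))

    if cur.n_samples:
        cr_mark = 1.0 - np.isnan(cur.dosages).mean(axis=0)
        keep_m = cr_mark >= callrate_min
        rep.removed_by_marker_callrate = list(cur.marker_ids[~keep_m])
        cur = cur.subset(marker_idx=np.flatnonzero(keep_m))

    if cur.n_markers:
        p = cur.allele_freq()
        maf = np.minimum(p, 1.0 - p)
        keep_maf = maf >= maf_min  # "lower than 0.05" removed: strict
        rep.removed_by_maf = list(cur.marker_ids[~keep_maf])
        cur = cur.subset(marker_idx=np.flatnonzero(keep_maf))

    if cur.n_markers:
        pv = hwe_pvalues(cur)
        keep_hwe = pv > hwe_p  # p <= threshold removed
        rep.removed_by_hwe = list(cur.marker_ids[~keep_hwe])
        cur = cur.subset(marker_idx=np.flatnonzero(keep_hwe))

    rep.n_samples_out = cur.n_samples
    rep.n_markers_out = cur.n_markers
    if cur.n_markers == 0 or cur.n_samples == 0:
        raise ValueError(f"QC removed everything: {rep.summary()}")
    return cur, rep


def impute_missing_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage with 2 p_j (the column mean).

    Note the imputed matrix no longer has pure {0,1,2} codes, so it is
    returned as a plain copy with the same metadata (bypassing the code
    check); downstream kernels operate on real-valued dosages.
    """
    if not g.has_missing():
        return g
    p = g.allele_freq()
    dos = g.dosages.copy()
    miss = np.isnan(dos)
    dos[miss] = np.broadcast_to(2.0 * p, dos.shape)[miss]
    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out.dosages = dos
    out.sample_ids = g.sample_ids.copy()
    out.marker_meta = g.marker_meta.copy()
    return out
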