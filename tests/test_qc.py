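import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cattlegp.genotypes import GenotypeMatrix, read_genotypes, write_tsv, write_vcf
from cattlegp.qc import compute_allele_freq, hwe_pvalues, impute_missing_mean, qc_filter


def _matrix(dosages, chroms=None):
    dos = np.asarray(dosages, dtype=float)
    m = dos.shape[1]
    meta = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": chroms or ["1"] * m,
            "pos": np.arange(1, m + 1) * 10,
            "a1": ["A"] * m,
            "a2": ["B"] * m,
        }
    )
    ids = np.array([f"s{i}" for i in range(dos.shape[0])], dtype=object)
    return GenotypeMatrix(dos, ids, meta)


# ----------------------------------------------------------------------
# IO
# ----------------------------------------------------------------------
def test_tsv_round_trip(tiny_genotypes, tmp_path):
    path = tmp_path / "g.tsv"
    write_tsv(tiny_genotypes, path)
    back = read_genotypes(path, "tsv")
    assert np.array_equal(back.dosages, tiny_genotypes.dosages, equal_nan=True)
    assert list(back.sample_ids) == list(tiny_genotypes.sample_ids)


def test_vcf_round_trip_and_het_coding(tiny_genotypes, tmp_path):
    path = tmp_path / "g.vcf"
    write_vcf(tiny_genotypes, path)
    back = read_genotypes(path, "vcf")
    assert np.array_equal(back.dosages, tiny_genotypes.dosages, equal_nan=True)
    # a 0/1 GT is one copy of the ALT allele
    text = path.read_text()
    assert "0/1" in text and "./." in text


def test_vcf_multiallelic_rejected(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tmx\tA\tC,T\t.\t.\t.\tGT\t0/1\n"
    )
    with pytest.raises(ValueError, match="multi-allelic"):
        read_genotypes(path, "vcf")


def test_plink_text_parsing_with_missing(tmp_path):
    """3-sample .ped/.map fixture with hand-derived expected dosages."""
    (tmp_path / "f.map").write_text("1 m1 0 100\n1 m2 0 200\n")
    (tmp_path / "f.ped").write_text(
        "fam1 s1 0 0 2 -9 A A A G\n"
        "fam1 s2 0 0 2 -9 A G 0 0\n"
        "fam1 s3 0 0 2 -9 G G G G\n"
    )
    g = read_genotypes(tmp_path / "f.ped", "plink_text")
    # dosage counts the lexicographically second allele (G)
    expected = np.array([[0.0, 1.0], [1.0, np.nan], [2.0, 2.0]])
    assert np.array_equal(g.dosages, expected, equal_nan=True)
    assert list(g.marker_meta["a2"]) == ["G", "G"]


# ----------------------------------------------------------------------
# Filters
# ----------------------------------------------------------------------
def test_hwe_excess_homozygotes_removed():
    # 45 AA, 10 Aa, 45 aa among 100: massive heterozygote deficit
    dos = np.array([0.0] * 45 + [1.0] * 10 + [2.0] * 45)[:, None]
    g = _matrix(np.hstack([dos, np.tile([[0], [1]], (50, 1))]))
    pv = hwe_pvalues(g)
    # independent oracle: 1-df chi-square from observed vs expected counts
    p = (2 * 45 + 10) / 200
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * 100
    chi2 = (((np.array([45, 10, 45]) - exp) ** 2) / exp).sum()
    assert pv[0] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)
    assert pv[0] < 1e-5
    kept, rep = qc_filter(g, maf_min=0.0, callrate_min=0.0)
    assert "m0" in rep.removed_by_hwe


@pytest.mark.parametrize(
    "counts",
    [(25, 50, 25), (40, 20, 40), (70, 25, 5), (10, 80, 10), (90, 9, 1), (50, 0, 50)],
)
def test_hwe_statistic_matches_bruteforce(counts):
    n0, n1, n2 = counts
    dos = np.array([0.0] * n0 + [1.0] * n1 + [2.0] * n2)[:, None]
    g = _matrix(dos)
    n = n0 + n1 + n2
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        expected = 1.0
    else:
        exp = np.array([(1 - p) ** 2 * n, 2 * p * (1 - p) * n, p * p * n])
        chi2 = (((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum()
        expected = stats.chi2.sf(chi2, 1)
    assert hwe_pvalues(g)[0] == pytest.approx(expected, rel=1e-10)


def test_maf_threshold_is_strict():
    rng = np.random.default_rng(0)
    base = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
    maf_004 = np.array([1.0] * 8 + [0.0] * 92)[:, None]  # MAF 0.04
    maf_005 = np.array([1.0] * 10 + [0.0] * 90)[:, None]  # MAF exactly 0.05
    g = _matrix(np.hstack([base, maf_004, maf_005]))
    kept, rep = qc_filter(g, hwe_p=0.0, callrate_min=0.0)
    assert "m1" in rep.removed_by_maf
    assert "m2" not in rep.removed_by_maf
    assert "m2" in kept.marker_ids


def test_sample_callrate_filter_and_report_reconciliation():
    rng = np.random.default_rng(1)
    dos = rng.binomial(2, 0.5, size=(20, 50)).astype(float)
    dos[0, :3] = np.nan  # 94% call rate -> removed at 0.95
    chroms = ["1"] * 48 + ["X", "MT"]
    g = _matrix(dos, chroms=chroms)
    kept, rep = qc_filter(g, maf_min=0.0, hwe_p=0.0)
    assert "s0" in rep.removed_by_sample_callrate
    assert set(rep.removed_nonautosomal) == {"m48", "m49"}
    assert rep.n_samples_out == rep.n_samples_in - len(rep.removed_by_sample_callrate)
    removed_markers = (
        len(rep.removed_nonautosomal)
        + len(rep.removed_by_marker_callrate)
        + len(rep.removed_by_maf)
        + len(rep.removed_by_hwe)
    )
    assert rep.n_markers_out == rep.n_markers_in - removed_markers


def test_qc_filter_idempotent():
    rng = np.random.default_rng(2)
    dos = rng.binomial(2, rng.uniform(0.05, 0.5, 30), size=(120, 30)).astype(float)
    dos[rng.random(dos.shape) < 0.02] = np.nan
    g = _matrix(dos)
    once, _ = qc_filter(g)
    twice, rep2 = qc_filter(once)
    assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
    assert rep2.n_markers_in == rep2.n_markers_out


# ----------------------------------------------------------------------
# Imputation and allele frequency
# ----------------------------------------------------------------------
def test_impute_missing_mean(tiny_genotypes):
    imp = impute_missing_mean(tiny_genotypes)
    assert not imp.has_missing()
    # m2 has observed dosages (1,1,1): p=0.5 -> imputed 1.0
    assert imp.dosages[2, 1] == pytest.approx(1.0)
    # column means preserved
    for j in range(3):
        obs = tiny_genotypes.dosages[:, j]
        assert imp.dosages[:, j].mean() == pytest.approx(np.nanmean(obs), abs=1e-12)


def test_impute_identity_when_complete():
    g = _matrix([[0, 1], [2, 1]])
    assert impute_missing_mean(g) is g


def test_allele_freq_counting_oracle():
    rng = np.random.default_rng(3)
    dos = rng.binomial(2, 0.3, size=(50, 10)).astype(float)
    dos[rng.random(dos.shape) < 0.1] = np.nan
    g = _matrix(dos)
    p = compute_allele_freq(g)
    for j in range(10):
        col = dos[:, j]
        obs = col[~np.isnan(col)]
        assert p[j] == pytest.approx(obs.sum() / (2 * len(obs)), abs=1e-14)
    g2 = _matrix([[2.0], [2.0], [2.0]])
    assert compute_allele_freq(g2)[0] == 1.0
    g3 = _matrix([[0.0], [1.0], [2.0]])
    assert compute_allele_freq(g3)[0] == 0.5


def test_all_missing_marker_rejected():
    g = _matrix([[np.nan, 1.0], [np.nan, 2.0]])
    with pytest.raises(ValueError, match="no observed calls"):
        g.allele_freq()
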