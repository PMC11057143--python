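"""Genotype containers and file IO.

Dosages are stored as a dense float array of alternate-allele counts
(0, 1, 2) with ``numpy.nan`` marking missing calls.  The counted allele
is the ALT allele for VCF input and the second allele for PLINK text
input, matching the usual 0/1/2 coding of *AA*, *AB*, *BB* genotypes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "write_tsv", "write_vcf"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_markers)
        Alternate/second-allele counts in {0, 1, 2}; nan = missing.
    sample_ids : ndarray of str
    marker_meta : DataFrame
        Columns ``id``, ``chrom``, ``pos``, ``a1``, ``a2``; one row per
        marker, aligned with the columns of ``dosages``.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    marker_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.marker_meta) != m:
            raise ValueError("marker_meta length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample identifiers must be unique")
        ids = self.marker_meta["id"]
        if ids.duplicated().any():
            raise ValueError("marker identifiers must be unique")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage codes must be 0, 1, 2 or missing")
        self.marker_meta = self.marker_meta.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_meta["id"].to_numpy()

    def allele_freq(self) -> np.ndarray:
        """Counted-allele frequency p_j from observed calls only.

        p_j = (sum of observed dosages) / (2 * number of observed calls).
        """
        obs = ~np.isnan(self.dosages)
        n_obs = obs.sum(axis=0)
        if (n_obs == 0).any():
            bad = self.marker_ids[n_obs == 0]
            raise ValueError(f"markers with no observed calls: {list(bad[:5])}")
        return np.nansum(self.dosages, axis=0) / (2.0 * n_obs)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        sids = self.sample_ids
        meta = self.marker_meta
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx]
            sids = sids[sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            d = d[:, marker_idx]
            meta = meta.iloc[marker_idx]
        return GenotypeMatrix(d.copy(), sids.copy(), meta.reset_index(drop=True))


# ----------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------

def read_genotypes(path, fmt: str, map_path=None) -> GenotypeMatrix:
    """Read genotypes from ``vcf``, ``plink_text`` (.ped + .map) or ``tsv``.

    For ``plink_text``, ``path`` is the .ped file and ``map_path`` the
    matching .map file (defaults to ``path`` with a .map suffix).
    """
    if fmt == "vcf":
        return _read_vcf(str(path))
    if fmt == "plink_text":
        if map_path is None:
            map_path = re.sub(r"\.ped$", ".map", str(path))
        return _read_plink_text(str(path), str(map_path))
    if fmt == "tsv":
        return _read_tsv(str(path))
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {var.ID or var.CHROM + ':' + str(var.POS)}"
            )
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = np.asarray(var.gt_types, dtype=float)
        g[g == 3] = np.nan
        rows.append(g)
        meta.append(
            (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS), var.REF, var.ALT[0])
        )
    dos = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    mm = pd.DataFrame(meta, columns=["id", "chrom", "pos", "a1", "a2"])
    return GenotypeMatrix(dos, samples, mm)


def _read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    mm_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns")
            chrom, mid, _cm, pos = parts[:4]
            mm_rows.append((mid, chrom, int(pos)))
    m = len(mm_rows)

    sample_ids, geno_rows = [], []
    # first allele seen per marker defines the "first" allele; dosage counts
    # the SECOND allele, fixed below after all alleles are known
    alleles: list[dict] = [dict() for _ in range(m)]
    raw = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            raw.append(parts[6:])
            for j in range(m):
                for al in parts[6 + 2 * j : 8 + 2 * j]:
                    if al != "0":
                        alleles[j][al] = alleles[j].get(al, 0) + 1
    allele_pairs = []
    for j, cnt in enumerate(alleles):
        obs = sorted(cnt)  # lexicographic: deterministic first/second assignment
        if len(obs) > 2:
            raise ValueError(f"marker {mm_rows[j][0]} has >2 alleles")
        a1 = obs[0] if obs else "0"
        a2 = obs[1] if len(obs) > 1 else a1
        allele_pairs.append((a1, a2))
    dos = np.full((len(sample_ids), m), np.nan)
    for i, fields in enumerate(raw):
        for j in range(m):
            x, y = fields[2 * j], fields[2 * j + 1]
            if x == "0" or y == "0":
                continue  # "0 0" (or half-missing) stays missing
            a2 = allele_pairs[j][1]
            dos[i, j] = (x == a2) + (y == a2)
    mm = pd.DataFrame(
        [(mid, chrom, pos, p[0], p[1]) for (mid, chrom, pos), p in zip(mm_rows, allele_pairs)],
        columns=["id", "chrom", "pos", "a1", "a2"],
    )
    return GenotypeMatrix(dos, np.asarray(sample_ids, dtype=object), mm)


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dos = df.to_numpy(dtype=float)
    ids = df.columns.to_numpy(dtype=object)
    mm = pd.DataFrame(
        {
            "id": ids,
            "chrom": ["1"] * len(ids),  # dosage TSV carries no map: assume autosomal
            "pos": np.arange(1, len(ids) + 1),
            "a1": ["A"] * len(ids),
            "a2": ["B"] * len(ids),
        }
    )
    return GenotypeMatrix(dos, df.index.to_numpy(dtype=object), mm)


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

def write_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.marker_ids)
    out = df.where(~df.isna(), other=np.nan)
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, g.marker_ids)) + "\n")
        for sid, row in zip(g.sample_ids, out.to_numpy()):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


_VCF_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.sample_ids))
            + "\n"
        )
        meta = g.marker_meta
        for j in range(g.n_markers):
            row = meta.iloc[j]
            gts = [
                "./." if np.isnan(v) else _VCF_GT[v] for v in g.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['a1']}\t{row['a2']}"
                "\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )
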