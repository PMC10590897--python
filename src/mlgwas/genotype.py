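"""Genotype matrices: reading, writing, minor-allele orientation and MAF filtering.

Genotypes are held as a lines x SNPs minor-allele dosage matrix (0/1/2, with
``-1`` as the missing sentinel).  The minor allele is recomputed per dataset
from observed allele frequencies, never taken from the file's ref/alt order,
so MAF is always <= 0.5 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Lines x SNPs minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    line_ids : list of str
        Sample identifiers, one per row of ``dosages``.
    snp_ids : list of str
        Marker identifiers, one per column.
    dosages : ndarray of int8, shape (n_lines, n_snps)
        Minor-allele counts in {0, 1, 2}; ``-1`` marks a missing call.
    snp_meta : DataFrame indexed by snp_id
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    line_ids: list
    snp_ids: list
    dosages: np.ndarray
    snp_meta: pd.DataFrame
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.line_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids")
        if self.maf is None:
            self.maf = compute_maf(self)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (lines x SNPs, missing as NaN)."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        return pd.DataFrame(d, index=self.line_ids, columns=self.snp_ids)

    def imputed(self) -> pd.DataFrame:
        """Dosages with missing calls mean-imputed per SNP (for modelling)."""
        df = self.to_frame()
        n_miss = int(df.isna().to_numpy().sum())
        if n_miss:
            logger.info("mean-imputing %d missing dosage calls", n_miss)
            df = df.fillna(df.mean())
        return df

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            snp_ids=list(snp_ids),
            dosages=self.dosages[:, idx].copy(),
            snp_meta=self.snp_meta.loc[list(snp_ids)].copy(),
            maf=self.maf[idx].copy(),
        )


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency, missing calls excluded.

    MAF = min(f, 1 - f) with f = (sum of dosages) / (2 * non-missing lines).
    A SNP with every call missing gets NaN and is flagged in the log.
    """
    d = g.dosages.astype(float)
    miss = d == MISSING
    d[miss] = 0.0
    n_called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = d.sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    if np.any(n_called == 0):
        bad = [g.snp_ids[j] for j in np.where(n_called == 0)[0]]
        logger.warning("MAF undefined (all calls missing) for SNPs: %s", bad)
        maf[n_called == 0] = np.nan
    return maf


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05):
    """Drop SNPs with MAF strictly below ``threshold``.

    The boundary is kept: a SNP with MAF exactly equal to the threshold
    survives.  Returns the filtered matrix and the number of SNPs removed.
    """
    maf = g.maf if g.maf is not None else compute_maf(g)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    n_removed = g.n_snps - len(keep)
    if len(keep) == 0:
        raise ValueError(
            f"MAF filter at {threshold} removed all {g.n_snps} SNPs; "
            "review the threshold or the genotype data"
        )
    logger.info("MAF >= %s filter: kept %d / %d SNPs", threshold, len(keep), g.n_snps)
    out = GenotypeMatrix(
        line_ids=list(g.line_ids),
        snp_ids=[g.snp_ids[j] for j in keep],
        dosages=g.dosages[:, keep].copy(),
        snp_meta=g.snp_meta.iloc[keep].copy(),
        maf=maf[keep].copy(),
    )
    return out, n_removed


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip columns so the counted allele is the minor one (dataset-wide)."""
    d = dosages.astype(np.int8)
    miss = d == MISSING
    dd = d.astype(float)
    dd[miss] = np.nan
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dd, axis=1 if False else 0) / 2.0
    flip = f > 0.5
    d[:, flip] = 2 - d[:, flip]
    d[miss] = MISSING
    return d


def read_genotypes(path, format: str = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the dosage-CSV dialect.

    ``format`` is ``"vcf"`` or ``"dosage-csv"``; if omitted it is inferred
    from the file extension.  Multi-allelic VCF records are dropped (count
    logged); genotypes are re-oriented to minor-allele dosage.
    """
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "dosage-csv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    line_ids = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts = [], [], [], [], []
    cols = []
    n_multi = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        col = np.where(gt == 3, MISSING, np.where(gt == 2, 2, gt))
        cols.append(col.astype(np.int8))
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if n_multi:
        logger.info("dropped %d multi-allelic records from %s", n_multi, path)
    if not cols:
        raise ValueError(f"no biallelic SNPs parsed from {path}")
    dosages = _orient_minor(np.column_stack(cols))
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}, index=snp_ids
    )
    return GenotypeMatrix(line_ids, snp_ids, dosages, meta)


def _read_dosage_csv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas names the bad line
        raise ValueError(f"malformed dosage CSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"zero SNPs parsed from {path}")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, [0.0, 1.0, 2.0]))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"malformed dosage CSV {path}: non-dosage value {vals[r, c]!r} at "
            f"line {df.index[r]!r}, SNP {df.columns[c]!r}"
        )
    d = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    d = _orient_minor(d)
    snp_ids = list(df.columns)
    meta = pd.DataFrame(
        {"chrom": "0", "pos": np.arange(1, len(snp_ids) + 1), "ref": "A", "alt": "B"},
        index=snp_ids,
    )
    return GenotypeMatrix(list(df.index.astype(str)), snp_ids, d, meta)


def attach_metadata(g: GenotypeMatrix, meta_path) -> GenotypeMatrix:
    """Attach a SNP metadata TSV (snp_id, chrom, pos, ref, alt) to a matrix."""
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = [s for s in g.snp_ids if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for SNPs: {missing[:5]}...")
    g.snp_meta = meta.loc[g.snp_ids, ["chrom", "pos", "ref", "alt"]].copy()
    return g


def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    """Write the dosage-CSV dialect: header of snp_ids, first column line_id."""
    df = g.to_frame()
    out = df.astype("Int64")  # keeps 0/1/2 integral, missing as empty cell
    out.index.name = "line_id"
    out.to_csv(path)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with one sample per line and GT calls.

    Dosage d is emitted as an unphased genotype with d copies of the ALT
    allele, where ALT is the minor allele (the matrix orientation).
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(g.snp_meta["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.line_ids))
            + "\n"
        )
        for j, sid in enumerate(g.snp_ids):
            m = g.snp_meta.iloc[j]
            calls = "\t".join(gt_map[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{sid}\t{m['ref']}\t{m['alt']}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )
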