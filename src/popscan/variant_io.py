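"""VCF input and the population-genetic variant filters.

Only biallelic SNPs enter the genotype model: multiallelic rows, indels and
symbolic alleles are dropped at read time (not split). Downstream filters are
the standard resequencing-panel pair — minor allele frequency strictly above
0.05 and per-variant missing-call fraction strictly below 0.20 — applied to
non-missing calls only, the PLINK/VCFtools convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, FilterReport, GenotypeMatrix

__all__ = [
    "read_sample_sheet",
    "read_vcf",
    "filter_variants",
    "group_allele_frequencies",
]

_BASES = {"A", "C", "G", "T"}


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the ``sample_id / group / clone_of`` TSV written by the simulator."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must contain columns {sorted(required)}")
    if "clone_of" not in df.columns:
        df["clone_of"] = ""
    return df


def _is_biallelic_snp(ref: str, alts: list[str]) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return ref in _BASES and alt in _BASES


def read_vcf(path: str | Path, sample_sheet_path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Rows that are not simple biallelic SNPs are skipped and counted in
    ``n_non_biallelic_dropped``. Genotypes are parsed unphased ('/' and '|'
    equivalent); half-calls such as ``./1`` are treated as missing. Every VCF
    sample must appear in the sample sheet.
    """
    sheet = read_sample_sheet(sample_sheet_path)
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in group_of]
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {unknown}")

    seqlens = None
    if vcf.seqnames and vcf.seqlens:
        seqlens = dict(zip(vcf.seqnames, (int(x) for x in vcf.seqlens)))

    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        if not _is_biallelic_snp(var.REF, var.ALT):
            n_dropped += 1
            continue
        alleles = np.asarray(var.genotypes, dtype=np.int16)[:, :2]
        dosage = alleles.sum(axis=1).astype(np.int8)
        dosage[(alleles < 0).any(axis=1)] = MISSING
        chroms.append(var.CHROM)
        positions.append(var.POS)
        columns.append(dosage)
    vcf.close()

    if not columns:
        raise ValueError(f"no biallelic SNPs found in {path}")

    gm = GenotypeMatrix(
        samples=samples,
        groups=np.asarray([group_of[s] for s in samples], dtype=object),
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        dosages=np.stack(columns, axis=1),
        chrom_lengths=seqlens,
        n_non_biallelic_dropped=n_dropped,
    )
    gm.validate()
    return gm


def _maf_and_missing(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    miss = gm.dosages == MISSING
    n_called = (~miss).sum(axis=0)
    alt = np.where(miss, 0, gm.dosages).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    missing_frac = miss.sum(axis=0) / gm.n_samples
    return maf, missing_frac


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.20,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep variants with folded MAF strictly above ``maf_min`` and missing
    fraction strictly below ``max_missing``; boundary values are removed.

    MAF is computed over non-missing calls; an all-missing variant has
    undefined MAF and is removed on the missingness rule. A variant failing
    both rules is counted once, under the MAF removal.
    """
    maf, missing_frac = _maf_and_missing(gm)
    maf_ok = np.nan_to_num(maf, nan=-1.0) > maf_min
    miss_ok = missing_frac < max_missing
    keep = maf_ok & miss_ok

    report = FilterReport(
        n_input=gm.n_variants + gm.n_non_biallelic_dropped,
        n_non_biallelic_removed=gm.n_non_biallelic_dropped,
        n_maf_removed=int((~maf_ok).sum()),
        n_missing_removed=int((maf_ok & ~miss_ok).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        warnings.warn("all variants removed by filtering")
    out = gm.subset_variants(keep)
    out.n_non_biallelic_dropped = 0
    return out, report


def group_allele_frequencies(gm: GenotypeMatrix, group: str) -> np.ndarray:
    """Alternate-allele frequency per variant within one group.

    Frequency is alt-dosage sum over twice the non-missing sample count;
    variants where the whole group is missing return NaN so consumers can
    skip them.
    """
    idx = gm.group_indices(group)
    sub = gm.dosages[idx]
    miss = sub == MISSING
    n_called = (~miss).sum(axis=0)
    alt = np.where(miss, 0, sub).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
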