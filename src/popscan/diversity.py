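"""Sliding-window nucleotide diversity and Weir-Cockerham FST.

Per-site diversity uses the unbiased estimator: with k non-missing diploid
calls and alt frequency p-hat, pi_site = (2k/(2k-1)) * 2 * p-hat * (1-p-hat),
which equals the mean pairwise difference among the 2k sampled alleles.
Window pi is the sum of per-site values divided by the *full* window length
in bp (monomorphic and unsampled positions contribute zero) — the VCFtools
``--window-pi`` convention, and the only one consistent with per-bp values
orders of magnitude below per-SNP heterozygosity.

FST follows Weir & Cockerham's 1984 moment estimator for two populations:
per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) are computed from sample
sizes, allele frequencies and observed heterozygote fractions; a window
estimate is the ratio of sums, sum(a) / sum(a+b+c). Raw estimates can be
negative by sampling variance; truncation to zero happens per window before
any genome-wide averaging.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, WindowSpec

__all__ = [
    "make_windows",
    "windowed_pi",
    "windowed_wc_fst",
    "window_stats",
    "genomewide_summary",
    "fst_pair_column",
    "pi_column",
]


def pi_column(group: str) -> str:
    return f"pi_{group}"


def fst_pair_column(a: str, b: str, truncated: bool = False) -> str:
    stem = f"{a}_vs_{b}"
    return f"fst_trunc_{stem}" if truncated else f"fst_{stem}"


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

def make_windows(
    chrom_lengths: list[tuple[str, int]] | dict[str, int],
    spec: WindowSpec = WindowSpec(),
    full_only: bool = False,
) -> pd.DataFrame:
    """Enumerate sliding windows per chromosome.

    Windows start at 1, 1+step, 1+2*step, ... while the start lies on the
    chromosome; terminal windows are clipped to the chromosome end and
    flagged ``full=False``. ``full_only`` drops clipped windows (the default
    input to the selection scan, which compares equal-length windows).
    """
    if isinstance(chrom_lengths, dict):
        chrom_lengths = list(chrom_lengths.items())
    frames = []
    for chrom, length in chrom_lengths:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(1, length + 1, spec.step, dtype=np.int64)
        ends = np.minimum(starts + spec.size - 1, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "full": ends - starts + 1 == spec.size,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if full_only:
        out = out[out["full"]].reset_index(drop=True)
    return out


def _window_sums(pos: np.ndarray, values: np.ndarray, starts, ends) -> np.ndarray:
    """Sum ``values`` over variants with start <= pos <= end, per window."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    return csum[hi] - csum[lo]


# --------------------------------------------------------------------------
# per-site group summaries
# --------------------------------------------------------------------------

def _group_site_stats(gm: GenotypeMatrix, group: str):
    """Per-variant (n non-missing diploid calls, alt frequency, het fraction)."""
    sub = gm.dosages[gm.group_indices(group)]
    miss = sub == MISSING
    n = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, sub).sum(axis=0).astype(float)
    het = (sub == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def _site_pi(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Unbiased per-site diversity; zero where fewer than 2 calls."""
    with np.errstate(invalid="ignore"):
        pi = (2.0 * n / (2.0 * n - 1.0)) * 2.0 * p * (1.0 - p)
    pi = np.where(n >= 2, pi, 0.0)
    return np.nan_to_num(pi, nan=0.0)


def _site_wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham 1984 per-site components a and a+b+c for two samples.

    Sites where either sample has fewer than 2 calls are zeroed out (they
    contribute nothing to either sum).
    """
    usable = (n1 >= 2) & (n2 >= 2)
    n1 = np.where(usable, n1, 2.0)
    n2 = np.where(usable, n2, 2.0)
    p1 = np.nan_to_num(p1)
    p2 = np.nan_to_num(p2)
    h1 = np.nan_to_num(h1)
    h2 = np.nan_to_num(h2)

    nsum = n1 + n2
    nbar = nsum / 2.0
    nc = nsum - (n1 * n1 + n2 * n2) / nsum
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / nsum

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    a = np.where(usable, a, 0.0)
    abc = np.where(usable, a + b + c, 0.0)
    return a, abc


# --------------------------------------------------------------------------
# windowed statistics
# --------------------------------------------------------------------------

def _per_chrom(gm: GenotypeMatrix, windows: pd.DataFrame, site_values, combine):
    """Apply a per-chromosome window reduction over precomputed site arrays."""
    out = np.full(len(windows), np.nan)
    for chrom, sl in gm.chrom_blocks():
        wmask = (windows["chrom"] == chrom).to_numpy()
        if not wmask.any():
            continue
        pos = gm.positions[sl]
        starts = windows.loc[wmask, "start"].to_numpy()
        ends = windows.loc[wmask, "end"].to_numpy()
        sums = [_window_sums(pos, v[sl], starts, ends) for v in site_values]
        out[wmask] = combine(starts, ends, *sums)
    return out


def windowed_pi(gm: GenotypeMatrix, group: str, windows: pd.DataFrame) -> np.ndarray:
    """Per-bp nucleotide diversity of one group, one value per window."""
    if len(gm.group_indices(group)) < 2:
        return np.full(len(windows), np.nan)
    n, p, _ = _group_site_stats(gm, group)
    site = _site_pi(n, p)

    def combine(starts, ends, pi_sum):
        return pi_sum / (ends - starts + 1)

    return _per_chrom(gm, windows, [site], combine)


def windowed_wc_fst(
    gm: GenotypeMatrix,
    group_a: str,
    group_b: str,
    windows: pd.DataFrame,
    ratio_of_sums: bool = True,
) -> np.ndarray:
    """Raw (untruncated) Weir-Cockerham FST per window between two groups.

    Default is the ratio-of-sums ("weighted") window estimate; with
    ``ratio_of_sums=False`` the mean of per-site ratios is returned instead.
    Windows with zero total variance are NaN.
    """
    if group_a == group_b:
        raise ValueError("FST requires two distinct groups")
    sa = _group_site_stats(gm, group_a)
    sb = _group_site_stats(gm, group_b)
    a, abc = _site_wc_components(*sa, *sb)

    if ratio_of_sums:
        def combine(starts, ends, a_sum, abc_sum):
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(abc_sum != 0.0, a_sum / abc_sum, np.nan)

        return _per_chrom(gm, windows, [a, abc], combine)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(abc != 0.0, a / abc, np.nan)
    defined = np.isfinite(ratio)

    def combine(starts, ends, ratio_sum, count):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, ratio_sum / count, np.nan)

    return _per_chrom(
        gm, windows, [np.nan_to_num(ratio), defined.astype(float)], combine
    )


def window_stats(
    gm: GenotypeMatrix,
    windows: pd.DataFrame | None = None,
    spec: WindowSpec = WindowSpec(),
    full_only: bool = True,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Window table with n_snps, per-group pi, and raw + truncated pairwise FST.

    Columns: chrom, start, end, full, n_snps, ``pi_<group>`` for each group,
    and ``fst_<a>_vs_<b>`` / ``fst_trunc_<a>_vs_<b>`` for every unordered
    group pair.
    """
    if groups is None:
        groups = gm.group_labels()
    if windows is None:
        lengths = [(c, gm.chrom_length(c)) for c, _ in gm.chrom_blocks()]
        windows = make_windows(lengths, spec, full_only=full_only)
    out = windows.reset_index(drop=True).copy()

    ones = np.ones(gm.n_variants)

    def count(starts, ends, s):
        return s

    out["n_snps"] = _per_chrom(gm, out, [ones], count).astype(int)
    for g in groups:
        out[pi_column(g)] = windowed_pi(gm, g, out)
    for a, b in combinations(groups, 2):
        raw = windowed_wc_fst(gm, a, b, out)
        out[fst_pair_column(a, b)] = raw
        out[fst_pair_column(a, b, truncated=True)] = np.where(
            np.isnan(raw), np.nan, np.maximum(raw, 0.0)
        )
    return out


def genomewide_summary(stats: pd.DataFrame) -> dict[str, float]:
    """Unweighted genome-wide means over defined windows.

    Returns ``mean_pi_<group>`` for each pi column and
    ``mean_fst_<a>_vs_<b>`` for each *truncated* FST column (truncation is
    applied per window before averaging; undefined windows are excluded from
    both numerator and denominator).
    """
    out: dict[str, float] = {}
    for col in stats.columns:
        if col.startswith("pi_"):
            out[f"mean_{col}"] = float(np.nanmean(stats[col].to_numpy()))
        elif col.startswith("fst_trunc_"):
            key = "mean_fst_" + col[len("fst_trunc_"):]
            out[key] = float(np.nanmean(stats[col].to_numpy()))
    return out
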