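"""Linkage disequilibrium: pairwise genotype r-squared and decay curves.

r-squared here is the squared Pearson correlation of dosage vectors
(the "composite" unphased measure PLINK reports), computed over mutually
non-missing samples of a pair. Pairs where either vector has zero variance
on the shared samples are skipped. Curves are per group by default; on
unlinked loci the null expectation of r-squared is about 1/n for n samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

__all__ = ["pairwise_r2", "decay_curve", "r2_matrix"]


def _cross_stats(va, ma, vb, mb):
    """Pairwise sufficient statistics over joint non-missing samples.

    ``va, vb`` are variants x samples dosage arrays with missing entries
    zeroed; ``ma, mb`` the matching non-missing indicators.
    """
    n = ma @ mb.T
    sa = va @ mb.T
    sb = ma @ vb.T
    sab = va @ vb.T
    saa = (va * va) @ mb.T
    sbb = ma @ (vb * vb).T
    cov = n * sab - sa * sb
    var_a = n * saa - sa * sa
    var_b = n * sbb - sb * sb
    return n, cov, var_a, var_b


def r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Full pairwise r-squared among the columns of a samples x variants
    dosage block (missing = MISSING). Undefined pairs are NaN."""
    v = dosages.T.astype(float)
    m = (v != MISSING).astype(float)
    v = np.where(v == MISSING, 0.0, v)
    n, cov, var_a, var_b = _cross_stats(v, m, v, m)
    denom = var_a * var_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((denom > 0) & (n >= 2), (cov * cov) / denom, np.nan)
    np.fill_diagonal(r2, np.nan)
    return r2


def pairwise_r2(
    gm: GenotypeMatrix,
    group: str | None = None,
    max_dist_bp: int = 1_000_000,
    chunk: int = 512,
) -> pd.DataFrame:
    """All same-chromosome SNP pairs within ``max_dist_bp``.

    Returns a frame with columns ``chrom, dist, r2`` (one row per retained
    pair). ``group=None`` uses the whole panel.
    """
    rows = (
        gm.group_indices(group) if group is not None else np.arange(gm.n_samples)
    )
    if rows.size < 2:
        raise ValueError("need at least 2 samples for r2")
    frames = []
    for chrom, sl in gm.chrom_blocks():
        pos = gm.positions[sl]
        v_all = gm.dosages[rows, sl].astype(float).T  # variants x samples
        m_all = (v_all != MISSING).astype(float)
        v_all = np.where(v_all == MISSING, 0.0, v_all)
        m_var = pos.size
        for i0 in range(0, m_var, chunk):
            i1 = min(i0 + chunk, m_var)
            j1 = int(np.searchsorted(pos, pos[i1 - 1] + max_dist_bp, side="right"))
            n, cov, var_a, var_b = _cross_stats(
                v_all[i0:i1], m_all[i0:i1], v_all[i0:j1], m_all[i0:j1]
            )
            denom = var_a * var_b
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where((denom > 0) & (n >= 2), (cov * cov) / denom, np.nan)
            dist = pos[None, i0:j1] - pos[i0:i1, None]
            keep = (dist > 0) & (dist <= max_dist_bp) & np.isfinite(r2)
            if keep.any():
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "dist": dist[keep].astype(np.int64),
                            "r2": r2[keep],
                        }
                    )
                )
    if not frames:
        return pd.DataFrame({"chrom": [], "dist": [], "r2": []})
    return pd.concat(frames, ignore_index=True)


def decay_curve(pairs: pd.DataFrame, bin_width_bp: int = 10_000) -> pd.DataFrame:
    """Distance-binned mean r-squared.

    Bins are [0, w), [w, 2w), ... up to the largest observed distance; empty
    bins carry NaN means and zero counts so the curve is contiguous.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to bin")
    dist = pairs["dist"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    n_bins = int(dist.max() // bin_width_bp) + 1
    idx = (dist // bin_width_bp).astype(np.intp)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins, dtype=np.int64) * bin_width_bp,
            "bin_end": (np.arange(n_bins, dtype=np.int64) + 1) * bin_width_bp,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
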