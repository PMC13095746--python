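"""Composite diversity-differentiation selection scan.

For every sliding window the scan combines two signals across the panel's
groups: log2(pi_max / pi_min), the diversity contrast between the most and
least diverse group, and FSTmax, the maximum of the pairwise (truncated)
window FST values, additionally reported as a Z-score over all included
windows. Candidate windows exceed the empirical top-1% threshold of *both*
metrics simultaneously; runs of overlapping-or-bookended candidate windows
are merged into candidate intervals — the sweep-like regions a follow-up
study would prioritise.

A window where the least diverse group is monomorphic (pi_min = 0 while
pi_max > 0) has an infinite log2 ratio. Rather than adding an arbitrary
pseudocount, such windows carry +inf and rank above every finite value; the
ratio threshold is an order statistic (the "higher" empirical quantile), so
a handful of infinities cannot make the threshold itself infinite unless
more than 1% of windows are monomorphic somewhere.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import write_tsv
from .diversity import fst_pair_column

__all__ = [
    "composite_metrics",
    "call_candidates",
    "merge_candidates",
    "scan_report",
]


def _pi_cols(stats: pd.DataFrame) -> list[str]:
    return [c for c in stats.columns if c.startswith("pi_")]


def _fst_trunc_cols(stats: pd.DataFrame) -> list[str]:
    return [c for c in stats.columns if c.startswith("fst_trunc_")]


def composite_metrics(stats: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-window composite metrics from a window-statistics table.

    Windows lacking defined pi for at least two groups or lacking every
    pairwise FST are excluded; the number excluded is returned alongside the
    metric table. Raises on a degenerate scan where FSTmax does not vary.
    """
    pi_cols = _pi_cols(stats)
    fst_cols = _fst_trunc_cols(stats)
    if len(pi_cols) < 2 or not fst_cols:
        raise ValueError("window table lacks per-group pi or pairwise FST columns")

    pi = stats[pi_cols].to_numpy(float)
    fst = stats[fst_cols].to_numpy(float)
    n_pi_defined = np.isfinite(pi).sum(axis=1)
    n_fst_defined = np.isfinite(fst).sum(axis=1)
    included = (n_pi_defined >= 2) & (n_fst_defined >= 1)
    n_excluded = int((~included).sum())

    rows = stats.loc[included, ["chrom", "start", "end"]].reset_index(drop=True)
    pi = pi[included]
    fst = fst[included]

    pi_max = np.nanmax(pi, axis=1)
    pi_min = np.nanmin(pi, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pi_max / pi_min)
    ratio = np.where(pi_max == pi_min, 0.0, ratio)  # includes the all-zero case
    ratio = np.where((pi_min == 0.0) & (pi_max > 0.0), np.inf, ratio)

    fst_max = np.nanmax(fst, axis=1)
    which = np.nanargmax(fst, axis=1)
    pair_label = [fst_cols[k][len("fst_trunc_"):] for k in which]
    sd = float(np.std(fst_max))
    if sd == 0.0:
        raise ValueError("degenerate scan: FSTmax identical across all windows")
    z = (fst_max - float(np.mean(fst_max))) / sd

    rows["pi_max"] = pi_max
    rows["pi_min"] = pi_min
    rows["log2_pi_ratio"] = ratio
    rows["fst_max"] = fst_max
    rows["fst_max_pair"] = pair_label
    rows["z_fst_max"] = z
    return rows, n_excluded


def _upper_quantile(values: np.ndarray, quantile: float) -> float:
    """Empirical quantile as an order statistic (numpy's 'higher' method), so
    infinite entries only surface when they exceed the chosen rank."""
    return float(np.quantile(values, quantile, method="higher"))


def call_candidates(rows: pd.DataFrame, quantile: float = 0.99) -> tuple[pd.DataFrame, dict]:
    """Flag windows at or above the empirical ``quantile`` of both metrics.

    Returns the table with an ``is_candidate`` column plus the thresholds
    actually applied (including the Z-scale equivalent of the FSTmax cut).
    """
    if len(rows) < 100:
        raise ValueError("need at least 100 windows for a meaningful top-1% call")
    ratio_thr = _upper_quantile(rows["log2_pi_ratio"].to_numpy(), quantile)
    fst_thr = _upper_quantile(rows["fst_max"].to_numpy(), quantile)
    out = rows.copy()
    out["is_candidate"] = (out["log2_pi_ratio"] >= ratio_thr) & (
        out["fst_max"] >= fst_thr
    )
    z = out["z_fst_max"].to_numpy()
    fst = out["fst_max"].to_numpy()
    sd = float(np.std(fst))
    z_thr = (fst_thr - float(np.mean(fst))) / sd if sd > 0 else np.nan
    thresholds = {
        "quantile": quantile,
        "log2_pi_ratio_threshold": ratio_thr,
        "fst_max_threshold": fst_thr,
        "z_fst_max_threshold": z_thr,
    }
    return out, thresholds


def merge_candidates(
    rows: pd.DataFrame, stats: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge adjacent candidate windows into candidate intervals.

    Consecutive candidate windows on one chromosome merge while they overlap
    or are bookended (next start <= current end + 1); the interval span is
    the union of member windows. When the full window-statistics table is
    supplied, each interval also reports per-group pi ranges and the maximum
    pairwise FST with its pair label over member windows.
    """
    cand = rows.loc[rows.get("is_candidate", False)].sort_values(
        ["chrom", "start"], kind="stable"
    )
    intervals: list[dict] = []
    for _, w in cand.iterrows():
        if (
            intervals
            and intervals[-1]["chrom"] == w["chrom"]
            and w["start"] <= intervals[-1]["end"] + 1
        ):
            iv = intervals[-1]
            iv["end"] = max(iv["end"], int(w["end"]))
            iv["n_windows"] += 1
            iv["members"].append(w)
        else:
            intervals.append(
                {
                    "chrom": w["chrom"],
                    "start": int(w["start"]),
                    "end": int(w["end"]),
                    "n_windows": 1,
                    "members": [w],
                }
            )

    records = []
    for iv in intervals:
        rec = {
            "chrom": iv["chrom"],
            "start": iv["start"],
            "end": iv["end"],
            "span_bp": iv["end"] - iv["start"] + 1,
            "n_windows": iv["n_windows"],
            "max_z_fst_max": max(float(m["z_fst_max"]) for m in iv["members"]),
        }
        if stats is not None:
            starts = {int(m["start"]) for m in iv["members"]}
            members = stats[
                (stats["chrom"] == iv["chrom"]) & stats["start"].isin(starts)
            ]
            for col in _pi_cols(stats):
                rec[f"{col}_min"] = float(np.nanmin(members[col]))
                rec[f"{col}_max"] = float(np.nanmax(members[col]))
            fst_cols = _fst_trunc_cols(stats)
            sub = members[fst_cols].to_numpy(float)
            flat = np.nanargmax(sub)
            r, c = np.unravel_index(flat, sub.shape)
            rec["max_fst"] = float(sub[r, c])
            rec["max_fst_pair"] = fst_cols[c][len("fst_trunc_"):]
        records.append(rec)
    return pd.DataFrame(records)


def scan_report(
    rows: pd.DataFrame,
    intervals: pd.DataFrame,
    thresholds: dict,
    out_dir: str | Path,
    n_excluded: int = 0,
) -> dict[str, float]:
    """Write ``windows.tsv``, ``intervals.tsv`` and ``summary.txt``; returns
    the genome-wide summary values it printed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {k: v for k, v in thresholds.items()}
    meta["n_windows_excluded"] = n_excluded
    write_tsv(rows, out_dir / "windows.tsv", meta=meta)
    iv = intervals if len(intervals) else pd.DataFrame(
        columns=["chrom", "start", "end", "span_bp", "n_windows", "max_z_fst_max"]
    )
    write_tsv(iv, out_dir / "intervals.tsv", meta=meta)

    summary = {
        "n_windows": float(len(rows)),
        "n_candidates": float(int(rows["is_candidate"].sum())),
        "n_intervals": float(len(intervals)),
        "median_fst_max": float(np.median(rows["fst_max"])),
        "fst_max_threshold": float(thresholds["fst_max_threshold"]),
        "z_fst_max_threshold": float(thresholds["z_fst_max_threshold"]),
    }
    with open(out_dir / "summary.txt", "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value:.6g}\n")
    return summary
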