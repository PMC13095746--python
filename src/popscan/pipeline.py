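"""End-to-end orchestration: simulate/load -> filter -> stats -> structure
-> LD -> scan, with one config, derived per-stage seeds, and a run manifest.

The global seed never feeds a shared RNG: each stage derives its own seed by
hashing the stage name, so inserting a stage cannot perturb the draws of the
stages after it. Every output table carries its parameters as ``#key=value``
header lines, making each stage re-runnable in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, ld, scan, structure, variant_io
from ._utils import sha256_file, stage_seed, write_tsv
from .datatypes import GenotypeMatrix, InvalidConfigError, WindowSpec
from .simulate import (
    LDBlockSpec,
    SimulationConfig,
    SweepSpec,
    simulate_panel,
    write_simulation,
)

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """One reproducible run: either input files or a simulation, never both."""

    out_dir: str
    seed: int = 0
    vcf: str | None = None
    sample_sheet: str | None = None
    simulation: SimulationConfig | None = None
    maf_min: float = 0.05
    max_missing: float = 0.20
    window: WindowSpec = field(default_factory=WindowSpec)
    prune: tuple[int, int, float] = (50, 5, 0.2)
    kinship_threshold: float = 0.45
    ld_max_dist: int = 1_000_000
    ld_bin: int = 10_000
    scan_quantile: float = 0.99

    def validate(self) -> None:
        has_files = self.vcf is not None or self.sample_sheet is not None
        if has_files and self.simulation is not None:
            raise InvalidConfigError("config must give input files OR a simulation, not both")
        if not has_files and self.simulation is None:
            raise InvalidConfigError("config gives neither input files nor a simulation")
        if has_files and (self.vcf is None or self.sample_sheet is None):
            raise InvalidConfigError("both --vcf and --sheet are required for file input")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (see README for the layout)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = None
    if "simulation" in raw:
        s = dict(raw["simulation"])
        if "sweep" in s and s["sweep"] is not None:
            s["sweep"] = SweepSpec(**s["sweep"])
        if "ld_block" in s and s["ld_block"] is not None:
            s["ld_block"] = LDBlockSpec(**s["ld_block"])
        if "chrom_lengths" in s:
            s["chrom_lengths"] = [tuple(x) for x in s["chrom_lengths"]]
        if "admixture_props" in s and s["admixture_props"] is not None:
            s["admixture_props"] = np.asarray(s["admixture_props"], dtype=float)
        sim = SimulationConfig(**s)
    window = WindowSpec(**raw.get("window", {}))
    kwargs = {
        k: raw[k]
        for k in (
            "out_dir",
            "seed",
            "vcf",
            "sample_sheet",
            "maf_min",
            "max_missing",
            "kinship_threshold",
            "ld_max_dist",
            "ld_bin",
            "scan_quantile",
        )
        if k in raw
    }
    if "prune" in raw:
        kwargs["prune"] = tuple(raw["prune"])
    return RunConfig(simulation=sim, window=window, **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    stage = "init"
    try:
        # ---------------------------------------------------------- input
        if config.simulation is not None:
            stage = "simulate"
            sim = config.simulation
            sim.seed = stage_seed(config.seed, "simulate")
            panel = simulate_panel(sim)
            vcf_path, sheet_path = write_simulation(panel, out / "sim")
            manifest["stages"]["simulate"] = {
                "n_samples": panel.gm.n_samples,
                "n_variants": panel.gm.n_variants,
                "sweep_truth": asdict(panel.sweep_truth) if panel.sweep_truth else None,
            }
        else:
            vcf_path, sheet_path = Path(config.vcf), Path(config.sample_sheet)
        manifest["inputs"] = {
            "vcf": {"path": str(vcf_path), "sha256": sha256_file(vcf_path)},
            "sample_sheet": {"path": str(sheet_path), "sha256": sha256_file(sheet_path)},
        }

        # --------------------------------------------------------- filter
        stage = "filter"
        gm = variant_io.read_vcf(vcf_path, sheet_path)
        gm, report = variant_io.filter_variants(gm, config.maf_min, config.max_missing)
        write_tsv(
            pd.DataFrame([report.to_dict()]),
            out / "filter_report.tsv",
            meta={"maf_min": config.maf_min, "max_missing": config.max_missing},
        )
        manifest["stages"]["filter"] = report.to_dict()

        # ---------------------------------------------------------- stats
        stage = "stats"
        stats = diversity.window_stats(gm, spec=config.window, full_only=True)
        write_tsv(
            stats,
            out / "window_stats.tsv",
            meta={"window_size": config.window.size, "window_step": config.window.step},
        )
        summary = diversity.genomewide_summary(stats)
        write_tsv(
            pd.DataFrame(sorted(summary.items()), columns=["statistic", "value"]),
            out / "genomewide_summary.tsv",
        )
        manifest["stages"]["stats"] = {"n_windows": len(stats), **summary}

        # ------------------------------------------------------ structure
        stage = "structure"
        w, s, r2t = config.prune
        pruned, _ = structure.ld_prune(gm, w, s, r2t)
        dm = structure.pairwise_distance(pruned)
        newick = structure.neighbor_joining(dm)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        coords, pct = structure.pca(pruned)
        coords_out = coords.reset_index(names="sample_id")
        write_tsv(
            coords_out,
            out / "pca_coords.tsv",
            meta={"pct_variance": ",".join(f"{x:.6g}" for x in pct)},
        )
        kin = structure.grm_kinship(gm)
        write_tsv(
            pd.DataFrame(kin.values, index=kin.ids, columns=kin.ids).reset_index(
                names="sample_id"
            ),
            out / "kinship.tsv",
        )
        flagged, retained = structure.high_kinship_prune(kin, config.kinship_threshold)
        off = kin.values[np.triu_indices(len(kin.ids), k=1)]
        manifest["stages"]["structure"] = {
            "n_pruned_snps": pruned.n_variants,
            "pc_pct_variance": [float(x) for x in pct[:3]],
            "kinship_median": float(np.median(off)),
            "kinship_max": float(off.max()),
            "n_high_kinship_pairs": len(flagged),
            "n_retained_after_kinship_prune": len(retained),
        }

        # --------------------------------------------------------------- ld
        stage = "ld"
        curves = []
        for g in gm.group_labels():
            pairs = ld.pairwise_r2(gm, g, max_dist_bp=config.ld_max_dist)
            if len(pairs) == 0:
                continue
            curve = ld.decay_curve(pairs, bin_width_bp=config.ld_bin)
            curve.insert(0, "group", g)
            curves.append(curve)
        ld_table = pd.concat(curves, ignore_index=True)
        write_tsv(
            ld_table,
            out / "ld_decay.tsv",
            meta={"max_dist_bp": config.ld_max_dist, "bin_width_bp": config.ld_bin},
        )
        manifest["stages"]["ld"] = {"n_bins": len(ld_table)}

        # -------------------------------------------------------------- scan
        stage = "scan"
        rows, n_excluded = scan.composite_metrics(stats)
        rows, thresholds = scan.call_candidates(rows, config.scan_quantile)
        intervals = scan.merge_candidates(rows, stats)
        scan_summary = scan.scan_report(
            rows, intervals, thresholds, out / "scan", n_excluded=n_excluded
        )
        manifest["stages"]["scan"] = scan_summary

    except Exception as exc:  # mark partial outputs, re-raise with stage tag
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = sha256_file(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
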