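"""Structured-population genotype simulation with known truth.

The generator emulates a resequenced germplasm panel of four partially
differentiated groups: per-group allele frequencies follow the
Balding-Nichols model (group frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around
an ancestral frequency p), so that the expected pairwise Weir-Cockerham FST
between two groups with drift parameters F1 and F2 is approximately
(F1 + F2) / 2. On top of the group layer it supports admixed individuals
(each allele draws its group of origin from the sample's admixture
proportions), exact clone/duplicate pairs, per-call missingness, an optional
LD-block mode producing distance-decaying r-squared, and a planted selective
sweep: an interval made monomorphic in exactly one group, the signature a
diversity/differentiation scan should recover.

Loci are unlinked and positions uniform by default; there is no coalescent
or recombination-map realism, which is irrelevant for the window statistics
tested here but means haplotype-based statistics would be meaningless on
this output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, InvalidConfigError

__all__ = [
    "SweepSpec",
    "LDBlockSpec",
    "SimulationConfig",
    "FrequencyTable",
    "SimulatedPanel",
    "simulate_group_frequencies",
    "simulate_genotypes",
    "plant_sweep",
    "simulate_panel",
    "write_simulation",
    "default_panel_config",
]


@dataclass
class SweepSpec:
    """A planted sweep: interval [start, end] (1-based, inclusive) made
    monomorphic in the group at ``group_index``."""

    chrom: str
    start: int
    end: int
    group_index: int


@dataclass
class LDBlockSpec:
    """LD-block mode: each seed variant spawns ``copies`` satellite variants
    spread over ``span_bp``; each copy is derived from the previous one by
    redrawing a fraction ``flip_prob`` of samples from their group frequency,
    so r-squared decays geometrically with copy distance."""

    copies: int = 4
    span_bp: int = 50_000
    flip_prob: float = 0.05


@dataclass
class SimulationConfig:
    """Full description of one simulated panel.

    ``drift_F`` is one Balding-Nichols drift parameter per group, strictly in
    (0, 1). ``admixture_props`` has one row per admixed sample, summing to 1
    over groups. ``min_maf`` controls resampling of near-monomorphic loci at
    the frequency stage so the post-filter SNP count is predictable.
    """

    samples_per_group: list[int]
    chrom_lengths: list[tuple[str, int]]
    n_variants_per_chrom: int
    drift_F: list[float]
    n_groups: int = 4
    group_names: list[str] | None = None
    n_admixed: int = 0
    admixture_props: np.ndarray | None = None
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    min_maf: float = 0.01
    sweep: SweepSpec | None = None
    clone_pairs: int = 0
    missing_rate: float = 0.0
    ld_block: LDBlockSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_names is None:
            self.group_names = [f"G{i + 1}" for i in range(self.n_groups)]
        self.validate()

    def validate(self) -> None:
        if self.n_groups < 1:
            raise InvalidConfigError("need at least one group")
        if len(self.samples_per_group) != self.n_groups:
            raise InvalidConfigError("samples_per_group must have one entry per group")
        if len(self.drift_F) != self.n_groups:
            raise InvalidConfigError("drift_F must have one entry per group")
        if any(not (0.0 < f < 1.0) for f in self.drift_F):
            raise InvalidConfigError("drift_F values must lie strictly in (0, 1)")
        if self.n_variants_per_chrom <= 0:
            raise InvalidConfigError("n_variants_per_chrom must be positive")
        if not self.chrom_lengths:
            raise InvalidConfigError("at least one chromosome required")
        for chrom, length in self.chrom_lengths:
            if length <= 0:
                raise InvalidConfigError(f"chromosome {chrom!r} has non-positive length")
            if length < self.n_variants_per_chrom:
                raise InvalidConfigError(
                    f"chromosome {chrom!r} too short for {self.n_variants_per_chrom} variants"
                )
        if self.n_admixed:
            props = np.asarray(self.admixture_props, dtype=float)
            if props.shape != (self.n_admixed, self.n_groups):
                raise InvalidConfigError(
                    "admixture_props must be (n_admixed, n_groups)"
                )
            if np.any(np.abs(props.sum(axis=1) - 1.0) > 1e-9):
                raise InvalidConfigError("admixture_props rows must sum to 1")
            self.admixture_props = props
        if not (0.0 <= self.missing_rate < 1.0):
            raise InvalidConfigError("missing_rate must lie in [0, 1)")
        if self.sweep is not None:
            lengths = dict(self.chrom_lengths)
            sw = self.sweep
            if sw.chrom not in lengths:
                raise InvalidConfigError(f"sweep chromosome {sw.chrom!r} not simulated")
            if not (1 <= sw.start <= sw.end <= lengths[sw.chrom]):
                raise InvalidConfigError("sweep interval outside its chromosome")
            if not (0 <= sw.group_index < self.n_groups):
                raise InvalidConfigError("sweep group index out of range")


@dataclass
class FrequencyTable:
    """Per-variant ancestral and per-group alternate-allele frequencies."""

    chroms: np.ndarray
    positions: np.ndarray
    ancestral: np.ndarray          # (n_variants,)
    group_freqs: np.ndarray        # (n_groups, n_variants)


@dataclass
class SimulatedPanel:
    """A simulated genotype matrix plus its sample sheet and planted truth."""

    gm: GenotypeMatrix
    sample_sheet: pd.DataFrame     # sample_id, group, clone_of
    sweep_truth: SweepSpec | None = None


# --------------------------------------------------------------------------
# frequency layer
# --------------------------------------------------------------------------

def _draw_frequencies(rng, config: SimulationConfig, n: int):
    a, b = config.ancestral_beta
    p = rng.beta(a, b, size=n)
    # keep ancestral frequencies away from exact fixation for BN shape params
    p = np.clip(p, 1e-4, 1 - 1e-4)
    freqs = np.empty((config.n_groups, n))
    for g, F in enumerate(config.drift_F):
        ratio = (1.0 - F) / F
        freqs[g] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return p, freqs


def simulate_group_frequencies(config: SimulationConfig) -> FrequencyTable:
    """Draw positions and Balding-Nichols group frequencies for every variant.

    Variants whose expected pooled minor-allele frequency (mean of group
    frequencies, folded) falls below ``config.min_maf`` are redrawn, so the
    loci surviving the downstream MAF filter are predictable in number.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chroms_out, pos_out = [], []
    for chrom, length in config.chrom_lengths:
        top = length
        if config.ld_block is not None:
            top = max(length - config.ld_block.span_bp, config.n_variants_per_chrom)
        pos = rng.choice(top, size=config.n_variants_per_chrom, replace=False) + 1
        pos.sort()
        chroms_out.append(np.full(config.n_variants_per_chrom, chrom, dtype=object))
        pos_out.append(pos.astype(np.int64))
    chroms = np.concatenate(chroms_out)
    positions = np.concatenate(pos_out)
    n = positions.size

    p, freqs = _draw_frequencies(rng, config, n)
    for _ in range(100):
        pooled = freqs.mean(axis=0)
        maf = np.minimum(pooled, 1.0 - pooled)
        bad = maf < config.min_maf
        if not bad.any():
            break
        p_new, f_new = _draw_frequencies(rng, config, int(bad.sum()))
        p[bad] = p_new
        freqs[:, bad] = f_new
    return FrequencyTable(chroms, positions, p, freqs)


# --------------------------------------------------------------------------
# genotype layer
# --------------------------------------------------------------------------

def _admixed_genotypes(rng, props: np.ndarray, group_freqs: np.ndarray) -> np.ndarray:
    """Each of the two alleles independently picks a group of origin from the
    admixture proportions, then a Bernoulli draw from that group's frequency."""
    n_adm = props.shape[0]
    n_var = group_freqs.shape[1]
    out = np.zeros((n_adm, n_var), dtype=np.int8)
    for i in range(n_adm):
        for _allele in range(2):
            origin = rng.choice(props.shape[1], size=n_var, p=props[i])
            out[i] += (rng.random(n_var) < group_freqs[origin, np.arange(n_var)]).astype(np.int8)
    return out


def simulate_genotypes(freqs: FrequencyTable, config: SimulationConfig) -> SimulatedPanel:
    """Draw HWE genotypes, expand LD blocks, plant the sweep, add clones and
    missingness; returns the panel with its sample sheet and sweep truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    names = config.group_names
    assert names is not None

    sample_ids: list[str] = []
    group_labels: list[str] = []
    blocks: list[np.ndarray] = []
    for g, count in enumerate(config.samples_per_group):
        sample_ids += [f"{names[g]}_S{j + 1:03d}" for j in range(count)]
        group_labels += [names[g]] * count
        blocks.append(
            rng.binomial(2, freqs.group_freqs[g], size=(count, freqs.positions.size)).astype(np.int8)
        )
    if config.n_admixed:
        props = np.asarray(config.admixture_props, dtype=float)
        sample_ids += [f"ADM_S{j + 1:03d}" for j in range(config.n_admixed)]
        # an admixed sample is labelled with its majority-ancestry group
        group_labels += [names[int(np.argmax(props[j]))] for j in range(config.n_admixed)]
        blocks.append(_admixed_genotypes(rng, props, freqs.group_freqs))
    dosages = np.vstack(blocks)

    gm = GenotypeMatrix(
        samples=sample_ids,
        groups=np.asarray(group_labels, dtype=object),
        chroms=freqs.chroms.copy(),
        positions=freqs.positions.copy(),
        dosages=dosages,
        chrom_lengths={c: int(l) for c, l in config.chrom_lengths},
    )

    group_of_sample = _sample_group_index(gm, config)
    if config.ld_block is not None:
        gm = _expand_ld_blocks(rng, gm, freqs, config, group_of_sample)

    truth = None
    if config.sweep is not None:
        gm, truth = plant_sweep(gm, config.sweep)

    clone_of = {s: "" for s in gm.samples}
    if config.clone_pairs:
        if config.clone_pairs > gm.n_samples:
            raise InvalidConfigError("more clone pairs than source samples")
        clones = []
        for k in range(config.clone_pairs):
            src = gm.samples[k]
            cid = f"{src}_CL"
            clones.append((cid, gm.groups[k], gm.dosages[k].copy()))
            clone_of[cid] = src
        gm = GenotypeMatrix(
            samples=gm.samples + [c[0] for c in clones],
            groups=np.concatenate([gm.groups, np.asarray([c[1] for c in clones], dtype=object)]),
            chroms=gm.chroms,
            positions=gm.positions,
            dosages=np.vstack([gm.dosages] + [c[2][None, :] for c in clones]),
            chrom_lengths=gm.chrom_lengths,
        )

    if config.missing_rate > 0:
        mask = rng.random(gm.dosages.shape) < config.missing_rate
        gm.dosages[mask] = MISSING

    sheet = pd.DataFrame(
        {
            "sample_id": gm.samples,
            "group": list(gm.groups),
            "clone_of": [clone_of[s] for s in gm.samples],
        }
    )
    return SimulatedPanel(gm=gm, sample_sheet=sheet, sweep_truth=truth)


def _sample_group_index(gm: GenotypeMatrix, config: SimulationConfig) -> np.ndarray:
    names = list(config.group_names or [])
    return np.asarray([names.index(g) for g in gm.groups], dtype=np.intp)


def _expand_ld_blocks(rng, gm, freqs, config, group_of_sample):
    """Spawn satellite copies of each seed variant with cumulative re-draws."""
    spec = config.ld_block
    chroms, positions, columns = [], [], []
    gf = freqs.group_freqs
    for v in range(gm.n_variants):
        col = gm.dosages[:, v].copy()
        chroms.append(gm.chroms[v])
        positions.append(gm.positions[v])
        columns.append(col)
        # random offsets spread copies over the whole span; chaining the
        # re-draws in offset order makes r-squared decay with distance
        offsets = np.sort(rng.integers(1, spec.span_bp + 1, size=spec.copies))
        for off in offsets:
            col = col.copy()
            flip = rng.random(col.size) < spec.flip_prob
            if flip.any():
                pg = gf[group_of_sample[flip], v]
                col[flip] = rng.binomial(2, pg).astype(np.int8)
            chroms.append(gm.chroms[v])
            positions.append(gm.positions[v] + int(off))
            columns.append(col)
    # keep per-chromosome position uniqueness: drop colliding copies
    chroms_a = np.asarray(chroms, dtype=object)
    pos_a = np.asarray(positions, dtype=np.int64)
    dos = np.stack(columns, axis=1)
    new_order = []
    for chrom in dict.fromkeys(chroms_a):
        idx = np.flatnonzero(chroms_a == chrom)
        idx = idx[np.argsort(pos_a[idx], kind="stable")]
        uniq = np.concatenate([[True], np.diff(pos_a[idx]) > 0])
        new_order.append(idx[uniq])
    order = np.concatenate(new_order)
    return GenotypeMatrix(
        samples=gm.samples,
        groups=gm.groups,
        chroms=chroms_a[order],
        positions=pos_a[order],
        dosages=dos[:, order],
        chrom_lengths=gm.chrom_lengths,
    )


def plant_sweep(gm: GenotypeMatrix, sweep: SweepSpec) -> tuple[GenotypeMatrix, SweepSpec | None]:
    """Make ``sweep``'s interval monomorphic in the swept group.

    Every non-missing call of the swept group inside the interval is replaced
    by a homozygote for that group's major allele at the site. Other groups
    are untouched. Returns the matrix and the truth record (None if the
    interval holds no variants, in which case the call is a no-op).
    """
    names = gm.group_labels()
    group = names[sweep.group_index]
    in_iv = (gm.chroms == sweep.chrom) & (gm.positions >= sweep.start) & (gm.positions <= sweep.end)
    if not in_iv.any():
        warnings.warn("sweep interval contains no variants; nothing planted")
        return gm, None
    rows = gm.group_indices(group)
    sub = gm.dosages[np.ix_(rows, np.flatnonzero(in_iv))]
    valid = sub != MISSING
    alt_count = np.where(valid, sub, 0).sum(axis=0)
    n_calls = valid.sum(axis=0)
    major_is_alt = alt_count > n_calls  # alt frequency above 0.5
    fill = np.where(major_is_alt, 2, 0).astype(np.int8)
    sub = np.where(valid, np.broadcast_to(fill, sub.shape), MISSING).astype(np.int8)
    gm.dosages[np.ix_(rows, np.flatnonzero(in_iv))] = sub
    return gm, sweep


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Convenience wrapper: frequencies then genotypes in one call."""
    return simulate_genotypes(simulate_group_frequencies(config), config)


# --------------------------------------------------------------------------
# output
# --------------------------------------------------------------------------

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_simulation(panel: SimulatedPanel, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the panel as ``<prefix>.vcf`` (VCFv4.2, GT-only) and
    ``<prefix>.samples.tsv``; bit-identical for a fixed seed."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    vcf_path = out_prefix.with_suffix(".vcf")
    sheet_path = Path(str(out_prefix) + ".samples.tsv")

    gm = panel.gm
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popscan-simulate\n")
        if gm.chrom_lengths:
            for chrom, length in gm.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        dosT = gm.dosages.T
        for v in range(gm.n_variants):
            gts = "\t".join(_GT_CODES[int(d)] for d in dosT[v])
            fh.write(
                f"{gm.chroms[v]}\t{gm.positions[v]}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )

    panel.sample_sheet.to_csv(sheet_path, sep="\t", index=False)
    return vcf_path, sheet_path


def default_panel_config(seed: int = 42) -> SimulationConfig:
    """A panel emulating the study conditions: 185 samples in 4 groups of
    unequal drift (pairwise FST roughly 0.005-0.04, group 4 most diverged),
    a few admixed accessions and clone pairs, 2% missingness, and one 200 kb
    sweep planted in group 2."""
    props = np.asarray(
        [
            [0.55, 0.25, 0.15, 0.05],
            [0.25, 0.55, 0.15, 0.05],
            [0.10, 0.20, 0.60, 0.10],
            [0.15, 0.15, 0.15, 0.55],
            [0.40, 0.40, 0.10, 0.10],
        ]
    )
    return SimulationConfig(
        samples_per_group=[45, 45, 45, 42],
        chrom_lengths=[(f"chr{i + 1}", 10_000_000) for i in range(5)],
        n_variants_per_chrom=10_000,
        drift_F=[0.005, 0.006, 0.005, 0.07],
        n_admixed=5,
        admixture_props=props,
        sweep=SweepSpec(chrom="chr3", start=4_000_001, end=4_200_000, group_index=1),
        clone_pairs=3,
        missing_rate=0.02,
        seed=seed,
    )
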