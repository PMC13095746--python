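"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from popscan.datatypes import GenotypeMatrix
from popscan.simulate import SimulationConfig, SweepSpec, simulate_panel


def make_gm(dosages, positions=None, chrom="chr1", groups=None, samples=None,
            chrom_length=None):
    """Hand-build a GenotypeMatrix from a list-of-lists dosage table."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 10
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n)]
    if groups is None:
        groups = ["A"] * n
    lengths = {chrom: chrom_length} if chrom_length else None
    return GenotypeMatrix(
        samples=samples,
        groups=np.asarray(groups, dtype=object),
        chroms=np.asarray([chrom] * m, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        dosages=dosages,
        chrom_lengths=lengths,
    )


@pytest.fixture(scope="session")
def two_group_panel():
    """2 groups x 50 samples, F = 0.05 each, 20k unlinked SNPs on one 20 Mb
    chromosome — the parameter-recovery workhorse."""
    cfg = SimulationConfig(
        samples_per_group=[50, 50],
        chrom_lengths=[("chr1", 20_000_000)],
        n_variants_per_chrom=20_000,
        drift_F=[0.05, 0.05],
        n_groups=2,
        seed=101,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def four_group_panel():
    """4 well-separated groups (F = 0.10), 20 samples each, 10k SNPs."""
    cfg = SimulationConfig(
        samples_per_group=[20, 20, 20, 20],
        chrom_lengths=[("chr1", 10_000_000)],
        n_variants_per_chrom=10_000,
        drift_F=[0.10, 0.10, 0.10, 0.10],
        seed=202,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def clone_panel():
    """2 groups with 3 clone pairs and no missingness (exact-copy checks)."""
    cfg = SimulationConfig(
        samples_per_group=[25, 25],
        chrom_lengths=[("chr1", 5_000_000)],
        n_variants_per_chrom=5_000,
        drift_F=[0.03, 0.03],
        n_groups=2,
        clone_pairs=3,
        missing_rate=0.0,
        seed=303,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def sweep_panel():
    """4 groups, 185 samples, planted 200 kb sweep in group 2 on chr2."""
    cfg = SimulationConfig(
        samples_per_group=[47, 46, 46, 46],
        chrom_lengths=[("chr1", 10_000_000), ("chr2", 10_000_000)],
        n_variants_per_chrom=10_000,
        drift_F=[0.02, 0.02, 0.02, 0.08],
        sweep=SweepSpec("chr2", 3_000_001, 3_200_000, 1),
        seed=404,
    )
    return simulate_panel(cfg)
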