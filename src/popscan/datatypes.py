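"""Core data containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`, a dense samples x variants
dosage matrix (0/1/2 alternate-allele copies, ``MISSING`` for no-calls) with
chromosome/position coordinates and a group label per sample. All statistics
modules consume this container; nothing downstream re-reads the VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1

_ALLOWED_DOSAGES = frozenset({-1, 0, 1, 2})


class InvalidConfigError(ValueError):
    """Raised when a simulation or run configuration is internally inconsistent."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with genomic coordinates and groups.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``dosages``).
    groups
        Group label per sample, aligned with ``samples``.
    chroms
        Chromosome label per variant. Variants of one chromosome must form a
        contiguous block.
    positions
        1-based physical positions, strictly increasing within a chromosome.
    dosages
        ``int8`` array of shape (n_samples, n_variants) with values in
        {0, 1, 2, MISSING}.
    chrom_lengths
        Optional chromosome lengths in bp (used for windowing); inferred from
        the maximum observed position when absent.
    n_non_biallelic_dropped
        Bookkeeping from the VCF reader: rows discarded for not being
        biallelic SNPs.
    """

    samples: list[str]
    groups: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray
    chrom_lengths: dict[str, int] | None = None
    n_non_biallelic_dropped: int = 0

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=object)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return int(self.positions.shape[0])

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.n_samples < 2:
            raise ValueError("a GenotypeMatrix needs at least 2 samples")
        if self.dosages.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"({self.n_samples}, {self.n_variants})"
            )
        if len(self.groups) != self.n_samples:
            raise ValueError("one group label per sample required")
        bad = ~np.isin(self.dosages, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values outside {0,1,2,MISSING}")
        seen: set[str] = set()
        for chrom, sl in self.chrom_blocks():
            if chrom in seen:
                raise ValueError(f"chromosome {chrom!r} is not contiguous")
            seen.add(chrom)
            pos = self.positions[sl]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom!r}")

    # ------------------------------------------------------------- accessors
    def group_labels(self) -> list[str]:
        """Unique group labels in first-appearance order."""
        out: list[str] = []
        for g in self.groups:
            if g not in out:
                out.append(g)
        return out

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise KeyError(f"unknown group label {group!r}")
        return idx

    def chrom_blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom, slice)`` for each contiguous chromosome block."""
        if self.n_variants == 0:
            return
        start = 0
        for i in range(1, self.n_variants + 1):
            if i == self.n_variants or self.chroms[i] != self.chroms[start]:
                yield self.chroms[start], slice(start, i)
                start = i

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        mask = self.chroms == chrom
        if not mask.any():
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.positions[mask].max())

    # -------------------------------------------------------------- subsetting
    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping variants selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            chroms=self.chroms[index],
            positions=self.positions[index],
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.intp)
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            groups=self.groups[index],
            dosages=self.dosages[index, :],
        )


@dataclass
class FilterReport:
    """Variant-filter accounting; inputs always equal removals plus retained."""

    n_input: int
    n_non_biallelic_removed: int
    n_maf_removed: int
    n_missing_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_non_biallelic_removed
            + self.n_maf_removed
            + self.n_missing_removed
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"FilterReport not conserved: {self.n_input} != {total}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_non_biallelic_removed": self.n_non_biallelic_removed,
            "n_maf_removed": self.n_maf_removed,
            "n_missing_removed": self.n_missing_removed,
            "n_retained": self.n_retained,
        }


@dataclass
class WindowSpec:
    """Sliding-window geometry: 100 kb windows advanced in 10 kb steps by default."""

    size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")
        if self.step > self.size:
            raise ValueError("step must not exceed window size")


@dataclass
class SquareMatrix:
    """Symmetric sample x sample matrix (base for distance and kinship)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


class DistanceMatrix(SquareMatrix):
    """Allele-sharing distances: symmetric, non-negative, zero diagonal."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance diagonal must be zero")


class KinshipMatrix(SquareMatrix):
    """Genomic-relationship values; diagonal ~= 1 + inbreeding and may exceed 1."""
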