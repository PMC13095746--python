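"""Population structure: LD pruning, distances, NJ tree, PCA, GRM kinship.

The distance metric is the allele-sharing distance (mean |dosage difference|
/ 2 over mutually non-missing variants), a simple missing-tolerant choice.
PCA uses the EIGENSTRAT convention — each variant centred by its mean dosage
and scaled by sqrt(2*p*(1-p)), missing calls mean-imputed — so eigenvalue
percentages are comparable across panels. Kinship is the GCTA-style genomic
relationship matrix with per-pair marker counts under missingness; its
diagonal estimates 1 + inbreeding and clone pairs show off-diagonal values
near (or above) 1.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import MISSING, DistanceMatrix, GenotypeMatrix, KinshipMatrix
from .ld import r2_matrix

__all__ = [
    "ld_prune",
    "pairwise_distance",
    "neighbor_joining",
    "pca",
    "grm_kinship",
    "high_kinship_prune",
]


# --------------------------------------------------------------------------
# LD pruning (PLINK --indep-pairwise semantics on dosage correlation)
# --------------------------------------------------------------------------

def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Greedy sliding-window LD pruning.

    A ``window_snps``-wide window advances by ``step_snps`` SNPs per
    chromosome; while any surviving pair in the window has r-squared above
    the threshold, the member of the worst (highest-r2) pair with the lower
    MAF is removed (tie: the SNP at the larger position). Removals persist
    across windows. Returns the pruned matrix and the kept variant indices.
    """
    miss = gm.dosages == MISSING
    n_called = (~miss).sum(axis=0)
    alt = np.where(miss, 0, gm.dosages).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(freq, 1.0 - freq)

    keep = np.ones(gm.n_variants, dtype=bool)
    for _, sl in gm.chrom_blocks():
        lo, hi = sl.start, sl.stop
        for w0 in range(lo, hi, step_snps):
            idx = np.flatnonzero(keep[w0 : min(w0 + window_snps, hi)]) + w0
            if idx.size < 2:
                continue
            r2 = r2_matrix(gm.dosages[:, idx])
            r2 = np.nan_to_num(r2, nan=0.0)
            while True:
                worst = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[worst] <= r2_threshold:
                    break
                i, j = (idx[worst[0]], idx[worst[1]])
                if maf[i] < maf[j]:
                    drop = i
                elif maf[j] < maf[i]:
                    drop = j
                else:
                    drop = max(i, j, key=lambda v: gm.positions[v])
                keep[drop] = False
                local = worst[0] if drop == i else worst[1]
                r2[local, :] = 0.0
                r2[:, local] = 0.0
    return gm.subset_variants(keep), np.flatnonzero(keep)


# --------------------------------------------------------------------------
# distances and neighbor joining
# --------------------------------------------------------------------------

def pairwise_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance d(i,j) = mean |x_i - x_j| / 2 over mutually
    non-missing variants; errors if any pair shares no called variant."""
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    # decompose dosages into per-value indicators so |a-b| sums become
    # matrix products: sum |a-b| = sum_{a,b} |a-b| * count(x_i=a, x_j=b)
    ind = [(gm.dosages == v).astype(float) for v in (0, 1, 2)]
    counts = {}
    for a in range(3):
        for b in range(3):
            counts[(a, b)] = ind[a] @ ind[b].T
    overlap = sum(counts.values())
    numer = sum(abs(a - b) * c for (a, b), c in counts.items())
    if np.any(overlap == 0):
        i, j = np.argwhere(overlap == 0)[0]
        raise ValueError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no called variant"
        )
    d = numer / overlap / 2.0
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=list(gm.samples), values=d)


class _Node:
    __slots__ = ("name", "children", "lengths", "key")

    def __init__(self, name=None, children=(), lengths=(), key=""):
        self.name = name
        self.children = list(children)
        self.lengths = list(lengths)
        self.key = key  # smallest leaf name under this node, for tie-breaks

    def newick(self) -> str:
        if not self.children:
            return self.name
        parts = [
            f"{c.newick()}:{l:.10g}" for c, l in zip(self.children, self.lengths)
        ]
        return "(" + ",".join(parts) + ")"


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    At each step the pair minimising the Q-criterion is joined (ties broken
    on the lexicographically smallest leaf-name pair); negative branch
    lengths are clamped to zero with the deficit moved to the sister branch
    so the pair's summed length is preserved. The last three nodes form the
    root trifurcation.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    d = dm.values.astype(float).copy()
    nodes = [_Node(name=s, key=s) for s in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((nodes[active[i]].key, nodes[active[j]].key))), i, j)
            for i, j in cand
            if i < j
        )
        _, bi, bj = best
        i, j = active[bi], active[bj]
        li = sub[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = sub[bi, bj] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = _Node(
            children=(nodes[i], nodes[j]),
            lengths=(li, lj),
            key=min(nodes[i].key, nodes[j].key),
        )
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(nodes)] = dnew
        d[: len(nodes), -1] = dnew
        d[-1, -1] = 0.0
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(
        children=(nodes[a], nodes[b], nodes[c]),
        lengths=(la, lb, lc),
        key=min(nodes[a].key, nodes[b].key, nodes[c].key),
    )
    return root.newick() + ";"


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def pca(gm: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """EIGENSTRAT-style PCA of the standardized genotype matrix.

    Returns (coordinates frame indexed like ``gm.samples`` with columns
    PC1..PCk, percent-variance vector over the same components). Percent
    variance is eigenvalue / trace x 100 over the full spectrum.
    """
    X = gm.dosages.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    informative = scale > 0
    if not informative.any():
        raise ValueError("no polymorphic variants for PCA")
    X = (X[:, informative] - 2.0 * p[informative]) / scale[informative]
    X = np.nan_to_num(X, nan=0.0)  # mean imputation after centering

    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    trace = eigval.sum()
    if trace <= 0:
        raise ValueError("zero-variance genotype matrix")
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pct = eigval[:k] / trace * 100.0
    frame = pd.DataFrame(
        coords, index=gm.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, pct


# --------------------------------------------------------------------------
# kinship
# --------------------------------------------------------------------------

def grm_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """GCTA-style genomic relationship matrix.

    G(i,j) = mean over markers of (x_i - 2p)(x_j - 2p) / (2p(1-p)) with the
    in-sample alt frequency p; markers missing in either member of a pair
    are excluded for that pair (per-pair marker count). Monomorphic markers
    are excluded with a warning.
    """
    X = gm.dosages.astype(float)
    miss = X == MISSING
    Xn = np.where(miss, np.nan, X)
    p = np.nanmean(Xn, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(f"excluding {int((~poly).sum())} monomorphic markers from GRM")
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    Z = (Xn[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    called = ~np.isnan(Z)
    Z0 = np.nan_to_num(Z, nan=0.0)
    numer = Z0 @ Z0.T
    counts = called.astype(float) @ called.astype(float).T
    if np.any(counts == 0):
        raise ValueError("a sample pair shares no called polymorphic marker")
    G = numer / counts
    G = (G + G.T) / 2.0
    return KinshipMatrix(ids=list(gm.samples), values=G)


def high_kinship_prune(
    kin: KinshipMatrix, threshold: float = 0.45
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Flag pairs above ``threshold`` and greedily resolve them.

    Repeatedly drops the sample involved in the most unresolved flagged
    pairs (ties: the lexicographically larger ID) until none remain.
    Returns (flagged pairs with their kinship, retained sample IDs).
    """
    ids = kin.ids
    flagged = [
        (ids[i], ids[j], float(kin.values[i, j]))
        for i, j in combinations(range(len(ids)), 2)
        if kin.values[i, j] > threshold
    ]
    retained = set(ids)
    live = [(a, b) for a, b, _ in flagged]
    while live:
        tally: dict[str, int] = {}
        for a, b in live:
            tally[a] = tally.get(a, 0) + 1
            tally[b] = tally.get(b, 0) + 1
        worst = max(tally.items(), key=lambda kv: (kv[1], kv[0]))[0]
        retained.discard(worst)
        live = [(a, b) for a, b in live if worst not in (a, b)]
    return flagged, [s for s in ids if s in retained]
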