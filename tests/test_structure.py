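"""LD pruning, distances, neighbor joining, PCA and GRM kinship."""

import io
from itertools import combinations

import numpy as np
import pytest

from popscan import structure
from popscan.datatypes import MISSING, DistanceMatrix, KinshipMatrix
from popscan.simulate import SimulationConfig, simulate_panel
from conftest import make_gm


# --------------------------------------------------------------------------
# LD pruning
# --------------------------------------------------------------------------

class TestLdPrune:
    def test_duplicated_adjacent_column_leaves_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(30, 10)).astype(np.int8)
        dup = np.insert(base, 4, base[:, 3], axis=1)  # twin of column 3
        gm = make_gm(dup, positions=np.arange(1, 12))
        pruned, kept = structure.ld_prune(gm, 50, 5, 0.2)
        assert (3 in kept) != (4 in kept)

    def test_threshold_one_prunes_nothing(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.integers(0, 3, size=(20, 40)).astype(np.int8))
        pruned, kept = structure.ld_prune(gm, 50, 5, 1.0)
        assert pruned.n_variants == 40

    def test_unlinked_snps_mostly_retained(self):
        # independent loci at n = 500: null r2 ~ 1/n, far below 0.2
        cfg = SimulationConfig(
            samples_per_group=[500],
            chrom_lengths=[("chr1", 2_000_000)],
            n_variants_per_chrom=2_000,
            drift_F=[0.05],
            n_groups=1,
            seed=17,
        )
        gm = simulate_panel(cfg).gm
        pruned, _ = structure.ld_prune(gm, 50, 5, 0.2)
        assert pruned.n_variants >= 0.99 * gm.n_variants


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

class TestPairwiseDistance:
    def test_identical_and_opposite_samples(self):
        gm = make_gm([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        dm = structure.pairwise_distance(gm)
        assert dm.values[0, 1] == 0.0
        gm2 = make_gm([[0, 0], [2, 2]])
        assert structure.pairwise_distance(gm2).values[0, 1] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        dos = rng.choice([-1, 0, 1, 2], size=(4, 10)).astype(np.int8)
        gm = make_gm(dos)
        dm = structure.pairwise_distance(gm)
        for i, j in combinations(range(4), 2):
            pairs = [
                abs(int(a) - int(b)) / 2
                for a, b in zip(dos[i], dos[j])
                if a != MISSING and b != MISSING
            ]
            assert dm.values[i, j] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_zero_overlap_pair_is_hard_error(self):
        gm = make_gm([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="share no called variant"):
            structure.pairwise_distance(gm)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def read_tree(newick: str):
    from skbio import TreeNode

    # sample IDs contain underscores; keep them verbatim
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def patristic(newick: str):
    return read_tree(newick).tip_tip_distances()


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        dm = DistanceMatrix(ids=["A", "B", "C"], values=d)
        nwk = structure.neighbor_joining(dm)
        td = patristic(nwk)
        for a, b, want in [("A", "B", 3), ("A", "C", 4), ("B", "C", 5)]:
            assert td[a, b] == pytest.approx(want, abs=1e-9)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):0.5,(C:3,D:4):0.5) -> additive distances
        d = {
            ("A", "B"): 3.0,
            ("A", "C"): 5.0,
            ("A", "D"): 6.0,
            ("B", "C"): 6.0,
            ("B", "D"): 7.0,
            ("C", "D"): 7.0,
        }
        ids = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            mat[i, j] = mat[j, i] = v
        nwk = structure.neighbor_joining(DistanceMatrix(ids=ids, values=mat))
        td = patristic(nwk)
        for (x, y), v in d.items():
            assert td[x, y] == pytest.approx(v, abs=1e-9)

    def test_additive_random_trees_roundtrip(self):
        # random additive distances from random topologies, 5-8 taxa
        rng = np.random.default_rng(11)
        for n in (5, 6, 8):
            # build a random tree by sequential attachment; compute its
            # path-length matrix directly as the oracle
            import networkx as nx

            g = nx.Graph()
            g.add_edge("t0", "t1", weight=rng.uniform(0.1, 2))
            internal = 0
            for k in range(2, n):
                edge = list(g.edges)[rng.integers(len(g.edges))]
                mid = f"i{internal}"
                internal += 1
                w = g.edges[edge]["weight"]
                g.remove_edge(*edge)
                s1 = rng.uniform(0.05, 1)
                g.add_edge(edge[0], mid, weight=w * 0.5)
                g.add_edge(mid, edge[1], weight=w * 0.5)
                g.add_edge(mid, f"t{k}", weight=s1)
            tips = [f"t{k}" for k in range(n)]
            mat = np.zeros((n, n))
            lengths = dict(nx.all_pairs_dijkstra_path_length(g))
            for i, j in combinations(range(n), 2):
                mat[i, j] = mat[j, i] = lengths[tips[i]][tips[j]]
            nwk = structure.neighbor_joining(DistanceMatrix(ids=tips, values=mat))
            td = patristic(nwk)
            for i, j in combinations(range(n), 2):
                assert td[tips[i], tips[j]] == pytest.approx(mat[i, j], abs=1e-9)

    def test_groups_monophyletic_on_simulated_panel(self, four_group_panel):
        gm = four_group_panel.gm
        dm = structure.pairwise_distance(gm)
        tree = read_tree(structure.neighbor_joining(dm))
        groups = {g: {s for s, lab in zip(gm.samples, gm.groups) if lab == g}
                  for g in gm.group_labels()}
        tip_names = {t.name for t in tree.tips()}
        for g, members in groups.items():
            # a group is monophyletic in the unrooted tree iff some edge
            # splits exactly that set from the rest
            found = False
            for node in tree.traverse():
                clade = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
                if clade == members or (tip_names - clade) == members:
                    found = True
                    break
            assert found, f"group {g} not monophyletic"


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class TestPca:
    def test_clone_pair_identical_coordinates(self, clone_panel):
        gm = clone_panel.gm
        coords, pct = structure.pca(gm)
        sheet = clone_panel.sample_sheet
        for _, row in sheet[sheet.clone_of != ""].iterrows():
            np.testing.assert_allclose(
                coords.loc[row.sample_id].to_numpy(),
                coords.loc[row.clone_of].to_numpy(),
                atol=1e-8,
            )

    def test_percent_variance_shape(self, clone_panel):
        _, pct = structure.pca(clone_panel.gm)
        assert pct.sum() <= 100 + 1e-9
        assert np.all(np.diff(pct) <= 1e-12)

    def test_pc1_separates_two_groups(self):
        cfg = SimulationConfig(
            samples_per_group=[50, 50],
            chrom_lengths=[("chr1", 5_000_000)],
            n_variants_per_chrom=10_000,
            drift_F=[0.10, 0.10],
            n_groups=2,
            seed=23,
        )
        panel = simulate_panel(cfg)
        coords, _ = structure.pca(panel.gm)
        pc1 = coords["PC1"].to_numpy()
        a, b = pc1[:50], pc1[50:]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_percent_variance_invariant_to_sample_permutation(self, clone_panel):
        gm = clone_panel.gm
        perm = np.random.default_rng(4).permutation(gm.n_samples)
        _, pct1 = structure.pca(gm)
        _, pct2 = structure.pca(gm.subset_samples(perm))
        np.testing.assert_allclose(pct1, pct2, atol=1e-9)


# --------------------------------------------------------------------------
# kinship
# --------------------------------------------------------------------------

class TestGrmKinship:
    def test_clone_offdiagonal_near_self_kinship(self, clone_panel):
        kin = structure.grm_kinship(clone_panel.gm)
        sheet = clone_panel.sample_sheet
        for _, row in sheet[sheet.clone_of != ""].iterrows():
            assert kin.loc(row.sample_id, row.clone_of) > 0.9
            assert kin.loc(row.sample_id, row.clone_of) == pytest.approx(
                kin.loc(row.clone_of, row.clone_of), abs=1e-9
            )

    def test_offdiagonal_mean_matches_centering_constraint(self):
        cfg = SimulationConfig(
            samples_per_group=[80],
            chrom_lengths=[("chr1", 5_000_000)],
            n_variants_per_chrom=10_000,
            drift_F=[0.05],
            n_groups=1,
            seed=31,
        )
        gm = simulate_panel(cfg).gm
        kin = structure.grm_kinship(gm)
        n = len(kin.ids)
        off = kin.values[np.triu_indices(n, k=1)]
        # in-sample centering forces mean off-diagonal ~ -1/(n-1)
        se = off.std() / np.sqrt(len(off))
        assert abs(off.mean() - (-1 / (n - 1))) < 2 * se + 1e-3

    def test_permutation_commutes(self, clone_panel):
        gm = clone_panel.gm
        perm = np.random.default_rng(9).permutation(gm.n_samples)
        kin = structure.grm_kinship(gm)
        kin_p = structure.grm_kinship(gm.subset_samples(perm))
        np.testing.assert_allclose(
            kin.values[np.ix_(perm, perm)], kin_p.values, atol=1e-10
        )


class TestHighKinshipPrune:
    def test_no_flagged_pairs_keeps_everyone(self):
        kin = KinshipMatrix(ids=["a", "b", "c"], values=np.eye(3))
        flagged, retained = structure.high_kinship_prune(kin, 0.45)
        assert flagged == [] and retained == ["a", "b", "c"]

    def test_single_clone_pair_drops_exactly_one(self, clone_panel):
        kin = structure.grm_kinship(clone_panel.gm)
        flagged, retained = structure.high_kinship_prune(kin, 0.45)
        n_clones = (clone_panel.sample_sheet.clone_of != "").sum()
        assert len(flagged) == n_clones
        assert len(retained) == len(kin.ids) - n_clones

    def test_related_triangle_drops_two(self):
        v = np.eye(4)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            v[i, j] = v[j, i] = 0.6
        kin = KinshipMatrix(ids=["a", "b", "c", "d"], values=v)
        flagged, retained = structure.high_kinship_prune(kin, 0.45)
        assert len(flagged) == 3
        assert len(retained) == 2 and "d" in retained

    def test_group_assignment_stable_after_pruning(self, clone_panel):
        # nearest-group-centroid assignments in PC space unchanged by
        # removing one member of each clone pair
        gm = clone_panel.gm
        coords, _ = structure.pca(gm)
        kin = structure.grm_kinship(gm)
        _, retained = structure.high_kinship_prune(kin, 0.45)

        def assignments(frame, samples, k=3):
            sub = frame.loc[samples, [f"PC{i+1}" for i in range(k)]]
            labels = {s: g for s, g in zip(gm.samples, gm.groups)}
            cents = {
                g: sub.loc[[s for s in samples if labels[s] == g]].mean()
                for g in set(labels.values())
            }
            out = {}
            for s in samples:
                out[s] = min(
                    cents, key=lambda g: np.linalg.norm(sub.loc[s] - cents[g])
                )
            return out

        before = assignments(coords, retained)
        pruned_gm = gm.subset_samples([gm.samples.index(s) for s in retained])
        coords_after, _ = structure.pca(pruned_gm)
        after = assignments(coords_after, retained)
        assert before == after
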