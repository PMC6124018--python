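"""Variome summaries, allele-sharing distance, classical MDS, and NJ trees.

Brute-force multiset arithmetic and scikit-bio (pcoa, nj) serve as the
independent oracles.
"""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from hybridseer import simulate as sim
from hybridseer.variome import (
    DistanceMatrix,
    GenotypeMatrix,
    VariomeError,
    allele_distance,
    classical_mds,
    nj_tree,
    summarize_variome,
)


def make_gm(samples, site_specs, genotypes):
    """site_specs: list of (ref, alt, type); genotypes: nested allele pairs."""
    sites = pd.DataFrame(
        [("chr1", i * 10, r, a, t) for i, (r, a, t) in enumerate(site_specs)],
        columns=["seq", "pos", "ref", "alt", "type"],
    )
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        genotypes=np.array(genotypes, dtype=np.int8),
    )


class TestSummaries:
    def test_reference_identical_sample_all_zero(self):
        gm = make_gm(
            ["s1"],
            [("A", "G", "SNP"), ("C", "T", "SNP")],
            [[[0, 0], [0, 0]]],
        )
        row = summarize_variome(gm).iloc[0]
        assert (
            row[["het_snps", "hom_snps", "indels", "snps_plus_indels", "ti", "tv"]]
            == 0
        ).all()

    def test_toy_titv_hand_count(self):
        # A->G hom alt (two transition copies) + C->A het (one transversion)
        gm = make_gm(
            ["s1"],
            [("A", "G", "SNP"), ("C", "A", "SNP"), ("G", "A", "SNP")],
            [[[1, 1], [0, 1], [0, 1]]],
        )
        row = summarize_variome(gm).iloc[0]
        assert row["het_snps"] == 2
        assert row["hom_snps"] == 1
        assert row["ti"] == 3  # A/G hom = 2 copies, G->A het = 1 copy
        assert row["tv"] == 1  # C->A het
        assert row["titv_ratio"] == pytest.approx(3.0)

    def test_indels_counted_separately(self):
        gm = make_gm(
            ["s1"],
            [("A", "AT", "InDel"), ("ATT", "A", "InDel"), ("A", "G", "SNP")],
            [[[0, 1], [1, 1], [0, 0]]],
        )
        row = summarize_variome(gm).iloc[0]
        assert row["indels"] == 2
        assert row["snps_plus_indels"] == 2
        assert row["ti"] == 0 and row["tv"] == 0
        assert np.isnan(row["titv_ratio"])

    def test_multiallelic_excluded_from_titv(self):
        gm = make_gm(
            ["s1"],
            [("A", "G,T", "SNP"), ("C", "T", "SNP")],
            [[[1, 2], [1, 1]]],
        )
        row = summarize_variome(gm).iloc[0]
        assert row["het_snps"] == 1 and row["hom_snps"] == 1
        assert row["ti"] == 2 and row["tv"] == 0

    def test_het_plus_hom_partitions_called_variant_sites(self, small_cross):
        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        gm = GenotypeMatrix(samples, sites.rename(columns=str), gts)
        summ = summarize_variome(gm)
        for i in range(gm.n_samples):
            g = gm.genotypes[i]
            called = (g >= 0).all(axis=1)
            variant = called & (g.max(axis=1) > 0)
            assert summ.iloc[i]["snps_plus_indels"] == int(variant.sum())


def brute_force_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Per-pair allele-difference totals using Counter multisets."""
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            total = 0
            for s in range(gm.n_sites):
                gi = [a for a in gm.genotypes[i, s]]
                gj = [a for a in gm.genotypes[j, s]]
                if -1 in gi or -1 in gj:
                    continue
                shared = sum((Counter(gi) & Counter(gj)).values())
                total += 2 - shared
            d[i, j] = total
    return d


class TestDistance:
    def test_identical_samples_distance_zero(self):
        g = [[[0, 1], [1, 1]], [[0, 1], [1, 1]]]
        gm = make_gm(["a", "b"], [("A", "G", "SNP")] * 2, g)
        assert allele_distance(gm).d[0, 1] == 0

    def test_hand_counted_two_sites(self):
        # site1 A/A vs A/G -> 1 shared A missing one -> distance 1
        # site2 C/T vs T/T -> share one T -> distance 1
        gm = make_gm(
            ["a", "b"],
            [("A", "G", "SNP"), ("C", "T", "SNP")],
            [[[0, 0], [0, 1]], [[0, 1], [1, 1]]],
        )
        assert allele_distance(gm).d[0, 1] == 2

    def test_opposite_homozygotes_reach_maximum(self):
        n_sites = 7
        gm = make_gm(
            ["a", "b"],
            [("A", "G", "SNP")] * n_sites,
            [[[0, 0]] * n_sites, [[1, 1]] * n_sites],
        )
        dm = allele_distance(gm)
        assert dm.d[0, 1] == 2 * n_sites
        assert dm.denom[0, 1] == n_sites

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for trial in range(3):
            n_samples, n_sites = 5, 200
            gts = rng.integers(0, 2, size=(n_samples, n_sites, 2), dtype=np.int8)
            miss = rng.random((n_samples, n_sites)) < 0.10
            gts[miss] = -1
            # guard against an all-missing pair
            gts[:, 0] = 0
            gm = make_gm(
                [f"s{i}" for i in range(n_samples)],
                [("A", "G", "SNP")] * n_sites,
                gts,
            )
            dm = allele_distance(gm)
            assert np.array_equal(dm.d, brute_force_distance(gm))

    def test_normalize_divides_by_joint_sites(self):
        gm = make_gm(
            ["a", "b"],
            [("A", "G", "SNP")] * 4,
            [[[0, 0], [0, 0], [1, 1], [-1, -1]], [[1, 1], [0, 0], [1, 1], [0, 0]]],
        )
        dm = allele_distance(gm, normalize=True)
        assert dm.d[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_missingness_raises_naming_pair(self):
        gm = make_gm(
            ["alpha", "beta"],
            [("A", "G", "SNP")] * 2,
            [[[0, 0], [-1, -1]], [[-1, -1], [0, 0]]],
        )
        with pytest.raises(VariomeError, match="alpha.*beta"):
            allele_distance(gm)

    def test_axioms_and_permutation_equivariance(self, small_cross):
        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        gm = GenotypeMatrix(samples, sites, gts)
        dm = allele_distance(gm)
        assert np.allclose(dm.d, dm.d.T)
        assert (np.diag(dm.d) == 0).all()
        perm = [3, 0, 5, 1, 4, 2]
        dm_p = allele_distance(gm.permuted(perm))
        assert np.allclose(dm_p.d, dm.d[np.ix_(perm, perm)])


class TestMDS:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], float
        ))
        coords = classical_mds(dm, dims=2).to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_two_samples_closed_form(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 4], [4, 0]], float))
        coords = classical_mds(dm, dims=1).to_numpy()
        assert sorted(coords[:, 0]) == pytest.approx([-2.0, 2.0])

    def test_full_rank_embedding_reproduces_distances(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        coords = classical_mds(dm, dims=5).to_numpy()
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(emb, d, rtol=1e-6, atol=1e-9)

    def test_matches_scikit_bio_pcoa(self):
        import warnings

        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix([f"s{i}" for i in range(7)], d)
        ours = classical_mds(dm, dims=2).to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = pcoa(SkbioDM(d), number_of_dimensions=2).samples.to_numpy()
        # same embedding up to per-axis sign
        for axis in range(2):
            assert np.allclose(np.abs(ours[:, axis]), np.abs(theirs[:, axis]),
                               atol=1e-8)

    def test_all_zero_distances_embed_at_origin(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        assert (classical_mds(dm).to_numpy() == 0).all()

    def test_dims_bound(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(VariomeError):
            classical_mds(dm, dims=2)


def patristic(newick: str) -> pd.DataFrame:
    import skbio

    tree = skbio.TreeNode.read([newick])
    return tree.tip_tip_distances().to_data_frame()


class TestNJ:
    def test_recovers_additive_four_taxon_tree_exactly(self):
        # tree ((A:2,B:3):1,C:4,D:6) -> additive distances
        d = np.array(
            [
                [0, 5, 7, 9],
                [5, 0, 8, 10],
                [7, 8, 0, 10],
                [9, 10, 10, 0],
            ],
            float,
        )
        names = ["A", "B", "C", "D"]
        nwk = nj_tree(DistanceMatrix(names, d))
        pat = patristic(nwk)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    assert pat.loc[a, b] == pytest.approx(d[i, j], abs=1e-9)

    def test_star_tree_zero_internal_branches(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        nwk = nj_tree(DistanceMatrix(list("ABCD"), d))
        pat = patristic(nwk)
        assert np.allclose(pat.to_numpy()[~np.eye(4, dtype=bool)], 2.0)

    def test_topology_matches_scikit_bio(self):
        import skbio
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        pts = rng.normal(size=(7, 5)) * 3
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        names = [f"s{i}" for i in range(7)]
        ours = skbio.TreeNode.read([nj_tree(DistanceMatrix(names, d))])
        theirs = skbio_nj(SkbioDM(d, ids=names))
        assert ours.compare_rfd(theirs) == 0

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(VariomeError):
            nj_tree(dm)

    def test_simulated_panel_maternal_clade(self, small_cross):
        import skbio

        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        gm = GenotypeMatrix(samples, sites, gts)
        dm = allele_distance(gm)
        tree = skbio.TreeNode.read([nj_tree(dm)])
        lca = tree.lca(["mat1", "mat2"])
        tips = {t.name for t in lca.tips()}
        assert "pat1" not in tips and "pat2" not in tips

    def test_f1_intermediate_on_mds_axis1(self, small_cross):
        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        gm = GenotypeMatrix(samples, sites, gts)
        coords = classical_mds(allele_distance(gm), dims=2)
        axis1 = coords["dim1"]
        mat = axis1[["mat1", "mat2"]].mean()
        pat = axis1[["pat1", "pat2"]].mean()
        lo, hi = sorted((mat, pat))
        for f1 in ("f1_1", "f1_2"):
            assert lo < axis1[f1] < hi

    def test_f1_signature_distances(self, small_cross):
        cfg = small_cross["config"]
        samples, sites, gts = sim.simulate_panel(
            small_cross["maternal"], small_cross["paternal"], cfg
        )
        gm = GenotypeMatrix(samples, sites, gts)
        dm = allele_distance(gm, normalize=True)
        idx = {s: i for i, s in enumerate(samples)}
        d_f1_mat = np.mean(
            [dm.d[idx[f], idx[m]] for f in ("f1_1", "f1_2") for m in ("mat1", "mat2")]
        )
        d_f1_pat = np.mean(
            [dm.d[idx[f], idx[p]] for f in ("f1_1", "f1_2") for p in ("pat1", "pat2")]
        )
        d_mat_pat = np.mean(
            [dm.d[idx[m], idx[p]] for m in ("mat1", "mat2") for p in ("pat1", "pat2")]
        )
        assert abs(d_f1_mat - d_f1_pat) / max(d_f1_mat, d_f1_pat) < 0.10
        assert d_f1_mat < d_mat_pat and d_f1_pat < d_mat_pat
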