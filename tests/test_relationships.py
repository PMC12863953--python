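"""Pedigree (A), genomic (G), and combined (H^-1) relationship matrices."""

import numpy as np
import pandas as pd
import pytest

import liabel as lb
from liabel.containers import GenotypeMatrix
from tests.conftest import toy_pedigree


class TestBuildA:
    def test_unrelated_pair(self):
        A = lb.build_A(toy_pedigree([(1, 0, 0), (2, 0, 0)]))
        assert np.allclose(A.values, np.eye(2))

    def test_parent_offspring_and_full_sibs(self):
        ped = toy_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2)])
        A = lb.build_A(ped)
        assert A.loc(1, 3) == pytest.approx(0.5)
        assert A.loc(3, 4) == pytest.approx(0.5)
        assert A.loc(3, 3) == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        ped = toy_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        A = lb.build_A(ped)
        assert A.loc(5, 5) == pytest.approx(1.25)  # F = 0.25
        assert lb.relationships.inbreeding(ped)[5] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "rows, pair, wright",
        [
            # half sibs: shared sire only
            ([(1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 1, 2), (5, 1, 3)], (4, 5), 0.25),
            # grandparent-grandchild
            ([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 0, 0), (5, 3, 4)], (1, 5), 0.25),
            # first cousins (full-sib parents mated to unrelated mates)
            (
                [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 0, 0), (6, 0, 0),
                 (7, 3, 5), (8, 4, 6)][:8],
                (7, 8),
                0.125,
            ),
        ],
    )
    def test_wright_path_coefficients(self, rows, pair, wright):
        """Tabular method agrees with Wright's path counting on small fixtures."""
        A = lb.build_A(toy_pedigree([r[:3] for r in rows]))
        assert A.loc(*pair) == pytest.approx(wright)

    def test_symmetry_and_psd(self, small_population):
        A = lb.build_A(small_population.pedigree)
        assert np.allclose(A.values, A.values.T)
        assert np.linalg.eigvalsh(A.values).min() > -1e-8

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            lb.build_A(toy_pedigree([(3, 1, 2), (1, 0, 0), (2, 0, 0)]))


class TestTruncatePedigree:
    def test_zero_horizon_keeps_anchors_only(self):
        ped = toy_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 3)])
        out = lb.truncate_pedigree(ped, 0, anchors={4})
        assert list(out["animal"]) == [4]
        assert out.iloc[0]["sire"] == 0 and out.iloc[0]["dam"] == 0

    def test_chain_horizon(self):
        # 4-generation maternal chain; 3-generation horizon from the last animal
        ped = toy_pedigree([(1, 0, 0), (2, 1, 0), (3, 2, 0), (4, 3, 0), (5, 4, 0)])
        out = lb.truncate_pedigree(ped, 3, anchors={5})
        assert set(out["animal"]) == {2, 3, 4, 5}
        assert out.set_index("animal").loc[2, "sire"] == 0  # recoded unknown

    def test_identity_when_horizon_covers_depth(self, small_population):
        ped = small_population.pedigree
        out = lb.truncate_pedigree(ped, 10, anchors=set(ped["animal"]))
        pd.testing.assert_frame_equal(out, ped.reset_index(drop=True))

    def test_missing_anchor_listed(self):
        ped = toy_pedigree([(1, 0, 0)])
        with pytest.raises(KeyError, match="99"):
            lb.truncate_pedigree(ped, 1, anchors={99})


class TestBuildG:
    def test_full_centering_gives_zero(self):
        g = GenotypeMatrix([1, 2], ["s1"], [[1.0], [1.0]])
        G = lb.build_G(g)  # p = 0.5, Z = 0
        assert np.allclose(G.values, 0.0)

    def test_two_animal_hand_computation(self):
        # codes (0, 2), p = 0.5: Z = (-1, 1), denom = 0.5
        g = GenotypeMatrix([1, 2], ["s1"], [[0.0], [2.0]])
        G = lb.build_G(g)
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_fixed_panel_rejected(self):
        g = GenotypeMatrix([1, 2], ["s1"], [[2.0], [2.0]])
        with pytest.raises(ValueError, match="fixed"):
            lb.build_G(g)

    def test_diag_tracks_pedigree_relationships(self, small_population):
        A = lb.build_A(small_population.pedigree)
        G = lb.build_G(small_population.genotypes)
        A22 = A.subset(small_population.genotypes.ids, "A22")
        assert abs(np.diag(G.values).mean() - np.diag(A22.values).mean()) < 0.05


class TestBlendAndHinverse:
    def test_blend_limits(self):
        g = GenotypeMatrix([1, 2], ["s1"], [[0.0], [2.0]])
        G = lb.build_G(g)
        A22 = lb.RelationshipMatrix(pd.Index([1, 2]), np.eye(2), "A22")
        assert np.allclose(lb.blend_G(G, A22, 1.0).values, G.values)
        assert np.allclose(lb.blend_G(G, A22, 0.0).values, A22.values)
        blended = lb.blend_G(G, A22, 0.95)
        assert blended.values[0, 0] == pytest.approx(1.95)

    def test_no_genotyped_animals_gives_A_inverse(self, small_population):
        A = lb.build_A(small_population.pedigree)
        hinv = lb.h_inverse_single_step(A, None)
        assert np.allclose(hinv.values, np.linalg.inv(A.values), atol=1e-8)

    def test_G_equal_A_cancels(self):
        ped = toy_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = lb.build_A(ped)
        G = lb.RelationshipMatrix(A.ids, A.values.copy(), "G")
        hinv = lb.h_inverse_single_step(A, G, blend_weight=1.0)
        assert np.allclose(hinv.values, np.linalg.inv(A.values), atol=1e-8)

    def test_dense_oracle_five_animals(self):
        """H^-1 assembly equals inversion of the explicitly joined H matrix."""
        ped = toy_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        A = lb.build_A(ped)
        rng = np.random.default_rng(1)
        M = rng.integers(0, 3, size=(2, 40)).astype(float)
        geno = GenotypeMatrix([4, 5], [f"s{i}" for i in range(40)], M)
        G = lb.build_G(geno)
        A22 = A.subset([4, 5], "A22")
        Gb = lb.blend_G(G, A22, 0.95)
        hinv = lb.h_inverse_single_step(A, G, blend_weight=0.95)
        # independent oracle: build H explicitly from its joint-density blocks
        idx_n = [0, 1, 2]
        idx_g = [3, 4]
        Av = A.values
        A11, A12, A22v = Av[np.ix_(idx_n, idx_n)], Av[np.ix_(idx_n, idx_g)], Av[np.ix_(idx_g, idx_g)]
        A22i = np.linalg.inv(A22v)
        Gv = Gb.values
        H = np.zeros_like(Av)
        H[np.ix_(idx_n, idx_n)] = A11 + A12 @ A22i @ (Gv - A22v) @ A22i @ A12.T
        H[np.ix_(idx_n, idx_g)] = A12 @ A22i @ Gv
        H[np.ix_(idx_g, idx_n)] = H[np.ix_(idx_n, idx_g)].T
        H[np.ix_(idx_g, idx_g)] = Gv
        assert np.allclose(hinv.values, np.linalg.inv(H), atol=1e-8)

    def test_nongenotyped_block_matches_A_inverse_increment(self, small_population):
        """H^-1 differs from A^-1 only on the genotyped block."""
        A = lb.build_A(small_population.pedigree)
        G = lb.build_G(small_population.genotypes)
        hinv = lb.h_inverse_single_step(A, G)
        Ainv = np.linalg.inv(A.values)
        gset = set(small_population.genotypes.ids)
        non = [A.ids.get_loc(i) for i in A.ids if i not in gset]
        sub = np.ix_(non, non)
        assert np.allclose(hinv.values[sub], Ainv[sub], atol=1e-8)

    def test_id_mismatch_rejected(self):
        g = GenotypeMatrix([1, 2], ["s1"], [[0.0], [2.0]])
        G = lb.build_G(g)
        A22 = lb.RelationshipMatrix(pd.Index([7, 8]), np.eye(2), "A22")
        with pytest.raises(ValueError):
            lb.blend_G(G, A22)
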