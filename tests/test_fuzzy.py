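import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform

import evoregion as ev
from conftest import random_tree_and_presence


@pytest.fixture
def toy_q(toy_distances):
    return ev.build_q(ev.phylo_similarity(toy_distances))


class TestPhyloSimilarity:
    def test_linear_transform(self, toy_distances):
        s = ev.phylo_similarity(toy_distances)
        assert s.loc["A", "B"] == pytest.approx(0.5)
        assert s.loc["A", "C"] == 0 and s.loc["B", "C"] == 0
        assert np.all(np.diag(s) == 1)

    def test_two_tips(self):
        d = pd.DataFrame([[0, 2], [2, 0]], index=["A", "B"], columns=["A", "B"])
        s = ev.phylo_similarity(d)
        assert s.loc["A", "B"] == 0

    def test_star_tree_symmetric(self):
        t = ev.read_newick("(A:1,B:1,C:1,D:1);")
        s = ev.phylo_similarity(ev.patristic_distances(t))
        off = s.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_zero_distances_rejected(self):
        d = pd.DataFrame(np.zeros((2, 2)), index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            ev.phylo_similarity(d)


class TestBuildQ:
    def test_hand_arithmetic(self, toy_q):
        # column A of s is (1, 0.5, 0); standardized: (2/3, 1/3, 0)
        assert toy_q["A"].tolist() == pytest.approx([2 / 3, 1 / 3, 0])

    def test_identity_similarity(self):
        s = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        assert np.allclose(ev.build_q(s), np.eye(3))

    def test_columns_sum_to_one(self, toy_q):
        assert np.allclose(toy_q.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(np.diag(toy_q) >= toy_q.to_numpy().max(axis=0) - 1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(arrays(float, (5, 5), elements=st.floats(0.0, 1.0)))
    def test_standardization_properties(self, raw):
        """For any similarity with unit diagonal, Q columns sum to 1 and
        the diagonal dominates each column."""
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 1.0)
        q = ev.build_q(pd.DataFrame(s, index=list("ABCDE"),
                                    columns=list("ABCDE")))
        assert np.abs(q.sum(axis=0) - 1).max() < 1e-12
        assert np.all(np.diag(q) >= q.to_numpy().max(axis=0) - 1e-12)


class TestBuildP:
    def test_identity_q_all_species(self):
        q = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        pres = pd.DataFrame([[1, 1, 1]], columns=list("ABC"))
        p = ev.build_p(pres, q)
        assert p.iloc[0].tolist() == pytest.approx([1 / 3] * 3)

    def test_identity_q_single_species(self):
        q = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        pres = pd.DataFrame([[0, 1, 0]], columns=list("ABC"))
        assert ev.build_p(pres, q).iloc[0].tolist() == [0, 1, 0]

    def test_hand_arithmetic_two_cells(self, toy_q):
        pres = pd.DataFrame([[1, 1, 0], [0, 1, 1]], columns=list("ABC"))
        p = ev.build_p(pres, toy_q)
        # cell 1 holds {A,B}: raw = (1, 1, 0), normalized (0.5, 0.5, 0)
        assert p.iloc[0].tolist() == pytest.approx([0.5, 0.5, 0])
        # cell 2 holds {B,C}: raw = (1/3, 2/3, 1), normalized (1/6, 1/3, 1/2)
        assert p.iloc[1].tolist() == pytest.approx([1 / 6, 1 / 3, 1 / 2])

    def test_misaligned_species_rejected(self, toy_q):
        pres = pd.DataFrame([[1, 1, 0]], columns=list("CAB"))
        with pytest.raises(ValueError, match="order"):
            ev.build_p(pres, toy_q)


class TestBrayCurtis:
    def test_extremes(self):
        p = pd.DataFrame([[0.5, 0.5, 0], [0.5, 0.5, 0], [0, 0, 1]])
        d = ev.sqrt_bray_curtis(p)
        assert d.iloc[0, 1] == 0
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        p = pd.DataFrame([[0.5, 0.5, 0], [0, 0.5, 0.5]])
        d = ev.sqrt_bray_curtis(p)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(0.5))


class TestPcoa:
    def test_three_equidistant_points(self):
        d = pd.DataFrame(1.0 - np.eye(3))
        res = ev.pcoa(d)
        rec = squareform(pdist(res.axes.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_collinear_points_single_axis(self):
        x = np.array([[0.0], [1.0], [3.0]])
        d = pd.DataFrame(squareform(pdist(x)))
        res = ev.pcoa(d)
        big = res.eigenvalues[res.relative_variance > 1e-9]
        assert len(big) == 1
        coord = np.sort(res.axes.iloc[:, 0].to_numpy())
        assert np.allclose(np.diff(coord), [1, 2]) or \
            np.allclose(np.diff(coord), [2, 1])

    @pytest.mark.parametrize("seed", range(4))
    def test_reconstruction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 3))
        d = pd.DataFrame(squareform(pdist(x)))
        res = ev.pcoa(d)
        rec = squareform(pdist(res.axes.to_numpy()))
        assert np.abs(rec - d.to_numpy()).max() < 1e-8

    def test_agrees_with_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(1)
        x = rng.normal(size=(9, 4))
        d = squareform(pdist(x))
        mine = ev.pcoa(pd.DataFrame(d))
        ref = skbio_ord.pcoa(d)
        ref_vals = np.sort(np.asarray(ref.eigvals))[::-1]
        assert np.allclose(ref_vals[:4], mine.eigenvalues[:4], atol=1e-8)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_q_and_p_standardization(self, seed):
        rng = np.random.default_rng(seed)
        tree, pres = random_tree_and_presence(rng)
        d = ev.patristic_distances(tree)
        q = ev.build_q(ev.phylo_similarity(d))
        p = ev.build_p(pres, q)
        assert np.allclose(q.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert p.to_numpy().min() >= 0 and p.to_numpy().max() <= 1

    def test_single_species_cells_reduce_to_q_rows(self, toy_q):
        pres = pd.DataFrame(np.eye(3, dtype=int), columns=list("ABC"))
        p = ev.build_p(pres, toy_q)
        expected = toy_q.to_numpy() / toy_q.sum(axis=1).to_numpy()[:, None]
        assert np.allclose(p.to_numpy(), expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_sqrt_transform_avoids_negative_eigenvalues(self, seed):
        rng = np.random.default_rng(seed)
        p = pd.DataFrame(rng.dirichlet(np.ones(6), size=12))
        d = ev.sqrt_bray_curtis(p).to_numpy()
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        vals = np.linalg.eigvalsh(-0.5 * j @ (d ** 2) @ j)
        assert vals.min() > -1e-10

    def test_transformer_pipeline(self, toy_distances):
        pres = pd.DataFrame([[1, 1, 0], [0, 1, 1], [1, 0, 1]],
                            columns=list("ABC"))
        fw = ev.PhylogeneticFuzzyWeighting(distances=toy_distances).fit()
        p = fw.transform(pres)
        axes = ev.PCPS(var_threshold=0.05).fit_transform(p)
        assert axes.shape[0] == 3 and axes.shape[1] >= 1
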