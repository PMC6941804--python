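"""Bray-Curtis, PCoA, PERMANOVA and dispersion homogeneity."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from daphnofit import beta
from daphnofit.datatypes import DistanceMatrix, OtuTable, ValidationError


def _table(rows, treatments=None):
    counts = pd.DataFrame(rows)
    counts.index = [f"s{i}" for i in range(counts.shape[0])]
    counts.columns = [f"o{i}" for i in range(counts.shape[1])]
    tax = pd.DataFrame({"family": [f"F{i}" for i in range(counts.shape[1])]},
                       index=counts.columns)
    treatments = treatments or [0.0] * counts.shape[0]
    meta = pd.DataFrame({"treatment": treatments, "clutch": 1, "day": 9},
                        index=counts.index)
    return OtuTable(counts, tax, meta)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = beta.bray_curtis(_table([[3, 3, 0], [3, 3, 0]]), transform="none")
        assert d.data[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d = beta.bray_curtis(_table([[5, 0], [0, 7]]), transform="none")
        assert d.data[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # |1-0|+|1-1|+|0-1| over (1+0)+(1+1)+(0+1) = 2/4
        d = beta.bray_curtis(_table([[1, 1, 0], [0, 1, 1]]), transform="none")
        assert d.data[0, 1] == pytest.approx(0.5)

    def test_zero_total_sample_named(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["s0", "s1"],
                              columns=["o0", "o1"])
        tax = pd.DataFrame({"family": ["F0", "F1"]}, index=counts.columns)
        meta = pd.DataFrame({"treatment": [0.0, 0.0]}, index=counts.index)
        with pytest.raises(ValidationError, match="s1"):
            beta.bray_curtis(OtuTable(counts, tax, meta), transform="none")

    def test_family_aggregation_used(self, toy_otu_table):
        d = beta.bray_curtis(toy_otu_table, rank="family")
        assert d.shape == (3, 3)
        assert np.all(d.data <= 1 + 1e-12)


class TestPcoa:
    def test_planted_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        d = DistanceMatrix(squareform(pdist(pts)),
                           [f"s{i}" for i in range(12)])
        res = beta.pcoa(d)
        x = res.coordinates.to_numpy()[:, :2]
        # Procrustes: align by orthogonal rotation, compare residual
        a = pts - pts.mean(axis=0)
        b = x - x.mean(axis=0)
        u, _, vt = np.linalg.svd(b.T @ a)
        rot = u @ vt
        err = np.sum((b @ rot - a) ** 2)
        assert err < 1e-8

    def test_identical_samples_identical_coordinates(self):
        d = DistanceMatrix(np.array([[0, 0, 1.0], [0, 0, 1.0], [1, 1, 0.0]]),
                           ["a", "b", "c"])
        res = beta.pcoa(d)
        np.testing.assert_allclose(res.coordinates.loc["a"],
                                   res.coordinates.loc["b"], atol=1e-10)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(1)
        x = rng.random((8, 5))
        t = _table((x * 20).astype(int) + 1)
        d = beta.bray_curtis(t)
        res = beta.pcoa(d)
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = j @ (-0.5 * d.data ** 2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-10)

    def test_negative_eigenvalues_reported(self):
        # semi-metric Bray-Curtis usually produces some negative eigenvalues
        rng = np.random.default_rng(2)
        t = _table(rng.integers(0, 30, size=(10, 6)) + 1)
        res = beta.pcoa(beta.bray_curtis(t))
        assert res.eigenvalues.min() < 0


def permanova_exact_p(d, labels):
    """Exhaustive enumeration over all distinct two-group relabelings."""
    labels = np.asarray(labels)
    n = len(labels)
    idx_a = [set(c) for c in combinations(range(n), int((labels == labels[0]).sum()))]
    d2 = d.data ** 2
    groups = np.unique(labels)

    def f_for(lab):
        return beta._pseudo_f(d2, lab, n, len(groups))[0]

    f_obs = f_for(labels)
    count = 0
    for subset in idx_a:
        lab = np.where([i in subset for i in range(n)], labels[0],
                       [l for l in labels if l != labels[0]][0])
        if f_for(lab) >= f_obs - 1e-12:
            count += 1
    return count / len(idx_a)


class TestPermanova:
    def _two_cloud_matrix(self, gap, n_per=3, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n_per, 2)),
                         rng.normal(gap, 1, (n_per, 2))])
        d = DistanceMatrix(squareform(pdist(pts)),
                           [f"s{i}" for i in range(2 * n_per)])
        labels = np.array(["a"] * n_per + ["b"] * n_per)
        return d, labels

    def test_exact_enumeration_oracle(self):
        d, labels = self._two_cloud_matrix(gap=2.0, seed=3)
        exact = permanova_exact_p(d, labels)
        # run with the full permutation distribution approximated densely
        res = beta.permanova(d, labels, n_perm=4999, seed=1)
        assert res["p"] == pytest.approx(exact, abs=0.03)

    def test_maximal_separation(self):
        # groups large enough that a random shuffle essentially never
        # regenerates the observed partition
        d, labels = self._two_cloud_matrix(gap=500.0, n_per=10, seed=4)
        res = beta.permanova(d, labels, n_perm=199, seed=2)
        assert res["p"] == pytest.approx(1 / 200)
        assert res["R2"] > 0.99

    def test_invariant_to_reordering_and_renaming(self):
        d, labels = self._two_cloud_matrix(gap=1.0, n_per=4, seed=5)
        res1 = beta.permanova(d, labels, n_perm=99, seed=9)
        perm = np.random.default_rng(6).permutation(len(labels))
        d2 = DistanceMatrix(d.data[np.ix_(perm, perm)],
                            [d.ids[i] for i in perm])
        renamed = np.where(labels[perm] == "a", "x", "y")
        res2 = beta.permanova(d2, renamed, n_perm=99, seed=9)
        assert res2["pseudo_F"] == pytest.approx(res1["pseudo_F"], rel=1e-10)
        assert res2["R2"] == pytest.approx(res1["R2"], rel=1e-10)

    def test_euclidean_ss_matches_classical_anova(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 3))
        labels = np.repeat(["a", "b", "c"], 3)
        d = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(9)])
        res = beta.permanova(d, labels, n_perm=9, seed=0)
        grand = pts.mean(axis=0)
        ss_tot = np.sum((pts - grand) ** 2)
        ss_w = sum(np.sum((pts[labels == g] - pts[labels == g].mean(axis=0)) ** 2)
                   for g in "abc")
        assert res["SS_total"] == pytest.approx(ss_tot, rel=1e-10)
        assert res["SS_resid"] == pytest.approx(ss_w, rel=1e-10)

    def test_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d, labels = self._two_cloud_matrix(gap=1.5, n_per=5, seed=8)
        ours = beta.permanova(d, labels, n_perm=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.data, d.ids), labels,
            permutations=99)
        assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"],
                                                 rel=1e-10)

    def test_small_group_rejected(self):
        d = DistanceMatrix(np.array([[0, 1, 1.0], [1, 0, 1], [1, 1, 0]]),
                           ["a", "b", "c"])
        with pytest.raises(ValidationError):
            beta.permanova(d, ["g1", "g1", "g2"])


class TestPairwisePermanova:
    def test_two_groups_adjusted_equals_raw(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 2))
        d = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        out = beta.pairwise_permanova(d, labels, n_perm=99, seed=1)
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_divergent_group_flagged(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.5, (5, 2)),
                         rng.normal(0, 0.5, (5, 2)),
                         rng.normal(8, 0.5, (5, 2))])
        d = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(15)])
        labels = np.repeat(["a", "b", "c"], 5)
        out = beta.pairwise_permanova(d, labels, n_perm=199, seed=2)
        flagged = out[out["p_adj"] < 0.05]
        assert set(map(tuple, flagged[["group_a", "group_b"]].to_numpy())) == \
            {("a", "c"), ("b", "c")}


class TestBetadisper:
    def test_hand_computable_euclidean_toy(self):
        pts = np.array([[0, 0], [2, 0], [1, 2],      # group a
                        [10, 0], [14, 0], [12, 4.0]])  # group b
        d = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(6)])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = beta.betadisper(d, labels, n_perm=99, seed=0)
        for g in ("a", "b"):
            sub = pts[labels == g]
            expected = np.linalg.norm(sub - sub.mean(axis=0), axis=1).mean()
            assert res["group_means"][g] == pytest.approx(expected, abs=1e-8)

    def test_degenerate_equal_distances_error(self):
        # two groups, each duplicated at its centroid -> all distances 0
        pts = np.array([[0, 0], [0, 0], [5, 0], [5, 0.0]])
        d = DistanceMatrix(squareform(pdist(pts)), list("abcd"))
        with pytest.raises(ValidationError):
            beta.betadisper(d, ["g1", "g1", "g2", "g2"], n_perm=19, seed=0)

    def test_unequal_dispersion_detected(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 0.2, (10, 2)),
                         rng.normal(0, 3.0, (10, 2))])
        d = DistanceMatrix(squareform(pdist(pts)), [str(i) for i in range(20)])
        res = beta.betadisper(d, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=3)
        assert res["p"] < 0.05
        assert res["group_means"]["b"] > res["group_means"]["a"]
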