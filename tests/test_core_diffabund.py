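"""Core-microbiome filters, zeta classes, TMM, NB exact test and BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from daphnofit import core_diffabund as cd
from daphnofit.datatypes import OtuTable, ValidationError


def _table(rows, treatments=None, genus=None):
    counts = pd.DataFrame(rows)
    counts.index = [f"s{i}" for i in range(counts.shape[0])]
    counts.columns = [f"o{i}" for i in range(counts.shape[1])]
    genus = genus or [f"G{i}" for i in range(counts.shape[1])]
    tax = pd.DataFrame({"genus": genus}, index=counts.columns)
    treatments = treatments if treatments is not None \
        else [0.0] * counts.shape[0]
    meta = pd.DataFrame({"treatment": treatments, "clutch": 1, "day": 9},
                        index=counts.index)
    return OtuTable(counts, tax, meta)


class TestCoreFilter:
    def test_ubiquitous_taxon_retained(self):
        t = _table([[100, 9900], [200, 19800]])
        assert "o0" in cd.core_filter(t)  # 1% everywhere

    def test_rare_taxon_dropped(self):
        # 0.005% everywhere, below the 0.01% detection threshold
        t = _table([[1, 19999], [1, 19999]])
        assert "o0" not in cd.core_filter(t, detection=1e-4)

    def test_hand_evaluated_toy(self):
        # 5 samples x 4 taxa at depth 10000; detection 1e-4 -> count >= 1;
        # prevalence 0.2 -> detected in >= 1 of 5 samples
        rows = [[10, 0, 1, 9989],
                [0, 0, 0, 10000],
                [0, 0, 2, 9998],
                [0, 0, 0, 10000],
                [0, 0, 1, 9999]]
        t = _table(rows)
        kept = set(cd.core_filter(t, prevalence=0.4, detection=1e-4))
        # o0 detected in 1/5 (<40%); o1 never; o2 in 3/5; o3 always
        assert kept == {"o2", "o3"}


class TestSharedUnique:
    def test_single_group_core_is_own_set(self):
        t = _table([[5, 5, 0], [6, 4, 0]])
        res = cd.shared_unique_sets(t, ["g"] * 2, min_count=4, prevalence=0.5)
        assert res.core == {"o0", "o1"} == res.group_sets["g"]

    def test_disjoint_groups_no_core(self):
        t = _table([[9, 0], [9, 0], [0, 9], [0, 9]],
                   treatments=[0, 0, 1, 1])
        res = cd.shared_unique_sets(t, ["a", "a", "b", "b"])
        assert res.core == set()
        assert res.shared_fraction == 0.0

    def test_four_group_regions_match_enumeration(self):
        # construct qualifying sets directly: taxon j present in group g iff
        # bit g of j is set; every Venn region then has exactly one OTU
        n_groups, n_taxa = 4, 16
        rows, labels = [], []
        for g in range(n_groups):
            row = [9 if (j >> g) & 1 else 0 for j in range(n_taxa)]
            rows.extend([row, row])
            labels.extend([f"g{g}"] * 2)
        t = _table(rows)
        res = cd.shared_unique_sets(t, labels)
        # 15 non-empty regions, one OTU each (taxon 0 is in no group)
        assert len(res.union) == 15
        assert sum(res.regions.values()) == len(res.union)
        assert res.region_count("g0", "g1", "g2", "g3") == 1
        assert res.region_count("g0") == 1
        assert res.core == {f"o{2**4 - 1}"}
        assert res.shared_fraction == pytest.approx(1 / 15)


class TestZetaClassify:
    def test_hand_standardization(self):
        traits = pd.DataFrame({"bl": [2.0, 4.0, 6.0]}, index=list("abc"))
        out = cd.zeta_classify(traits, [1, 1, 1])
        np.testing.assert_allclose(out["zeta_bl"],
                                   [-1.0, 0.0, 1.0], atol=1e-12)
        # tie at the mean is "not above" -> class 0
        assert out["class_bl"].tolist() == [0, 0, 1]

    def test_per_clutch_moments(self):
        rng = np.random.default_rng(0)
        traits = pd.DataFrame({"bl": rng.normal(3, 0.3, 24)},
                              index=[f"i{j}" for j in range(24)])
        clutch = np.repeat([1, 2, 3, 4], 6)
        out = cd.zeta_classify(traits, clutch)
        for c in range(1, 5):
            z = out["zeta_bl"][clutch == c]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_trait_names_clutch(self):
        traits = pd.DataFrame({"bl": [2.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        with pytest.raises(ValidationError, match="7"):
            cd.zeta_classify(traits, [7, 7, 8, 8])


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame([[10, 20, 30]] * 3, index=list("abc"))
        f = cd.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_change_unit_factors(self):
        base = np.array([40, 80, 120, 160, 600])
        counts = pd.DataFrame([base, base * 2, base * 5], index=list("abc"))
        f = cd.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-9)

    def test_composition_bias_corrected(self):
        # sample b doubles one dominant taxon; TMM factor should move to
        # compensate so the unchanged taxa align
        rng = np.random.default_rng(1)
        base = rng.integers(50, 200, 30)
        other = base.copy()
        other[0] = base[0] * 20
        counts = pd.DataFrame([base, other], index=list("ab"))
        f = cd.tmm_factors(counts)
        lib = counts.sum(axis=1)
        # after normalization, the median unchanged-taxon ratio is ~1
        norm = counts.div(lib * f, axis=0)
        ratios = (norm.iloc[1, 1:] / norm.iloc[0, 1:]).to_numpy()
        assert np.median(ratios) == pytest.approx(1.0, rel=0.05)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 500, size=(6, 40)))
        f = cd.tmm_factors(counts)
        assert np.prod(f) == pytest.approx(1.0, rel=1e-10)


class TestCommonDispersion:
    def test_poisson_data_gives_zero(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(12, 60)))
        classes = [0] * 6 + [1] * 6
        phi = cd.estimate_common_dispersion(counts, classes)
        assert phi == pytest.approx(0.0, abs=5e-3)

    def test_single_taxon_equal_counts(self):
        counts = pd.DataFrame({"t": [30, 30, 30, 30]})
        phi = cd.estimate_common_dispersion(counts, [0, 0, 1, 1])
        assert phi == pytest.approx(0.0, abs=1e-6)

    def test_nb_parameter_recovery(self):
        rng = np.random.default_rng(4)
        phi_true = 0.2
        r = 1 / phi_true
        mu = rng.uniform(20, 200, 100)
        counts = pd.DataFrame(
            rng.negative_binomial(r, r / (r + mu), size=(16, 100)))
        phi = cd.estimate_common_dispersion(counts, [0] * 8 + [1] * 8)
        assert phi == pytest.approx(phi_true, abs=0.05)


class TestNbExactTest:
    def test_poisson_limit_matches_conditional_binomial(self):
        counts = pd.DataFrame({"t1": [12, 9, 30, 25], "t2": [100, 110, 95, 105]})
        classes = [0, 0, 1, 1]
        lib = cd.effective_lib_sizes(counts)
        l0 = lib.iloc[:2].sum()
        res = cd.nb_exact_test(counts, classes, phi=0.0,
                               factors=pd.Series(1.0, index=counts.index))
        lib_raw = counts.sum(axis=1)
        p_null = lib_raw.iloc[:2].sum() / lib_raw.sum()
        for taxon in counts.columns:
            s0 = counts[taxon].iloc[:2].sum()
            t = counts[taxon].sum()
            oracle = stats.binomtest(int(s0), int(t), float(p_null)).pvalue
            assert res.loc[taxon, "p"] == pytest.approx(oracle, rel=1e-9)

    def test_balanced_identical_sums_null(self):
        counts = pd.DataFrame({"t": [10, 20, 20, 10]})
        res = cd.nb_exact_test(counts, [0, 0, 1, 1], phi=0.1)
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["log2FC"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(40, size=(6, 8)))
        a = cd.nb_exact_test(counts, [0, 0, 0, 1, 1, 1], phi=0.05)
        b = cd.nb_exact_test(counts, [1, 1, 1, 0, 0, 0], phi=0.05)
        np.testing.assert_allclose(a["log2FC"], -b["log2FC"], atol=1e-10)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_empty_class_rejected(self):
        counts = pd.DataFrame({"t": [1, 2]})
        with pytest.raises(ValidationError):
            cd.nb_exact_test(counts, [0, 0], phi=0.0)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(cd.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert cd.bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(cd.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(size=30)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(cd.bh_fdr(p), ref, atol=1e-12)

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        base = cd.bh_fdr(p)
        bumped = p.copy()
        bumped[4] = min(1.0, bumped[4] + 0.2)
        assert np.all(cd.bh_fdr(bumped) >= base - 1e-12)


class TestDifferentialAbundance:
    def _planted_table(self, seed, fold=8.0, n_samples=16, n_genera=25,
                       depth=3000):
        rng = np.random.default_rng(seed)
        base = rng.dirichlet(np.ones(n_genera) * 2)
        classes = np.array([0, 1] * (n_samples // 2))
        rows = []
        for c in classes:
            p = base.copy()
            if c == 1:
                p[0] *= fold
            p /= p.sum()
            rows.append(rng.multinomial(depth, p))
        t = _table(rows, genus=[f"G{i}" for i in range(n_genera)])
        return t, pd.Series(classes, index=t.sample_ids)

    def test_planted_genus_detected(self):
        t, classes = self._planted_table(seed=8)
        res = cd.differential_abundance(t, grouping="phenotype",
                                        classes=classes)
        assert "G0" in res.significant
        assert res.table.loc["G0", "log2FC"] > 0

    def test_null_table_mostly_clean(self):
        t, classes = self._planted_table(seed=9, fold=1.0)
        res = cd.differential_abundance(t, grouping="phenotype",
                                        classes=classes)
        assert len(res.significant) <= 1

    def test_exposure_mode_contrasts_each_concentration(self):
        rng = np.random.default_rng(10)
        rows = rng.multinomial(2000, np.ones(10) / 10, size=12)
        t = _table(rows, treatments=[0, 0, 0, 0, 0.1, 0.1, 0.1, 0.1,
                                     1, 1, 1, 1])
        out = cd.differential_abundance(t, grouping="exposure")
        assert set(out.keys()) == {0.1, 1.0}

    def test_missing_class_named(self):
        t, classes = self._planted_table(seed=11)
        with pytest.raises(ValidationError, match="s0"):
            cd.differential_abundance(t, grouping="phenotype",
                                      classes=classes.drop(index=["s0"]))
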