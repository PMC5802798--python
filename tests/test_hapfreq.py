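"""Haplogroup binning, frequency matrices, clustering, PCA, Fisher tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtstruct as m
from mtstruct.hapfreq import (
    CEPT23, EPT25, WORLD23, FrequencyMatrix, HapFreqError, assign_bin,
    bootstrap_support, build_frequency_matrix, build_metapopulation,
    fisher_rxc, pca_frequencies, ward_cluster,
)


class TestAssignBin:
    @pytest.mark.parametrize("label,scheme,expected", [
        ("U5a1d1", CEPT23, "U5a"),
        ("H5a1", CEPT23, "H5"),       # specificity: H5 beats H
        ("H28a1", CEPT23, "H"),
        ("HV18", CEPT23, "HV"),
        ("N1a1", CEPT23, "N1a"),
        ("K2a", CEPT23, "K"),
        ("L3e", CEPT23, "others"),
        ("C4a", EPT25, "Asian"),
        ("V3", EPT25, "V/HV0"),
        ("HV0a", EPT25, "V/HV0"),
        ("L2a1", WORLD23, "African"),
        ("I1a", WORLD23, "I1"),
    ])
    def test_longest_prefix_and_macro_rules(self, label, scheme, expected):
        assert assign_bin(label, scheme) == expected

    @settings(derandomize=True, max_examples=80)
    @given(st.text(alphabet="ABCDEFGHIJKLNRTUVWXZ0123456789ab", min_size=1, max_size=8))
    def test_total_and_idempotent(self, label):
        for scheme in (CEPT23, EPT25, WORLD23):
            bin_ = assign_bin(label, scheme)
            assert bin_ in scheme.bins
            if bin_ not in ("others", "Asian", "African", "V/HV0"):
                assert assign_bin(bin_, scheme) == bin_

    def test_empty_label_rejected(self):
        with pytest.raises(HapFreqError):
            assign_bin("", CEPT23)


class TestFrequencyMatrix:
    def test_counts_tabulated_and_zero_bins_retained(self):
        fm = build_frequency_matrix(
            {"s1": ("KOW", "H1a"), "s2": ("KOW", "H5a1"), "s3": ("KOW", "U5b1d")},
            CEPT23)
        row = fm.counts.loc["KOW"]
        assert row["H"] == 1 and row["H5"] == 1 and row["U5b"] == 1
        assert row.sum() == 3
        assert set(fm.bins) == set(CEPT23.bins)

    def test_published_assignments_row_conserves_forty(self, kowalewko_metadata):
        kept, _ = m.filter_assignments(
            kowalewko_metadata, exclusion_list=["PCA0018", "PCA0063"])
        fm = build_frequency_matrix(
            {sid: ("Kow-OVIA", meta.haplogroup_label) for sid, meta in kept.items()},
            CEPT23)
        assert fm.counts.loc["Kow-OVIA"].sum() == 40
        assert fm.frequencies.loc["Kow-OVIA"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_input_order_irrelevant(self):
        items = [("s1", ("A", "H")), ("s2", ("B", "U5a")), ("s3", ("A", "K"))]
        a = build_frequency_matrix(dict(items), CEPT23)
        b = build_frequency_matrix(dict(reversed(items)), CEPT23)
        assert (a.counts == b.counts).all().all()


class TestWardClustering:
    def test_identical_rows_merge_first_at_zero(self):
        counts = pd.DataFrame([[5, 5], [5, 5], [9, 1]],
                              index=["a", "b", "c"], columns=["x", "y"])
        dendro = ward_cluster(FrequencyMatrix(counts))
        assert dendro.clusters()[0] == frozenset({"a", "b"})
        assert dendro.heights()[0] == pytest.approx(0.0)

    def test_one_dimensional_hand_case(self):
        # frequencies 0, 1/11, 10/11 on one informative axis: {0, 1/11} first
        counts = pd.DataFrame([[0, 10], [1, 10], [10, 1]],
                              index=["p0", "p1", "p10"], columns=["x", "y"])
        dendro = ward_cluster(FrequencyMatrix(counts))
        assert dendro.clusters()[0] == frozenset({"p0", "p1"})

    def test_heights_monotone(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 20, size=(8, 6)),
                              index=[f"p{i}" for i in range(8)])
        dendro = ward_cluster(FrequencyMatrix(counts))
        assert (np.diff(dendro.heights()) >= -1e-12).all()

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(HapFreqError):
            ward_cluster(FrequencyMatrix(pd.DataFrame([[1, 2]], index=["a"])))


class TestBootstrapSupport:
    COUNTS = pd.DataFrame(
        [[20, 1, 0, 18, 2, 0], [18, 2, 1, 20, 0, 0],
         [0, 20, 18, 0, 1, 2], [1, 18, 20, 0, 0, 1]],
        index=["a1", "a2", "b1", "b2"], columns=[f"hap{i}" for i in range(6)])

    def test_planted_split_gets_high_support(self):
        supports = []
        for seed in range(30):
            dendro = bootstrap_support(FrequencyMatrix(self.COUNTS),
                                       n_boot=100, seed=seed)
            supports.append(dendro.support[frozenset({"a1", "a2"})])
        assert np.mean(supports) > 80

    def test_seed_determinism_and_range(self):
        fm = FrequencyMatrix(self.COUNTS)
        d1 = bootstrap_support(fm, n_boot=50, seed=9)
        d2 = bootstrap_support(fm, n_boot=50, seed=9)
        assert d1.support == d2.support
        assert all(0 <= v <= 100 for v in d1.support.values())

    def test_zero_replicates_rejected(self):
        with pytest.raises(HapFreqError):
            bootstrap_support(FrequencyMatrix(self.COUNTS), n_boot=0)


class TestPCA:
    def test_two_rows_rank_one(self):
        fm = FrequencyMatrix(pd.DataFrame([[8, 2], [2, 8]], index=["a", "b"]))
        res = pca_frequencies(fm)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_and_oracle_scores(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            fm = FrequencyMatrix(pd.DataFrame(rng.integers(0, 30, size=(10, 25))))
            res = pca_frequencies(fm)
            assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
            from sklearn.decomposition import PCA
            ref = PCA().fit(fm.frequencies.to_numpy())
            scores = ref.transform(fm.frequencies.to_numpy())
            k = res.scores.shape[1]
            assert np.abs(np.abs(scores[:, :k]) - np.abs(res.scores.to_numpy())).max() \
                < 1e-8

    def test_single_row_rejected(self):
        with pytest.raises(HapFreqError):
            pca_frequencies(FrequencyMatrix(pd.DataFrame([[1, 2]], index=["a"])))


class TestMetapopulation:
    def _pool(self, n=2000):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "country": rng.choice(["PL", "CZ", "DE", "AT"], p=[0.4, 0.2, 0.3, 0.1], size=n),
            "haplogroup": rng.choice(["H", "U5a", "K"], size=n),
        })

    def test_whole_pool_when_n_equals_size(self):
        pool = self._pool(50)
        sample, _ = build_metapopulation(pool, 50, seed=1)
        assert len(sample) == 50

    def test_different_seeds_different_sets(self):
        pool = self._pool()
        s1, _ = build_metapopulation(pool, 500, seed=1)
        s2, _ = build_metapopulation(pool, 500, seed=2)
        assert len(s1) == len(s2) == 500
        assert not s1.index.equals(s2.index)

    def test_country_proportions_reflect_pool(self):
        pool = self._pool()
        pool_frac = pool["country"].value_counts(normalize=True)
        tallies = []
        for seed in range(200):
            _, tally = build_metapopulation(pool, 500, seed=seed)
            tallies.append(tally)
        mean_frac = pd.DataFrame(tallies).fillna(0).mean() / 500
        from scipy.stats import chisquare
        obs = pd.DataFrame(tallies).fillna(0).sum()
        expected = pool_frac[obs.index] * obs.sum()
        assert chisquare(obs, expected).pvalue > 0.01
        assert (mean_frac - pool_frac[mean_frac.index]).abs().max() < 0.02

    def test_pool_too_small_rejected(self):
        with pytest.raises(HapFreqError):
            build_metapopulation(self._pool(10), 11, seed=0)


class TestFisherRxC:
    def test_2x2_exact_hand_value(self):
        assert fisher_rxc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_identical_rows_p_near_one(self):
        p = fisher_rxc([[5, 3, 2], [5, 3, 2]], n_sim=4000, seed=1)
        assert p > 0.9

    def test_monte_carlo_close_to_exact_2x2(self):
        from scipy.stats import fisher_exact
        table = np.array([[8, 3], [4, 9]])
        exact = fisher_exact(table)[1]
        from mtstruct.hapfreq import _log_table_prob
        from scipy.stats import random_table
        rng = np.random.default_rng(7)
        draws = random_table(table.sum(1), table.sum(0)).rvs(
            size=100_000, random_state=rng)
        obs = _log_table_prob(table)
        le = sum(1 for d in draws if _log_table_prob(np.asarray(d)) <= obs + 1e-9)
        mc = (1 + le) / 100_001
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc - exact) < 3 * se

    def test_degenerate_tables_rejected(self):
        with pytest.raises(HapFreqError):
            fisher_rxc([[1, 0], [2, 0]])
        with pytest.raises(HapFreqError):
            fisher_rxc([[1, 2]])
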