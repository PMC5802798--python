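"""Sequence distances, PhiST, permutation p-values, BH, MDS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtstruct as m
from mtstruct.popdist import (
    DistanceError, DistanceMatrix, classical_mds, mds_embed, seq_distance,
    squared_distance_matrix, _two_pop_phist,
)
from oracles import brute_amova, bh_bruteforce


class TestSeqDistance:
    A = ("ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT" * 5)
    # five substitutions: two A<->G transitions, one C->A, one G->T, one T->A
    B = A[:0] + "G" + A[1:7] + "C" + A[8:13] + "A" + A[14:22] + "T" + A[23:31] + "A" + A[32:]

    def test_identical_zero_under_every_model(self):
        for model in ("differences", "p", "TN93"):
            assert seq_distance(self.A, self.A, model) == 0.0

    def test_difference_count_and_proportion(self):
        assert seq_distance(self.A, self.B, "differences") == 5
        assert seq_distance(self.A, self.B, "p") == pytest.approx(5 / 200)

    def test_tn93_matches_reference_implementation(self):
        # frozen from an independent phylogenetics implementation (ape)
        assert seq_distance(self.A, self.B, "TN93") \
            == pytest.approx(0.025428405942, abs=1e-10)
        assert seq_distance(self.A, self.B, "TN93+G", gamma_shape=1.0) \
            == pytest.approx(0.025866705203, abs=1e-10)

    def test_tn93_close_to_p_at_low_divergence(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = list(a)
        for pos in rng.choice(500, size=5, replace=False):
            b[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[pos]]
        b = "".join(b)
        p = seq_distance(a, b, "p")
        tn = seq_distance(a, b, "TN93")
        assert abs(tn - p) / p < 0.05

    def test_uncalled_sites_are_pairwise_deleted(self):
        assert seq_distance("ACNT", "ACGA", "differences") == 1
        assert seq_distance("ACNT", "ACGA", "p") == pytest.approx(1 / 3)

    def test_errors(self):
        with pytest.raises(DistanceError):
            seq_distance("ACG", "AC", "differences")
        with pytest.raises(DistanceError):
            seq_distance("NNNN", "ACGT", "p")
        with pytest.raises(DistanceError, match="saturated"):
            seq_distance("ACGTACGTAC", "CGTAGTACGA", "TN93")


class TestPairwisePhist:
    def test_matches_brute_force_pair_by_pair(self):
        cfg = m.SimConfig(n_populations=3, n_per_population=[6, 8, 5],
                          region_length=200, founder_divergence=4,
                          within_theta=2, seed=31)
        ds, _ = m.simulate_divergence_populations(cfg)
        fst = m.pairwise_phist(ds)
        for i, a in enumerate(fst.labels):
            for j in range(i + 1, len(fst.labels)):
                b = fst.labels[j]
                seqs = [r.sequence for r in ds.population(a)] + \
                       [r.sequence for r in ds.population(b)]
                pops = [a] * len(ds.population(a)) + [b] * len(ds.population(b))
                _, sigma_b, sigma_c = brute_amova(seqs, pops, [[a, b]])
                assert fst.values[i, j] == pytest.approx(
                    sigma_b / (sigma_b + sigma_c), abs=1e-12)

    def test_invariant_to_within_population_order(self, two_pop_dataset):
        ds, _ = two_pop_dataset
        shuffled = m.SequenceDataset(records=list(reversed(ds.records)),
                                     metadata=dict(ds.metadata))
        a = m.pairwise_phist(ds)
        b = m.pairwise_phist(shuffled)
        assert a.to_frame().loc[a.labels, a.labels].values \
            == pytest.approx(b.to_frame().loc[a.labels, a.labels].values)

    def test_singleton_population_rejected(self):
        cfg = m.SimConfig(n_populations=2, n_per_population=[3, 1],
                          region_length=50, seed=1)
        ds, _ = m.simulate_divergence_populations(cfg)
        with pytest.raises(DistanceError, match="POP01"):
            m.pairwise_phist(ds)


class TestSlatkin:
    @pytest.mark.parametrize("fst,expected", [
        (0.0, 0.0),
        (0.5, 1.0),
        (-0.01, -0.01 / 1.01),
    ])
    def test_linearization(self, fst, expected):
        assert m.slatkin_linearize(fst) == pytest.approx(expected)

    def test_unit_fst_rejected(self):
        with pytest.raises(DistanceError):
            m.slatkin_linearize(1.0)


class TestPermutationP:
    def test_complete_fixation_minimum_attainable(self):
        cfg = m.SimConfig(n_populations=2, n_per_population=12, region_length=100,
                          founder_divergence=10, within_theta=0, seed=3)
        ds, _ = m.simulate_divergence_populations(cfg)
        p = m.fst_permutation_p(ds, ("POP00", "POP01"), n_perm=999, seed=0)
        # only the 2/C(24,12) label-preserving splits tie PhiST = 1
        assert p == pytest.approx(1 / 1000)

    def test_seed_determinism(self, two_pop_dataset):
        ds, _ = two_pop_dataset
        args = (ds, ("POP00", "POP01"))
        assert m.fst_permutation_p(*args, n_perm=99, seed=42) \
            == m.fst_permutation_p(*args, n_perm=99, seed=42)

    def test_panmictic_split_mean_phist_near_zero(self):
        vals = []
        for rep in range(60):
            cfg = m.SimConfig(n_populations=2, n_per_population=12,
                              region_length=200, founder_divergence=0,
                              within_theta=3, truth_groups=[[0, 1]],
                              seed=61000 + rep)
            ds, _ = m.simulate_divergence_populations(cfg)
            vals.append(m.pairwise_phist(ds).values[0, 1])
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals)) + 1e-3


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert m.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_hand_step_up(self):
        assert m.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(DistanceError):
            m.bh_adjust([0.0, 0.5])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_adjusted_ge_raw_and_matches_statsmodels(self, pvals):
        adj = m.bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        from statsmodels.stats.multitest import multipletests
        _, sm_adj, _, _ = multipletests(pvals, method="fdr_bh")
        assert adj == pytest.approx(sm_adj)

    def test_matches_bruteforce_on_permutations_of_six(self):
        from itertools import permutations
        base = [0.002, 0.01, 0.04, 0.05, 0.2, 0.9]
        expected = {p: a for p, a in zip(base, bh_bruteforce(base))}
        for perm in permutations(base):
            adj = m.bh_adjust(list(perm))
            assert adj == pytest.approx([expected[p] for p in perm])


class TestMDS:
    def test_equilateral_triangle_classical(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(d)
        from scipy.spatial.distance import pdist
        assert pdist(coords) == pytest.approx(np.ones(3), abs=1e-9)

    def test_perfectly_embeddable_nonmetric_stress_tiny(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 2))
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix([str(i) for i in range(7)], squareform(pdist(pts)))
        _, stress = mds_embed(dm, mode="nonmetric", seed=0)
        assert stress < 1e-6

    def test_nonmetric_not_worse_than_classical_seed(self):
        rng = np.random.default_rng(3)
        for k in range(20):
            a = rng.random((8, 8))
            d = (a + a.T) / 2
            np.fill_diagonal(d, 0)
            dm = DistanceMatrix([str(i) for i in range(8)], d)
            _, s_classical = mds_embed(dm, mode="classical")
            _, s_nonmetric = mds_embed(dm, mode="nonmetric", seed=k)
            assert s_nonmetric <= s_classical + 1e-9

    def test_negative_fst_clamped_before_embedding(self):
        vals = np.array([[0.0, -0.02, 0.1],
                         [-0.02, 0.0, 0.2],
                         [0.1, 0.2, 0.0]])
        dm = DistanceMatrix(list("abc"), vals, kind="population_fst")
        coords, stress = mds_embed(dm, mode="nonmetric", seed=0)
        assert np.isfinite(coords).all() and stress >= 0

    def test_excess_dimensions_rejected(self):
        dm = DistanceMatrix(list("ab"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(DistanceError):
            mds_embed(dm, dims=2)


class TestFullFstBundle:
    def test_compute_fst_shapes_and_bh_monotone(self, tmp_path):
        cfg = m.SimConfig(n_populations=3, n_per_population=6, region_length=150,
                          founder_divergence=5, within_theta=2, seed=17)
        ds, _ = m.simulate_divergence_populations(cfg)
        res = m.compute_fst(ds, n_perm=49, seed=3)
        assert (res.adjusted_pvalues >= res.pvalues - 1e-12).all()
        assert res.pvalues.min() > 0
        assert np.allclose(np.diag(res.linearized.values), 0)
        res.write(tmp_path / "fst")
        assert (tmp_path / "fst" / "manifest.json").exists()
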