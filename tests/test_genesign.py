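import itertools

import numpy as np
import pytest

import bubblegum as bg
from bubblegum import genesign as gs
from bubblegum import simulate as sim

from conftest import small_dataset

M = gs.SignatureMethod


def two_group(test_vals, ref_vals):
    vals = np.array([[*test_vals, *ref_vals]], dtype=float)
    classes = {f"t{i}": "T" for i in range(len(test_vals))}
    classes |= {f"r{i}": "R" for i in range(len(ref_vals))}
    return small_dataset(vals, classes), bg.ContrastSpec(("T",), ("R",))


class TestScoring:
    def test_min_vs_max(self):
        ds, c = two_group([4.1, 3.9], [2.0, 2.5])
        assert gs.score_genes(ds, c, M.MIN_VS_MAX)[0] == pytest.approx(3.9 / 2.5)

    def test_snr_with_sample_sd(self):
        ds, c = two_group([4.0, 6.0], [1.0, 3.0])
        expected = (5 - 2) / (np.sqrt(2) + np.sqrt(2))
        assert gs.score_genes(ds, c, M.SNR)[0] == pytest.approx(expected)

    def test_flat_gene_snr_is_zero(self):
        ds, c = two_group([5.0, 5.0], [5.0, 5.0])
        assert gs.score_genes(ds, c, M.SNR)[0] == 0.0

    def test_min_pairwise_mean_ratio_enumerates_class_pairs(self):
        vals = np.array([[4, 4, 6, 6, 2, 2, 3, 3.0]])
        classes = {"a1": "T1", "a2": "T1", "b1": "T2", "b2": "T2",
                   "c1": "R1", "c2": "R1", "d1": "R2", "d2": "R2"}
        ds = small_dataset(vals, classes)
        c = bg.ContrastSpec(("T1", "T2"), ("R1", "R2"))
        got = gs.score_genes(ds, c, M.MIN_PAIRWISE_MEAN_RATIO)[0]
        brute = min(t / r for t in (4, 6) for r in (2, 3))
        assert got == pytest.approx(brute) == pytest.approx(4 / 3)

    def test_nonpositive_value_under_ratio_names_gene_and_sample(self):
        ds, c = two_group([4.0, -1.0], [2.0, 2.0])
        with pytest.raises(bg.ValidationError, match="g1.*t1|t1.*g1"):
            gs.score_genes(ds, c, M.MEAN_RATIO)

    def test_single_replicate_snr_rejected(self):
        ds, c = two_group([4.0], [2.0, 2.0])
        with pytest.raises(bg.ReplicateCountError):
            gs.score_genes(ds, c, M.SNR)

    def test_pairwise_never_exceeds_pooled_ratio(self, planted):
        ds, _, _ = planted
        c = bg.ContrastSpec(("P1", "P2"), ("P3", "P4", "P5", "P6", "P7"))
        pooled = gs.score_genes(ds, c, M.MEAN_RATIO)
        pairwise = gs.score_genes(ds, c, M.MIN_PAIRWISE_MEAN_RATIO)
        assert np.all(pairwise <= pooled + 1e-12)


class TestPermutationPvalues:
    def test_exhaustive_matches_enumeration_oracle(self):
        # 3-vs-3: 20 distinct splits; identity included in the count
        rng = np.random.default_rng(4)
        vals = rng.lognormal(mean=2, size=(5, 6))
        classes = {f"s{i}": ("T" if i < 3 else "R") for i in range(6)}
        ds = small_dataset(vals, classes)
        c = bg.ContrastSpec(("T",), ("R",))
        p = gs.permutation_pvalues(ds, c, M.MEAN_RATIO, n_perm=1000, seed=0)
        obs = gs.score_genes(ds, c, M.MEAN_RATIO)
        for g in range(5):
            b = 0
            for test_ix in itertools.combinations(range(6), 3):
                ref_ix = [i for i in range(6) if i not in test_ix]
                score = vals[g, list(test_ix)].mean() / vals[g, ref_ix].mean()
                b += score >= obs[g]
            assert p[g] == pytest.approx((b + 1) / 21)

    def test_sampled_close_to_exhaustive(self):
        # 4-vs-4: 70 distinct splits; 50 sampled draws stay within 3 MC SDs
        rng = np.random.default_rng(9)
        vals = rng.lognormal(mean=2, size=(1, 8))
        classes = {f"s{i}": ("T" if i < 4 else "R") for i in range(8)}
        ds = small_dataset(vals, classes)
        c = bg.ContrastSpec(("T",), ("R",))
        obs = gs.score_genes(ds, c, M.MEAN_RATIO)[0]
        hits = 0
        for test_ix in itertools.combinations(range(8), 4):
            ref_ix = [i for i in range(8) if i not in test_ix]
            hits += vals[0, list(test_ix)].mean() / vals[0, ref_ix].mean() >= obs
        true_prop = hits / 70
        p = gs.permutation_pvalues(ds, c, M.MEAN_RATIO, n_perm=50, seed=5)[0]
        se = np.sqrt(true_prop * (1 - true_prop) / 50)
        assert abs(p - true_prop) <= 3 * se + 2 / 51

    def test_extreme_observation_gives_one_over_m_plus_one(self):
        spec = sim.SimulationSpec(n_genes=30, classes={"A": 3, "B": 18},
                                  planted_blocks={"A": (5, 6.0)}, seed=2,
                                  noise_sd=0.1)
        ds, truth = sim.simulate_dataset(spec)
        p = gs.permutation_pvalues(ds, bg.ContrastSpec(("A",), ("B",)),
                                   M.MEAN_RATIO, n_perm=99, seed=1)
        assert p.min() == pytest.approx(1 / 100)
        assert np.all(p > 0) and np.all(p <= 1)

    def test_min_vs_max_has_no_permutation_path(self, two_class_planted):
        ds, _ = two_class_planted
        with pytest.raises(bg.ValidationError, match="no permutation"):
            gs.permutation_pvalues(ds, bg.ContrastSpec(("A",), ("B",)),
                                   M.MIN_VS_MAX, 10, seed=0)

    def test_deterministic_given_seed(self, two_class_planted):
        ds, _ = two_class_planted
        c = bg.ContrastSpec(("A",), ("B",))
        a = gs.permutation_pvalues(ds, c, M.SNR, 200, seed=11)
        b = gs.permutation_pvalues(ds, c, M.SNR, 200, seed=11)
        np.testing.assert_array_equal(a, b)


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        got = gs.adjust_pvalues(np.array([0.01, 0.04, 0.03, 0.005]), "BH")
        np.testing.assert_allclose(got, [0.02, 0.04, 0.04, 0.02])

    def test_by_is_bh_times_harmonic_factor(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(gs.adjust_pvalues(p, "BY"),
                                   [0.0417, 0.0833, 0.0833, 0.0417], atol=5e-5)
        np.testing.assert_allclose(gs.adjust_pvalues(p, "BY"),
                                   np.minimum(gs.adjust_pvalues(p, "BH") * 25 / 12, 1))

    def test_single_p_of_one(self):
        for proc in ("BH", "BY"):
            assert gs.adjust_pvalues(np.array([1.0]), proc)[0] == 1.0

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(bg.ValidationError):
                gs.adjust_pvalues(np.array(bad), "BH")

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            m = int(rng.integers(1, 200))
            p = rng.uniform(1e-6, 1, size=m)
            order = np.argsort(p)
            for proc, c in (("BH", 1.0), ("BY", np.sum(1 / np.arange(1, m + 1)))):
                q_sorted = np.minimum(1, p[order] * c * m / np.arange(1, m + 1))
                q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
                expected = np.empty(m)
                expected[order] = q_sorted
                np.testing.assert_allclose(gs.adjust_pvalues(p, proc), expected,
                                           rtol=1e-12)
                assert np.all(gs.adjust_pvalues(p, proc) >= p - 1e-15)


class TestSignatures:
    def test_fold_threshold_is_strict(self):
        ds, c = two_group([4.0, 4.0], [2.0, 2.0])  # score exactly 2.0
        sig = gs.extract_signature(ds, c, M.MIN_VS_MAX, fold_threshold=2.0)
        assert len(sig) == 0 and sig.empty
        sig2 = gs.extract_signature(ds, c, M.MIN_VS_MAX, fold_threshold=1.5)
        assert sig2.genes == ["g1"]

    def test_min_vs_max_signature_holds_verbatim(self, planted):
        ds, _, _ = planted
        contrast = bg.ContrastSpec.absolute(ds, "P1")
        sig = gs.extract_signature(ds, contrast, M.MIN_VS_MAX, 1.5)
        assert len(sig) > 0
        idx = ds.gene_index()
        test_cols = ds.samples_of("P1")
        ref_cols = np.concatenate([ds.samples_of(c) for c in contrast.ref_classes])
        for g in sig.genes:
            row = ds.values[idx[g]]
            assert row[test_cols].min() > 1.5 * row[ref_cols].max()

    def test_fdr_forbidden_with_min_vs_max(self, two_class_planted):
        ds, _ = two_class_planted
        with pytest.raises(bg.ValidationError, match="not applicable"):
            gs.extract_signature(ds, bg.ContrastSpec(("A",), ("B",)),
                                 M.MIN_VS_MAX, 1.5, fdr_threshold=0.05)

    def test_rows_sorted_descending_and_fdr_at_least_p(self, two_class_planted):
        ds, _ = two_class_planted
        sig = gs.extract_signature(ds, bg.ContrastSpec(("A",), ("B",)),
                                   M.MEAN_RATIO, 1.2, fdr_threshold=0.9,
                                   n_perm=200, seed=0, procedure="BH")
        s = sig.rows["score"].to_numpy()
        assert np.all(np.diff(s) <= 0)
        assert np.all(sig.rows["fdr"] >= sig.rows["p"] - 1e-15)
        assert (sig.rows["n_test"] == 3).all() and (sig.rows["n_ref"] == 3).all()

    def test_absolute_signatures_one_per_class(self, planted):
        ds, _, _ = planted
        sigs = gs.absolute_signatures(ds, M.MIN_VS_MAX, 1.5)
        assert len(sigs) == 7
        assert all(s.contrast.mode == "absolute" for s in sigs)
        # P7 has no planted block: its absolute signature is empty, not an error
        by_name = {s.name: s for s in sigs}
        assert by_name["P7_absolute_min-vs-max"].empty

    def test_two_class_min_vs_max_signatures_disjoint(self, two_class_planted):
        ds, _ = two_class_planted
        a = gs.extract_signature(ds, bg.ContrastSpec(("A",), ("B",)), M.MIN_VS_MAX, 1.0)
        b = gs.extract_signature(ds, bg.ContrastSpec(("B",), ("A",)), M.MIN_VS_MAX, 1.0)
        assert not (set(a.genes) & set(b.genes))

    def test_single_class_dataset_rejected(self):
        ds = small_dataset(np.ones((3, 2)), {"s1": "A", "s2": "A"})
        with pytest.raises(bg.ValidationError):
            gs.absolute_signatures(ds, M.MIN_VS_MAX, 1.5)

    def test_signatures_bit_identical_across_runs(self, two_class_planted):
        ds, _ = two_class_planted
        kw = dict(fdr_threshold=0.5, n_perm=300, seed=42, procedure="BY")
        a = gs.extract_signature(ds, bg.ContrastSpec(("A",), ("B",)), M.SNR, 0.5, **kw)
        b = gs.extract_signature(ds, bg.ContrastSpec(("A",), ("B",)), M.SNR, 0.5, **kw)
        assert a.rows.equals(b.rows)
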