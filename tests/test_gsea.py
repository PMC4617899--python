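import itertools

import numpy as np
import pytest

import bubblegum as bg
from bubblegum import gsea
from bubblegum import simulate as sim


def brute_force_es(metrics, hit_positions, weight):
    """Independent running-sum oracle: walk the whole list, track the
    extremum, break magnitude ties by taking the earlier position."""
    N = len(metrics)
    hits = set(hit_positions)
    nr = sum(abs(metrics[i]) ** weight for i in hits)
    rs, best, best_abs = 0.0, 0.0, 0.0
    for i in range(N):
        if i in hits:
            rs += (abs(metrics[i]) ** weight) / nr if nr > 0 else 1 / len(hits)
        else:
            rs -= 1 / (N - len(hits))
        if abs(rs) > best_abs + 1e-9:
            best, best_abs = rs, abs(rs)
    return best


class TestRanking:
    def test_matches_independent_snr_sort(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(mean=3, size=(5, 6))
        ds = bg.ExpressionDataset(
            identifiers=[f"g{i}" for i in range(5)], values=vals,
            sample_names=[f"s{i}" for i in range(6)],
            class_of={f"s{i}": ("L" if i < 3 else "R") for i in range(6)})
        ranked = gsea.rank_genes(ds, "L", "R")
        delta = vals[vals > 0].min()
        snr = []
        for g in range(5):
            lm, rm = vals[g, :3].mean(), vals[g, 3:].mean()
            lsd = max(vals[g, :3].std(ddof=1), 0.2 * abs(lm), 0.2 * delta)
            rsd = max(vals[g, 3:].std(ddof=1), 0.2 * abs(rm), 0.2 * delta)
            snr.append((lm - rm) / (lsd + rsd))
        order = sorted(range(5), key=lambda g: -snr[g])
        assert ranked.genes == [f"g{g}" for g in order]
        np.testing.assert_allclose(ranked.metrics, sorted(snr, reverse=True))

    def test_swap_negates_and_reverses(self, two_class_planted):
        ds, _ = two_class_planted
        fwd = gsea.rank_genes(ds, "A", "B")
        rev = gsea.rank_genes(ds, "B", "A")
        np.testing.assert_array_equal(fwd.metrics, -rev.metrics[::-1])
        assert fwd.genes == rev.genes[::-1]

    def test_single_replicate_class_rejected(self):
        ds = bg.ExpressionDataset(
            identifiers=["g1"], values=np.array([[1.0, 2.0, 3.0]]),
            sample_names=["a", "b", "c"],
            class_of={"a": "L", "b": "R", "c": "R"})
        with pytest.raises(bg.ReplicateCountError, match="'L'"):
            gsea.rank_genes(ds, "L", "R")


class TestEnrichmentScore:
    def test_hand_enumerated_toy(self, toy_ranked):
        st = gsea.enrichment_score(toy_ranked, bg.GeneSet("s", "", frozenset({"g1", "g3"})),
                                   weight=1.0, min_size=1, max_size=10)
        assert st.es == pytest.approx(0.75)
        np.testing.assert_array_equal(st.hit_positions, [0, 2])
        assert st.set_size_used == 2

    def test_bottom_set_negative(self, toy_ranked):
        st = gsea.enrichment_score(toy_ranked, bg.GeneSet("s", "", frozenset({"g4", "g5"})),
                                   weight=1.0, min_size=1, max_size=10)
        assert st.es < 0

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    def test_matches_brute_force_on_all_placements(self, weight):
        rng = np.random.default_rng(17)
        for N in range(3, 9):
            metrics = np.sort(rng.normal(size=N))[::-1]
            ranked = bg.RankedList(genes=[f"g{i}" for i in range(N)],
                                   metrics=metrics, class_left="L", class_right="R")
            for k in range(1, min(3, N - 1) + 1):
                for pos in itertools.combinations(range(N), k):
                    gset = bg.GeneSet("s", "", frozenset(f"g{i}" for i in pos))
                    st = gsea.enrichment_score(ranked, gset, weight=weight,
                                               min_size=1, max_size=N)
                    assert st.es == pytest.approx(
                        brute_force_es(metrics, pos, weight), abs=1e-12)

    def test_weight_zero_equals_ks_statistic(self):
        rng = np.random.default_rng(3)
        N = 40
        metrics = np.sort(rng.normal(size=N))[::-1]
        ranked = bg.RankedList(genes=[f"g{i}" for i in range(N)], metrics=metrics,
                               class_left="L", class_right="R")
        pos = sorted(rng.choice(N, size=8, replace=False).tolist())
        gset = bg.GeneSet("s", "", frozenset(f"g{i}" for i in pos))
        st = gsea.enrichment_score(ranked, gset, weight=0.0, min_size=1, max_size=N)
        # signed two-sample KS between hit ranks and miss ranks
        hits = np.zeros(N, bool)
        hits[pos] = True
        d = np.cumsum(np.where(hits, 1 / 8, 0)) - np.cumsum(np.where(hits, 0, 1 / (N - 8)))
        expected = d[np.argmax(np.abs(d))]
        assert st.es == pytest.approx(expected, abs=1e-12)

    def test_running_sum_conserves_mass(self, toy_ranked):
        rs = gsea.running_sum(toy_ranked, np.array([0, 2]))
        assert abs(rs[-1]) < 1e-9
        assert rs.max() == pytest.approx(0.75)

    def test_size_filter_skip_signal(self, toy_ranked):
        with pytest.raises(bg.GeneSetSizeSkip):
            gsea.enrichment_score(toy_ranked, bg.GeneSet("s", "", frozenset({"g1"})),
                                  min_size=2, max_size=10)

    def test_set_covering_all_genes_degenerate(self, toy_ranked):
        full = bg.GeneSet("s", "", frozenset(toy_ranked.genes))
        with pytest.raises(bg.ValidationError, match="every ranked gene"):
            gsea.enrichment_score(toy_ranked, full, min_size=1, max_size=10)

    def test_absent_members_dropped_and_counted(self, toy_ranked):
        gset = bg.GeneSet("s", "", frozenset({"g1", "g3", "NOT_THERE"}))
        st = gsea.enrichment_score(toy_ranked, gset, min_size=1, max_size=10)
        assert st.set_size_used == 2

    def test_case_insensitive_matching(self, toy_ranked):
        st = gsea.enrichment_score(toy_ranked, bg.GeneSet("s", "", frozenset({"G1", "G3"})),
                                   min_size=1, max_size=10)
        assert st.set_size_used == 2


class TestNulls:
    def test_geneset_null_count_and_determinism(self, toy_ranked):
        a = gsea.null_enrichment_scores("geneset", 1000, 5, ranked=toy_ranked, set_size=2)
        b = gsea.null_enrichment_scores("geneset", 1000, 5, ranked=toy_ranked, set_size=2)
        assert a.shape == (1000,)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.abs(a) <= 1)

    def test_null_mean_near_zero_on_null_data(self):
        ds, _ = sim.simulate_dataset(sim.SimulationSpec(
            n_genes=400, classes={"A": 4, "B": 4}, planted_blocks={}, seed=8))
        ranked = gsea.rank_genes(ds, "A", "B")
        null = gsea.null_enrichment_scores("geneset", 2000, 1, ranked=ranked, set_size=25)
        assert abs(null.mean()) <= 3 * null.std(ddof=1) / np.sqrt(null.size)

    @pytest.mark.parametrize("replicates,ok", [(2, False), (3, False), (4, False),
                                               (5, True), (6, True), (8, True)])
    def test_sample_permutation_replicate_floor(self, replicates, ok):
        ds, _ = sim.simulate_dataset(sim.SimulationSpec(
            n_genes=60, classes={"A": replicates, "B": replicates},
            planted_blocks={}, seed=replicates))
        ranked = gsea.rank_genes(ds, "A", "B")
        gset = bg.GeneSet("s", "", frozenset(ds.identifiers[:10]))
        kw = dict(ranked=ranked, dataset=ds, geneset=gset)
        if ok:
            null = gsea.null_enrichment_scores("sample", 10, 0, **kw)
            assert null.shape == (10,)
        else:
            with pytest.raises(bg.ReplicateCountError, match="at least 5"):
                gsea.null_enrichment_scores("sample", 10, 0, **kw)

    def test_override_flag_allows_few_replicates(self):
        ds, _ = sim.simulate_dataset(sim.SimulationSpec(
            n_genes=60, classes={"A": 3, "B": 3}, planted_blocks={}, seed=0))
        ranked = gsea.rank_genes(ds, "A", "B")
        gset = bg.GeneSet("s", "", frozenset(ds.identifiers[:10]))
        null = gsea.null_enrichment_scores("sample", 5, 0, ranked=ranked, dataset=ds,
                                           geneset=gset, min_replicates_override=True)
        assert null.shape == (5,)


class TestNormalization:
    def test_forced_by_definition(self):
        nes, _ = gsea.normalize_es(0.6, np.array([0.3, 0.3, -0.2]))
        assert nes == pytest.approx(2.0)
        nes, _ = gsea.normalize_es(-0.4, np.array([0.5, -0.4, -0.4]))
        assert nes == pytest.approx(-1.0)

    def test_normalized_null_self_normalizes(self):
        rng = np.random.default_rng(0)
        null = rng.normal(scale=0.3, size=500)
        _, norm = gsea.normalize_es(0.5, null)
        assert norm[norm > 0].mean() == pytest.approx(1.0)
        assert np.abs(norm[norm < 0]).mean() == pytest.approx(1.0)

    def test_undefined_when_no_same_sign_null(self):
        nes, _ = gsea.normalize_es(0.5, np.array([-0.1, -0.2]))
        assert nes is None

    def test_nominal_p_never_zero(self):
        null = np.linspace(-0.5, 0.5, 101)
        p = gsea.nominal_pvalue(0.99, null)
        assert p == pytest.approx(1 / 52)  # 51 non-negative nulls, none as extreme
        assert gsea.nominal_pvalue(0.0, null) > 0
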