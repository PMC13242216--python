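import numpy as np
import pytest

import indurank as ir
from indurank.evaluation import (
    MetricsReport,
    RankRecord,
    aggregate_folds,
    compare_methods,
    disease_folds,
    filter_duplicate_test_diseases,
    ranking_metrics,
    tie_averaged_rank,
)

from .oracles import brute_auc_from_scores, brute_metrics


class TestFolds:
    def test_ten_diseases_ten_folds(self):
        folds = disease_folds({f"d{i}" for i in range(10)}, k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f.test_diseases) == 1 for f in folds)

    def test_partition_property(self):
        diseases = {f"d{i}" for i in range(37)}
        folds = disease_folds(diseases, k=10, seed=1)
        tests = [f.test_diseases for f in folds]
        assert frozenset().union(*tests) == diseases
        for i in range(len(tests)):
            for j in range(i + 1, len(tests)):
                assert not (tests[i] & tests[j])
        sizes = sorted(len(t) for t in tests)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic_under_seed(self):
        diseases = {f"d{i}" for i in range(23)}
        assert disease_folds(diseases, 5, seed=7) == disease_folds(diseases, 5, seed=7)

    def test_k_must_exceed_one(self):
        with pytest.raises(ValueError):
            disease_folds({"a", "b"}, k=1, seed=0)


class TestDuplicateFilter:
    profiles = {
        "train1": frozenset({"P1", "P2"}),
        "test_dup": frozenset({"P1", "P2"}),
        "test_samephen": frozenset({"P1", "P2"}),
        "test_keep": frozenset({"P3"}),
    }
    gda = ir.AssociationTable(
        ir.ASSOCIATED_WITH,
        {
            "train1": frozenset({"g1"}),
            "test_dup": frozenset({"g1"}),
            "test_samephen": frozenset({"g2"}),
            "test_keep": frozenset({"g1"}),
        },
    )

    def test_duplicate_profile_and_genes_removed(self):
        kept = filter_duplicate_test_diseases(
            {"test_dup", "test_samephen", "test_keep"}, {"train1"}, self.profiles, self.gda
        )
        assert kept == {"test_samephen", "test_keep"}

    def test_same_profile_different_genes_retained(self):
        kept = filter_duplicate_test_diseases(
            {"test_samephen"}, {"train1"}, self.profiles, self.gda
        )
        assert kept == {"test_samephen"}

    def test_empty_train_keeps_all(self):
        kept = filter_duplicate_test_diseases(
            {"test_dup"}, set(), self.profiles, self.gda
        )
        assert kept == {"test_dup"}

    def test_idempotent(self):
        once = filter_duplicate_test_diseases(
            {"test_dup", "test_keep"}, {"train1"}, self.profiles, self.gda
        )
        twice = filter_duplicate_test_diseases(once, {"train1"}, self.profiles, self.gda)
        assert once == twice


class TestTieAveragedRank:
    def test_unique_scores(self):
        scores = {"a": 0.9, "b": 0.5, "c": 0.1}
        assert tie_averaged_rank(scores, "b") == (2.0, 3)

    def test_ties_get_fractional_rank(self):
        scores = {"a": 0.9, "b": 0.5, "c": 0.5, "d": 0.5}
        rank, n = tie_averaged_rank(scores, "c")
        assert rank == 3.0 and n == 4  # positions 2,3,4 averaged

    def test_filtered_never_increases_rank(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            genes = [f"g{i}" for i in range(20)]
            scores = {g: float(rng.choice([0.1, 0.5, 0.9])) for g in genes}
            true = "g0"
            others = set(rng.choice(genes[1:], size=3, replace=False))
            unfiltered, _ = tie_averaged_rank(scores, true)
            filtered, _ = tie_averaged_rank(scores, true, exclude=others)
            assert filtered <= unfiltered


class TestMetrics:
    def test_mrr_arithmetic(self):
        records = [RankRecord("d", f"g{i}", r, 100) for i, r in enumerate([1, 2, 4])]
        report = ranking_metrics(records)
        assert report.mrr == pytest.approx((1 + 0.5 + 0.25) / 3)
        assert report.mr == pytest.approx(7 / 3)

    def test_top_rank_extremes(self):
        report = ranking_metrics([RankRecord("d", "g", 1.0, 100)])
        assert report.auc == 1.0 and report.hits[10] == 1.0 and report.mr == 1.0

    def test_single_candidate_auc_is_one(self):
        assert ranking_metrics([RankRecord("d", "g", 1.0, 1)]).auc == 1.0

    def test_hits_monotone_in_k(self):
        rng = np.random.default_rng(1)
        records = [
            RankRecord("d", f"g{i}", float(rng.integers(1, 101)), 100) for i in range(200)
        ]
        report = ranking_metrics(records, ks=(1, 5, 10, 50, 100))
        hits = [report.hits[k] for k in (1, 5, 10, 50, 100)]
        assert hits == sorted(hits)
        assert report.mrr <= 1.0 and report.mr >= 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        genes = [f"g{i}" for i in range(n)]
        scores = {g: float(rng.choice([0.1, 0.3, 0.5, 0.9])) for g in genes}
        true = genes[int(rng.integers(0, n))]
        rank, n_cand = tie_averaged_rank(scores, true)
        auc = ranking_metrics([RankRecord("d", true, rank, n_cand)]).auc
        assert auc == pytest.approx(brute_auc_from_scores(scores, true), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mr_mrr_hits_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [
            (float(rng.integers(1, 51)), 50) for _ in range(int(rng.integers(5, 100)))
        ]
        records = [RankRecord("d", f"g{i}", r, n) for i, (r, n) in enumerate(pairs)]
        report = ranking_metrics(records, ks=(1, 10))
        mr_o, mrr_o, hits_o = brute_metrics(pairs, (1, 10))
        assert report.mr == pytest.approx(mr_o)
        assert report.mrr == pytest.approx(mrr_o)
        assert report.hits == pytest.approx(hits_o)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            ranking_metrics([])

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            RankRecord("d", "g", 5.0, 3)


class TestCompareMethods:
    def test_identical_sequences_degenerate(self):
        with pytest.raises(ValueError):
            compare_methods([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])

    def test_uniform_improvement_is_significant(self):
        a = list(range(2, 22))
        b = [x + 1 for x in a]
        _, p = compare_methods(a, b)
        assert p < 0.01

    def test_symmetry_of_p_value(self):
        rng = np.random.default_rng(0)
        a = list(rng.integers(1, 100, size=15).astype(float))
        b = list(rng.integers(1, 100, size=15).astype(float))
        _, p_ab = compare_methods(a, b)
        _, p_ba = compare_methods(b, a)
        assert p_ab == pytest.approx(p_ba)


class TestAggregation:
    def test_mean_and_sample_sd_across_folds(self):
        folds = [
            MetricsReport(mr=10.0, mrr=0.5, hits={10: 0.5}, auc=0.8, n_records=5),
            MetricsReport(mr=20.0, mrr=0.3, hits={10: 0.7}, auc=0.9, n_records=5),
        ]
        agg = aggregate_folds(folds)
        assert agg.mr == 15.0
        assert agg.std["mr"] == pytest.approx(np.std([10, 20], ddof=1))
        assert agg.n_records == 10
        assert len(agg.per_fold) == 2


@pytest.fixture(scope="module")
def small_config(preset_data):
    onto, genes, diseases, gdas = preset_data
    return ir.ExperimentConfig(
            ontology=onto, gene_assoc=genes, disease_assoc=diseases, gda_assoc=gdas,
            variants=("G3", "G4"),
            methods=(
                ir.MethodSpec(name="transd-bma", type="kge", model="transd",
                              scorer="bma_e", kge_params={"dim": 16, "epochs": 40}),
                ir.MethodSpec(name="resnik-bma", type="semantic", measure="resnik"),
            ),
            n_folds=3, seed=11,
        )


class TestExperimentDriver:
    def test_run_experiment_structure_and_determinism(self, small_config):
        r1 = ir.run_experiment(small_config)
        r2 = ir.run_experiment(small_config)
        assert set(r1) == {(v, m) for v in ("G3", "G4") for m in ("transd-bma", "resnik-bma")}
        for key, report in r1.items():
            assert report.to_dict() == r2[key].to_dict()
            assert len(report.per_fold) == 3
            assert 0.0 <= report.auc <= 1.0

    def test_semantic_results_identical_across_variants(self, small_config):
        results = ir.run_experiment(small_config)
        assert (
            results[("G3", "resnik-bma")].to_dict()
            == results[("G4", "resnik-bma")].to_dict()
        )
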