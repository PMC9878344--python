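"""Unit and property tests for decoy generation, AUC, and rank statistics."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pepx.benchmark_eval import (
    BenchmarkResult,
    LigandSet,
    cohort_concordance,
    evaluate_metrics,
    generate_decoys,
    kruskal_wallis,
    paired_wilcoxon,
    range_matrix,
    roc_auc,
    spearman,
)
from pepx.errors import (
    CapacityError,
    ConfigurationError,
    DegenerateDataError,
    UndefinedCorrelationError,
)
from pepx.expression_store import CohortMatrix
from pepx.proteome_index import ProteinRecord, build_index
from pepx.synthetic_fixtures import make_planted_benchmark

from conftest import random_records


def brute_force_auc(pos, neg):
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([2, 3], [0, 1]) == 1.0

    def test_tie_symmetry(self):
        assert roc_auc([1], [1]) == 0.5

    def test_mixed_case_all_pairs(self):
        # pairs: 3>2, 3>0, 1<2, 1>0 -> 3/4
        assert roc_auc([3, 1], [2, 0]) == 0.75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=40),
        st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=40),
    )
    def test_matches_brute_force_and_complementarity(self, pos, neg):
        auc = roc_auc(pos, neg)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)
        assert auc + roc_auc(neg, pos) == pytest.approx(1.0, abs=1e-12)

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(1, 1, 50)
        neg = rng.normal(0, 1, 60)
        base = roc_auc(pos, neg)
        assert roc_auc(np.exp(pos), np.exp(neg)) == pytest.approx(base)
        pooled = sps.rankdata(np.concatenate([pos, neg]))
        assert roc_auc(pooled[:50], pooled[50:]) == pytest.approx(base)

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 8, 40).astype(float)
        neg = rng.integers(0, 8, 55).astype(float)
        labels = np.r_[np.ones(40), np.zeros(55)]
        scores = np.r_[pos, neg]
        assert roc_auc(pos, neg) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores)
        )


@pytest.fixture(scope="module")
def index():
    rng = np.random.default_rng(42)
    return build_index(random_records(rng, 30, min_len=20, max_len=60),
                       kmin=8, kmax=12)


class TestGenerateDecoys:
    def test_exact_length_distribution(self, index):
        decoys = generate_decoys(index, {9: 60, 10: 40}, n=100, seed=0)
        counts = Counter(len(d) for d in decoys)
        assert counts == {9: 60, 10: 40}

    def test_proportional_apportionment(self, index):
        decoys = generate_decoys(index, {9: 3, 10: 1}, n=40, seed=0)
        counts = Counter(len(d) for d in decoys)
        assert counts == {9: 30, 10: 10}

    def test_same_seed_reproducible(self, index):
        a = generate_decoys(index, {9: 50}, n=50, seed=123)
        b = generate_decoys(index, {9: 50}, n=50, seed=123)
        assert a == b

    def test_distinct_and_excluded(self, index):
        exclude = {o.peptide for o in index.positions_by_length(9)[:200]}
        decoys = generate_decoys(index, {9: 30}, n=30, seed=5, exclude=exclude)
        assert len(set(decoys)) == 30
        assert not set(decoys) & exclude

    def test_capacity_error_when_pool_exhausted(self):
        tiny = build_index(
            [ProteinRecord("ENSP1", "ENST1", "ENSG1", "G", "ACDEFGHIKL")],
            kmin=9, kmax=9,
        )
        all_9mers = {o.peptide for o in tiny.positions_by_length(9)}
        with pytest.raises(CapacityError):
            generate_decoys(tiny, {9: 5}, n=5, seed=0, exclude=all_9mers)

    def test_distinct_peptide_sampling_mode(self, index):
        decoys = generate_decoys(
            index, {9: 20}, n=20, seed=9, distinct_peptides=True
        )
        assert len(set(decoys)) == 20
        assert all(len(d) == 9 for d in decoys)


class TestEvaluateMetrics:
    def test_null_benchmark_near_half(self):
        bench = make_planted_benchmark(n_ligands=1000, target_auc=0.5, seed=3)
        (res,) = evaluate_metrics(
            bench.index, bench.gene_table, bench.ligands, bench.tissue_map,
            ["total"], "gene", seed=11, extra_exclude=bench.exclude,
        )
        assert 0.45 <= res.mean_auc <= 0.55

    def test_planted_dominance_beats_chance(self):
        bench = make_planted_benchmark(n_ligands=1000, target_auc=0.75, seed=4)
        (res,) = evaluate_metrics(
            bench.index, bench.gene_table, bench.ligands, bench.tissue_map,
            ["total"], "gene", seed=12, extra_exclude=bench.exclude,
        )
        assert res.mean_auc > 0.5

    def test_planted_binormal_recovery(self):
        bench = make_planted_benchmark(n_ligands=2000, target_auc=0.8, seed=5)
        (res,) = evaluate_metrics(
            bench.index, bench.gene_table, bench.ligands, bench.tissue_map,
            ["total"], "gene", seed=13, extra_exclude=bench.exclude,
        )
        assert res.mean_auc == pytest.approx(0.80, abs=0.02)

    def test_unmapped_group_rejected(self):
        bench = make_planted_benchmark(n_ligands=20, target_auc=0.8, seed=6)
        with pytest.raises(ConfigurationError, match="synthetic_tissue"):
            evaluate_metrics(
                bench.index, bench.gene_table, bench.ligands, {"other": "cohort"},
                ["total"], "gene", seed=1,
            )

    def test_total_scaled_requires_gene_level(self):
        bench = make_planted_benchmark(n_ligands=20, target_auc=0.8, seed=6)
        with pytest.raises(ConfigurationError):
            evaluate_metrics(
                bench.index, bench.transcript_table, bench.ligands,
                bench.tissue_map, ["total_scaled"], "transcript", seed=1,
            )

    def test_mean_auc_is_mean_of_groups(self):
        res = BenchmarkResult(
            metric_name="total_gene", level="gene",
            per_group_auc={"a": 0.7, "b": 0.9},
            n_pos={"a": 5, "b": 5}, n_neg={"a": 5, "b": 5},
        )
        assert res.mean_auc == pytest.approx(0.8)


class TestPairedWilcoxon:
    def test_exact_small_sample_with_tied_differences(self):
        # all three differences are -1: 2^3 equally likely sign assignments,
        # the observed W+ = 0 is one of the two most extreme -> p = 2/8
        stat, p = paired_wilcoxon([1, 2, 3], [2, 3, 4])
        assert stat == 0.0
        assert p == pytest.approx(0.25)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 20))
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            _, p = paired_wilcoxon(x, y)
            _, p_scipy = sps.wilcoxon(x, y, method="exact",
                                      alternative="two-sided")
            assert p == pytest.approx(p_scipy, abs=1e-10)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = x + rng.normal(0.5, 1, size=60)
        _, p = paired_wilcoxon(x, y)
        _, p_scipy = sps.wilcoxon(x, y, method="approx", correction=True,
                                  alternative="two-sided")
        assert p == pytest.approx(p_scipy)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        alpha = 0.05
        reps = 400
        rejections = sum(
            paired_wilcoxon(rng.normal(size=15), rng.normal(size=15))[1] <= alpha
            for _ in range(reps)
        )
        # binomial 99.9% interval around alpha
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3.3 * se + 1 / reps


class TestKruskalWallis:
    def test_identical_groups_zero_statistic(self):
        h, p = kruskal_wallis([[5, 5], [5, 5]])
        assert h == 0.0
        assert p == 1.0

    def test_hand_ranked_two_groups(self):
        # ranks 1..4; rank sums 3 and 7 -> H = 12/20 * (9/2 + 49/2) - 15 = 2.4
        h, _ = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            groups = [rng.integers(0, 6, size=int(rng.integers(3, 12))).astype(float)
                      for _ in range(3)]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            h, p = kruskal_wallis(groups)
            h_scipy, p_scipy = sps.kruskal(*groups)
            assert h == pytest.approx(h_scipy)
            assert p == pytest.approx(p_scipy)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(6)
        alpha = 0.05
        reps = 400
        rejections = sum(
            kruskal_wallis([rng.normal(size=15) for _ in range(3)])[1] <= alpha
            for _ in range(reps)
        )
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) < 3.3 * se + 1 / reps


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 21, 40]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=10),
        st.lists(st.integers(0, 5), min_size=3, max_size=10),
    )
    def test_ties_match_average_rank_pearson(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        expected = sps.spearmanr(x, y).statistic
        assert spearman(x, y) == pytest.approx(expected, abs=1e-12)


class TestCohortConcordance:
    def _cohort(self, matrix):
        matrix = np.asarray(matrix, dtype=float)
        return CohortMatrix(
            [f"F{i}" for i in range(matrix.shape[0])],
            [f"S{j}" for j in range(matrix.shape[1])],
            matrix,
        )

    def test_patient_equal_to_median_vector(self):
        cohort = self._cohort([[0, 1, 9], [2, 5, 8], [3, 3, 3], [0, 7, 9]])
        medians = np.median(cohort.tpm, axis=1)
        patient = {f: float(v) for f, v in zip(cohort.feature_ids, medians)}
        res = cohort_concordance(patient, cohort)
        assert res.correlations["median"] == pytest.approx(1.0)
        assert res.n_shared == 4

    def test_identical_samples_make_methods_agree(self):
        col = np.array([[1.0], [4.0], [2.0], [9.0]])
        cohort = self._cohort(np.repeat(col, 5, axis=1))
        patient = {"F0": 2.0, "F1": 3.0, "F2": 1.0, "F3": 10.0}
        res = cohort_concordance(patient, cohort)
        vals = list(res.correlations.values())
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_too_few_shared_features(self):
        cohort = self._cohort([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            cohort_concordance({"F0": 1.0, "F1": 2.0}, cohort)

    def test_skewed_cohort_median_tracks_members_best(self):
        """With heavy right-skew, the median aggregate correlates with a held-out
        cohort member at least as well as the mean, on average."""
        rng = np.random.default_rng(8)
        wins = 0
        reps = 30
        for _ in range(reps):
            n_feat, n_samp = 150, 60
            mu = rng.normal(0, 2, size=n_feat)
            cohort = np.exp(mu[:, None] + rng.normal(0, 1.5, size=(n_feat, n_samp)))
            # a few features carry extreme outliers that drag the mean
            outliers = rng.integers(0, n_feat, size=15)
            cohort[outliers, rng.integers(0, n_samp, size=15)] *= 1e3
            patient_vec = np.exp(mu + rng.normal(0, 1.5, size=n_feat))
            patient = {f"F{i}": float(v) for i, v in enumerate(patient_vec)}
            cm = CohortMatrix([f"F{i}" for i in range(n_feat)],
                              [f"S{j}" for j in range(n_samp)], cohort)
            res = cohort_concordance(patient, cm, methods=("mean", "median"))
            if res.correlations["median"] >= res.correlations["mean"]:
                wins += 1
        assert wins > reps / 2


class TestRangeMatrix:
    def test_direct_binning(self):
        patient = {"a": 0.5, "b": 5.0, "c": 0.5}
        reference = {"a": 0.5, "b": 5.0, "c": 5.0}
        m = range_matrix(patient, reference, [0, 1, 10])
        assert m[0, 0] == pytest.approx(100 / 3)
        assert m[1, 1] == pytest.approx(100 / 3)
        assert m[0, 1] == pytest.approx(100 / 3)
        assert m[1, 0] == 0.0

    def test_all_in_one_cell(self):
        m = range_matrix({"a": 2.0, "b": 3.0}, {"a": 2.5, "b": 9.0}, [0, 1, 10])
        assert m[1, 1] == pytest.approx(100.0)

    def test_total_is_conserved(self):
        rng = np.random.default_rng(9)
        patient = {f"F{i}": float(v) for i, v in enumerate(rng.lognormal(1, 2, 200))}
        reference = {f"F{i}": float(v) for i, v in enumerate(rng.lognormal(1, 2, 200))}
        m = range_matrix(patient, reference, [0, 1, 10, 100, 1000])
        assert m.sum() == pytest.approx(100.0, abs=0.1)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            range_matrix({"a": 1.0}, {"a": 1.0}, [0, 10, 1])

    def test_ligand_tsv_round_trip(self, tmp_path):
        ligands = LigandSet("x", [("KLWAEDGYR", "skin"), ("VYTWHGPLM", "lung")])
        path = tmp_path / "ligands.tsv"
        ligands.to_tsv(path)
        loaded = LigandSet.from_tsv(path)
        assert loaded.peptides == ligands.peptides
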