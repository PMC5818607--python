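"""Evaluation metric, cross-validation protocols, and robustness battery."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from mklconn import (
    CoactivationStack,
    FunctionalConnectome,
    PredictedFC,
    StructuralConnectome,
    TrainingCohort,
    UndefinedCorrelationError,
    ValidationError,
    cross_validate,
    fc_correlation,
    fit_mkl,
    mkl_model_factory,
    permute_pi_rows_test,
    perturb_sc,
    predict_fc,
    seed_correlation_map,
    swap_pi_test,
    threshold_sc,
)
from mklconn.evaluate import _mean_score
from mklconn.types import Subject
from conftest import random_connected_sc


def random_fc(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(-0.8, 0.8, (n, n))
    V = 0.5 * (A + A.T)
    np.fill_diagonal(V, 1.0)
    return FunctionalConnectome.from_values(V)


class TestFCCorrelation:
    def test_identical_matrices_score_one(self):
        fc = random_fc(6, 0)
        assert fc_correlation(PredictedFC(fc.values), fc) == pytest.approx(1.0)

    def test_negated_offdiagonals_score_minus_one(self):
        fc = random_fc(6, 1)
        assert fc_correlation(PredictedFC(-fc.values), fc) == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((4, 4))
        fc = random_fc(4, 3)
        iu = np.triu_indices(4, k=1)
        Ps = 0.5 * (P + P.T)
        expected = pearsonr(Ps[iu], fc.values[iu]).statistic
        assert fc_correlation(PredictedFC(P), fc) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_variance_prediction_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            fc_correlation(PredictedFC(np.ones((5, 5))), random_fc(5, 4))


def mean_fc_factory(train):
    """Trivial baseline: predict the mean training FC for everyone."""
    mean = np.mean([s.fc.values for s in train], axis=0)
    return lambda subject: PredictedFC(mean)


def make_subjects(p, n=8, seed=0):
    subjects = []
    for s in range(p):
        sc = random_connected_sc(n, seed=1000 + s)
        subjects.append(Subject(subject_id=f"s{s:02d}", sc=sc, spec=None,
                                bank=None, fc=random_fc(n, seed + s)))
    return subjects


class TestCrossValidate:
    def test_leave_one_out_scores_every_subject(self):
        subjects = make_subjects(7)
        report = cross_validate(subjects, mean_fc_factory, protocol="loo")
        assert len(report.per_subject) == 7
        assert set(report.per_subject) == {s.subject_id for s in subjects}

    def test_five_folds_of_nine_on_45_subjects(self):
        subjects = make_subjects(45)
        report = cross_validate(subjects, mean_fc_factory, protocol="kfold", k=5)
        counts = np.bincount(list(report.folds.values()))
        assert list(counts) == [9] * 5
        assert len(report.per_subject) == 45

    def test_holdout_scores_only_the_test_half(self):
        subjects = make_subjects(10)
        report = cross_validate(subjects, mean_fc_factory,
                                protocol="holdout_half", seed=1)
        assert len(report.per_subject) == 5

    def test_same_seed_reproduces_folds(self):
        subjects = make_subjects(12)
        a = cross_validate(subjects, mean_fc_factory, protocol="kfold", seed=5, k=3)
        b = cross_validate(subjects, mean_fc_factory, protocol="kfold", seed=5, k=3)
        assert a.folds == b.folds
        assert a.per_subject == b.per_subject

    def test_summary_statistics_match_per_subject_scores(self):
        subjects = make_subjects(9)
        report = cross_validate(subjects, mean_fc_factory, protocol="loo")
        vals = np.array(list(report.per_subject.values()))
        assert report.mean_correlation == pytest.approx(vals.mean(), abs=1e-12)
        assert report.std_correlation == pytest.approx(vals.std(), abs=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            cross_validate(make_subjects(3), mean_fc_factory, protocol="kfold", k=5)


class TestThresholdSC:
    def test_triangle_keeps_only_strongest_edge_at_34_percent(self):
        W = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        sc = StructuralConnectome.from_weights(W)
        with pytest.warns(RuntimeWarning):
            out = threshold_sc(sc, 34.0)
        assert np.count_nonzero(np.triu(out.weights, 1)) == 1
        assert out.weights[1, 2] == 3.0

    def test_full_retention_is_identity(self):
        sc = random_connected_sc(10, seed=9)
        out = threshold_sc(sc, 100.0)
        assert np.array_equal(out.weights, sc.weights)

    def test_keep_count_uses_ceiling_of_fraction(self):
        # build a graph with exactly 100 undirected edges
        n = 16
        rng = np.random.default_rng(3)
        iu = np.triu_indices(n, k=1)
        idx = rng.choice(iu[0].size, size=100, replace=False)
        W = np.zeros((n, n))
        W[iu[0][idx], iu[1][idx]] = rng.uniform(0.5, 2.0, 100)
        W = W + W.T
        sc = StructuralConnectome.from_weights(W, allow_isolated=True)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = threshold_sc(sc, 15.0)
        assert np.count_nonzero(np.triu(out.weights, 1)) == 15

    def test_invalid_percent_rejected(self):
        sc = random_connected_sc(5, seed=0)
        with pytest.raises(ValidationError):
            threshold_sc(sc, 0.0)


class TestPerturbSC:
    def test_weight_multiset_preserved_exactly(self):
        sc = random_connected_sc(12, seed=5)
        out = perturb_sc(sc, seed=1)
        iu = np.triu_indices(12, k=1)
        assert np.array_equal(np.sort(out.weights[iu]), np.sort(sc.weights[iu]))

    def test_degree_sequence_generally_not_preserved(self):
        sc = random_connected_sc(12, seed=6)
        out = perturb_sc(sc, seed=2)
        assert not np.allclose(np.sort(out.degrees), np.sort(sc.degrees))

    def test_null_correlation_with_original_over_draws(self):
        sc = random_connected_sc(20, seed=7)
        iu = np.triu_indices(20, k=1)
        orig = sc.weights[iu]
        rs = []
        for d in range(250):
            pert = perturb_sc(sc, seed=d).weights[iu]
            rs.append(np.corrcoef(orig, pert)[0, 1])
        assert abs(np.mean(rs)) < 0.05


@pytest.fixture(scope="module")
def fitted_synthetic():
    """Train on 10 synthetic subjects, hold out 5, with multi-scale truth."""
    from mklconn import SyntheticCohortSpec, generate_cohort
    spec = SyntheticCohortSpec(n=16, p=15, m=4, fc_noise_sd=0.01,
                               pi_sparsity=0.1, seed=23)
    subjects, truth, _ = spec_subjects = generate_cohort(spec)
    train, test = subjects[:10], subjects[10:]
    stack = fit_mkl(TrainingCohort([(s.bank, s.fc) for s in train]), lam=1e-3)
    return stack, test


class TestPiPermutationTests:
    def test_no_swap_entry_equals_baseline_exactly(self, fitted_synthetic):
        stack, test = fitted_synthetic
        scores = swap_pi_test(stack, test)
        assert len(scores) == stack.m
        assert scores[-1] == _mean_score(stack, test)

    def test_swapping_distant_scales_degrades_performance(self, fitted_synthetic):
        stack, test = fitted_synthetic
        scores = swap_pi_test(stack, test)
        assert scores[0] < scores[-1] - 0.1

    def test_identity_row_permutation_reproduces_baseline(self, fitted_synthetic):
        stack, test = fitted_synthetic
        same = CoactivationStack.from_stacked(
            stack.stacked[np.arange(stack.stacked.shape[0])],
            stack.scale_set, lam=stack.lam)
        assert _mean_score(same, test) == _mean_score(stack, test)

    def test_row_permutation_null_below_intact_score(self, fitted_synthetic):
        stack, test = fitted_synthetic
        null = permute_pi_rows_test(stack, test, n_perm=100, seed=3)
        assert len(null) == 100
        assert np.percentile(null, 95) < _mean_score(stack, test)


class TestSeedCorrelationMap:
    def test_self_entry_is_one_for_empirical_fc(self):
        fc = random_fc(7, 8)
        assert seed_correlation_map(fc, 3)[3] == 1.0

    def test_map_equals_matrix_row(self):
        fc = random_fc(7, 9)
        assert np.array_equal(seed_correlation_map(fc, 2), fc.values[2])

    def test_group_map_is_mean_of_subject_maps(self):
        fcs = [random_fc(6, s) for s in range(5)]
        group = FunctionalConnectome.from_values(
            np.mean([f.values for f in fcs], axis=0) * 0
            + np.mean([f.values for f in fcs], axis=0))
        maps = np.array([seed_correlation_map(f, 1) for f in fcs])
        assert np.allclose(seed_correlation_map(group, 1),
                           maps.mean(axis=0), atol=1e-12)
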