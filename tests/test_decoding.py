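"""Decoding primitives: features, balancing, pseudotrials, z-scoring,
feature selection, classifiers, AUC, Haufe patterns, and leakage control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sldecode.data import EpochSet
from sldecode.decoding import (
    DecodingConfig,
    LinearModel,
    _auc_columns,
    auc_score,
    balance_classes,
    decode_timecourse,
    extract_features,
    haufe_patterns,
    make_pseudotrials,
    select_features_f,
    standardize,
    train_linear_classifier,
    valid_centers,
)
from sldecode.synth import DesignConfig, PlantedEffectSpec, simulate_subject

from conftest import make_trial_table


def brute_force_auc(scores, labels):
    """Exhaustive pair counting: the Mann-Whitney definition of AUC."""
    classes = sorted(set(labels))
    pos = [s for s, l in zip(scores, labels) if l == classes[1]]
    neg = [s for s, l in zip(scores, labels) if l == classes[0]]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestExtractFeatures:
    @pytest.fixture
    def epochs(self):
        table = make_trial_table(["left", "right"])
        rng = np.random.default_rng(0)
        return EpochSet(
            data=rng.standard_normal((2, 4, 10)),
            times=np.arange(10) / 200.0,
            sfreq=200.0,
            trial_table=table,
        )

    def test_window_one_is_single_sample(self, epochs):
        X = extract_features(epochs, 0.02, 1)
        np.testing.assert_array_equal(X, epochs.data[:, :, 4])

    def test_feature_ordering_and_length(self, epochs):
        X = extract_features(epochs, 0.02, 5)
        assert X.shape == (2, 20)
        np.testing.assert_array_equal(X[0, :5], epochs.data[0, 0, 2:7])

    def test_edge_centers_rejected(self, epochs):
        # 10 samples, window 5 -> valid centers are indices 2..7 only
        for idx in (0, 1, 8, 9):
            with pytest.raises(ValueError):
                extract_features(epochs, idx / 200.0, 5)
        for idx in (2, 7):
            extract_features(epochs, idx / 200.0, 5)
        assert list(valid_centers(10, 5)) == [2, 3, 4, 5, 6, 7]


class TestBalanceClasses:
    def test_majority_subsampled(self):
        labels = np.array(["left"] * 300 + ["right"] * 100)
        keep = balance_classes(labels, seed=0)
        kept = labels[keep]
        assert (kept == "left").sum() == 100
        assert (kept == "right").sum() == 100

    def test_equal_counts_untouched(self):
        labels = np.array(["left", "right"] * 10)
        assert len(balance_classes(labels, seed=1)) == 20

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes(np.array(["left"] * 5), seed=0)


class TestPseudotrials:
    def test_floor_counts(self):
        X = np.arange(40, dtype=float).reshape(40, 1)
        y = np.array(["a"] * 20 + ["b"] * 20)
        Xp, yp = make_pseudotrials(X, y, m=5, seed=0)
        assert (yp == "a").sum() == 4 and (yp == "b").sum() == 4

    def test_m1_identity(self):
        X = np.arange(6, dtype=float).reshape(6, 1)
        y = np.array(["a", "a", "a", "b", "b", "b"])
        Xp, yp = make_pseudotrials(X, y, m=1, seed=0)
        np.testing.assert_array_equal(np.sort(Xp.ravel()), X.ravel())

    def test_remainder_dropped(self):
        X = np.ones((13, 2))
        y = np.array(["a"] * 13)
        Xp, yp = make_pseudotrials(X, y, m=5, seed=0)
        assert len(yp) == 2

    @given(n_a=st.integers(5, 25), n_b=st.integers(5, 25), m=st.integers(1, 5),
           seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_accounting_no_trial_reused(self, n_a, n_b, m, seed):
        """Pseudotrial count is floor(n/m) per class and each trial is used
        at most once: with power-of-two trial values, group sums are
        bitmasks, so disjointness means no shared bits across groups."""
        X = (2.0 ** np.arange(n_a + n_b)).reshape(-1, 1)
        y = np.array(["a"] * n_a + ["b"] * n_b)
        Xp, yp = make_pseudotrials(X, y, m=m, seed=seed)
        assert (yp == "a").sum() == n_a // m
        assert (yp == "b").sum() == n_b // m
        masks = [int(round(v * m)) for v in Xp.ravel()]
        combined = 0
        for mask in masks:
            assert combined & mask == 0
            combined |= mask


class TestStandardize:
    def test_population_sd_convention(self):
        train = np.array([[1.0], [3.0]])
        tz, sz = standardize(train, train)
        np.testing.assert_allclose(tz.ravel(), [-1.0, 1.0])
        np.testing.assert_allclose(sz, tz)

    def test_constant_feature_zeroed(self):
        train = np.full((4, 2), 2.0)
        test = np.array([[5.0, -1.0]])
        tz, sz = standardize(train, test)
        assert (tz == 0).all() and (sz == 0).all()

    def test_train_moments(self):
        rng = np.random.default_rng(3)
        train = rng.normal(5, 3, size=(50, 4))
        tz, _ = standardize(train, train)
        np.testing.assert_allclose(tz.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(tz.std(axis=0), 1.0, atol=1e-12)


class TestFeatureSelection:
    def test_known_f_statistic_ordering(self):
        # feature 0: classes {0,2} vs {4,6} -> F = (16/1)/(4/2) = 8
        # feature 1: same values in both classes -> F = 0
        X = np.array([[0.0, 1.0], [2.0, 2.0], [4.0, 1.0], [6.0, 2.0]])
        y = np.array(["a", "a", "b", "b"])
        sel = select_features_f(X, y, 1)
        assert list(sel) == [0]

    def test_k_equal_to_features_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        y = np.array(["a"] * 5 + ["b"] * 5)
        assert list(select_features_f(X, y, 5)) == [0, 1, 2, 3, 4]

    def test_k_clamped_with_warning(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning):
            sel = select_features_f(X, y, 10)
        assert len(sel) == 3

    def test_planted_informative_features_recovered(self):
        rng = np.random.default_rng(42)
        hits = []
        for _ in range(5):
            y = np.array(["a", "b"] * 50)
            signs = np.where(y == "a", 1.0, -1.0)
            X = rng.normal(size=(100, 100))
            X[:, :10] += 2.0 * signs[:, None]
            sel = select_features_f(X, y, 10)
            hits.append(np.isin(sel, np.arange(10)).sum())
        assert np.mean(hits) >= 9


class TestLinearClassifier:
    def test_separable_points_perfect_training_auc(self):
        X = np.array([[-1.0, 0.0], [1.0, 0.0]])
        y = np.array(["a", "b"])
        model = train_linear_classifier(X, y, DecodingConfig())
        assert auc_score(model.decision_scores(X), y) == 1.0

    @pytest.mark.parametrize("clf", ["linear_svm", "logistic"])
    def test_label_flip_negates_scores(self, clf):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = np.array(["a", "b"] * 20)
        X[y == "b"] += 0.8
        cfg = DecodingConfig(classifier=clf)
        m1 = train_linear_classifier(X, y, cfg)
        y_flip = np.where(y == "a", "b", "a")
        m2 = train_linear_classifier(X, y_flip, cfg)
        np.testing.assert_allclose(
            m1.decision_scores(X), -m2.decision_scores(X), atol=0.05
        )

    def test_gaussian_mean_direction_recovered(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(size=50)
        mu /= np.linalg.norm(mu)
        y = np.array(["a", "b"] * 250)
        signs = np.where(y == "b", 1.0, -1.0)
        X = rng.normal(size=(500, 50)) + signs[:, None] * mu
        model = train_linear_classifier(X, y, DecodingConfig())
        corr = np.corrcoef(model.weights, mu)[0, 1]
        assert corr > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(
                np.ones((3, 2)), np.array(["a"] * 3), DecodingConfig()
            )


class TestAUC:
    def test_worked_example(self):
        assert auc_score([0.1, 0.4, 0.35, 0.8], np.array([0, 0, 1, 1])) == 0.75

    def test_all_ties_half(self):
        assert auc_score([1.0] * 6, np.array([0, 0, 0, 1, 1, 1])) == 0.5

    def test_perfect_separation(self):
        assert auc_score([0, 1, 2, 10, 11], np.array(["a"] * 3 + ["b"] * 2)) == 1.0

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_oracle_equivalence_small_inputs(self, data):
        """auc_score equals exhaustive pair counting on inputs <= 12 trials,
        including ties."""
        n_pos = data.draw(st.integers(1, 6))
        n_neg = data.draw(st.integers(1, 6))
        scores = data.draw(
            st.lists(
                st.integers(-3, 3).map(float),
                min_size=n_pos + n_neg, max_size=n_pos + n_neg,
            )
        )
        labels = np.array([0] * n_neg + [1] * n_pos)
        expected = brute_force_auc(scores, labels)
        assert auc_score(scores, labels) == pytest.approx(expected, abs=1e-12)
        col = _auc_columns(np.array(scores)[:, None], labels)
        assert col[0] == pytest.approx(expected, abs=1e-12)

    def test_label_flip_equivariance_and_monotone_invariance(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=12)
        labels = np.array([0, 1] * 6)
        a = auc_score(scores, labels)
        assert auc_score(scores, 1 - labels) == pytest.approx(1 - a)
        assert auc_score(np.exp(3 * scores), labels) == pytest.approx(a)


class TestHaufePatterns:
    def test_identity_covariance_returns_weights(self):
        # 4 points whose sample covariance is exactly I2
        Z = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], dtype=float)
        Z /= Z.std(axis=0, ddof=1)
        w = np.array([3.0, 4.0])
        a = haufe_patterns(Z, LinearModel(weights=w, bias=0.0))
        np.testing.assert_allclose(a, w / 5.0, atol=1e-9)

    def test_known_covariance_product(self):
        # X constructed so Cov(X) = [[2, 1], [1, 1]]; A proportional to [2, 1]
        Z = np.array([[1, 1], [1, -1], [-1, -1], [-1, 1]], dtype=float)
        Z /= Z.std(axis=0, ddof=1)
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 1.0]]))
        X = Z @ L.T
        a = haufe_patterns(X, LinearModel(weights=np.array([1.0, 0.0]), bias=0.0))
        expected = np.array([2.0, 1.0]) / np.sqrt(5.0)
        np.testing.assert_allclose(a, expected, atol=1e-9)

    def test_planted_pattern_recovered(self):
        rng = np.random.default_rng(17)
        pattern = rng.normal(size=20)
        pattern /= np.linalg.norm(pattern)
        y = np.array(["a", "b"] * 100)
        signs = np.where(y == "b", 1.0, -1.0)
        X = 0.3 * rng.normal(size=(200, 20)) + 2.0 * signs[:, None] * pattern
        model = train_linear_classifier(X, y, DecodingConfig())
        a = haufe_patterns(X, model)
        assert abs(np.corrcoef(a, pattern)[0, 1]) >= 0.9


class TestDecodeTimecourse:
    def test_one_auc_per_valid_center(self):
        ep = simulate_subject(
            seed=0, n_sensors=8,
            design=DesignConfig(n_sessions=1, blocks_per_session=1,
                                trials_per_block=80, p_distractor_present=1.0,
                                p_high_hemifield=0.5),
            effects=PlantedEffectSpec.silent(),
            epoch_span=(0.0, 0.5),
        )
        cfg = DecodingConfig(time_step=3, pseudotrial_size=2, seed=0)
        res = decode_timecourse(ep, "distractor_hemifield", cfg)
        assert res.auc.shape == res.times.shape
        assert len(res.times) == len(valid_centers(100, 5, 3))
        assert np.all((res.auc >= 0) & (res.auc <= 1))

    def test_too_few_trials_rejected(self):
        ep = simulate_subject(
            seed=0, n_sensors=8,
            design=DesignConfig(n_sessions=1, blocks_per_session=1,
                                trials_per_block=12, p_distractor_present=1.0,
                                p_high_hemifield=0.5),
            effects=PlantedEffectSpec.silent(),
            epoch_span=(0.0, 0.5),
        )
        with pytest.raises(ValueError, match="n_folds"):
            decode_timecourse(ep, "distractor_hemifield",
                              DecodingConfig(seed=0))

    def test_no_leakage_on_pure_noise(self):
        """The full pipeline (balancing, CV, pseudotrials, z-scoring,
        selection) stays at chance when no signal is planted."""
        aucs = []
        for seed in range(4):
            ep = simulate_subject(
                seed=seed, n_sensors=12,
                design=DesignConfig(n_sessions=1, blocks_per_session=1,
                                    trials_per_block=80),
                effects=PlantedEffectSpec.silent(),
                epoch_span=(0.0, 0.8),
            )
            cfg = DecodingConfig(time_step=8, pseudotrial_size=2,
                                 feature_select_k=30, seed=seed)
            aucs.append(decode_timecourse(ep, "distractor_hemifield", cfg).auc)
        mean = np.mean(aucs)
        assert abs(mean - 0.5) < 0.05

    def test_permuted_labels_at_chance(self):
        effects = PlantedEffectSpec.silent()
        effects.presearch.amplitude = 0.4
        ep = simulate_subject(
            seed=3, n_sensors=12,
            design=DesignConfig(n_sessions=1, blocks_per_session=1,
                                trials_per_block=80, p_distractor_present=1.0,
                                p_high_hemifield=0.5),
            effects=effects,
            epoch_span=(0.0, 0.8),
        )
        rng = np.random.default_rng(0)
        table = ep.trial_table.copy()
        perm = rng.permutation(len(table))
        for col in ("distractor_hemifield", "distractor_position",
                    "distractor_present"):
            table[col] = table[col].to_numpy()[perm]
        ep_perm = EpochSet(data=ep.data, times=ep.times, sfreq=ep.sfreq,
                           trial_table=table)
        cfg = DecodingConfig(time_step=8, pseudotrial_size=2, seed=1)
        res = decode_timecourse(ep_perm, "distractor_hemifield", cfg)
        assert abs(res.auc.mean() - 0.5) < 0.06
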