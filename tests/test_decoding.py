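"""AUC computation, fold construction, per-timepoint decoding, generalization."""

import numpy as np
import pandas as pd
import pytest

from peersway.decoding import (
    ContrastError,
    auc_score,
    build_labels,
    decode_timecourse,
    disagreement_vs_agreement,
    fit_logistic,
    median_split,
    stage_mean_auc,
    stratified_kfold,
    temporal_generalization,
)
from .conftest import make_epochs


def brute_force_auc(p, y):
    """Exhaustive pairwise concordance count (the AUC definition)."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAucScore:
    def test_worked_example(self):
        # 3 of 4 positive/negative pairs concordant
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.4, 0.6, 0.1])
        assert auc_score(p, y) == pytest.approx(0.75)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert auc_score(p, y) == 1.0

    def test_all_ties_chance(self):
        y = np.array([0, 1, 0, 1])
        assert auc_score(np.full(4, 0.5), y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_brute_force_on_random_instances(self, rng):
        """1000 random instances, some with heavy ties, vs exhaustive count."""
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            assert auc_score(p, y) == pytest.approx(brute_force_auc(p, y),
                                                    abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = (rng.random(100) < 0.4).astype(int)
        p = rng.random(100)
        assert auc_score(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestStratifiedKfold:
    def test_balanced_folds(self):
        y = np.array([0] * 50 + [1] * 50)
        folds = stratified_kfold(y, k=10, seed=0)
        for f in range(10):
            test = folds == f
            assert test.sum() == 10
            assert y[test].sum() == 5

    def test_partition_property(self):
        y = np.array([0] * 60 + [1] * 40)
        folds = stratified_kfold(y, k=10, seed=1)
        assert np.bincount(folds).sum() == 100
        for f in range(10):
            assert y[folds == f].sum() == 4  # 40% of 10

    def test_small_class_rejected(self):
        y = np.array([0] * 50 + [1] * 5)
        with pytest.raises(ValueError):
            stratified_kfold(y, k=10)


class TestFitLogistic:
    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import LogisticRegression
        X = rng.standard_normal((150, 20))
        beta = rng.normal(0, 0.5, 20)
        y = (rng.random(150) < 1 / (1 + np.exp(-X @ beta))).astype(int)
        coef, icpt = fit_logistic(X, y, C=1.0)
        ref = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000,
                                 tol=1e-10).fit(X, y)
        assert np.abs(coef - ref.coef_[0]).max() < 1e-5
        assert abs(icpt - ref.intercept_[0]) < 1e-5

    def test_zero_variance_feature_no_crash(self, rng):
        X = rng.standard_normal((60, 5))
        X[:, 2] = 3.0
        y = (rng.random(60) < 0.5).astype(int)
        coef, icpt = fit_logistic(X, y)
        assert np.all(np.isfinite(coef))


def _labels_frame():
    rows = []
    for i in range(6):
        rows.append({"condition": "agree", "phase": "test",
                     "test_rating": 4, "fictive_rating": 4, "post_rating": 4})
    for cond, fict in [("pos_mod", 6), ("neg_strong", 1)]:
        for i in range(6):
            rows.append({"condition": cond, "phase": "test",
                         "test_rating": 4, "fictive_rating": fict,
                         "post_rating": 4})
    return pd.DataFrame(rows)


class TestBuildLabels:
    def test_disagreement_vs_agreement(self):
        df = _labels_frame()
        y, idx = build_labels(df, disagreement_vs_agreement())
        assert y.sum() == 12 and len(y) == 18

    def test_towards_away_classification(self):
        rows = [
            # moved in the fictive direction -> towards
            {"condition": "neg_strong", "phase": "post_test",
             "test_rating": 4, "fictive_rating": 1, "post_rating": 1},
            # moved opposite -> away
            {"condition": "pos_strong", "phase": "post_test",
             "test_rating": 4, "fictive_rating": 7, "post_rating": 3},
            # unchanged -> excluded from both
            {"condition": "pos_strong", "phase": "post_test",
             "test_rating": 4, "fictive_rating": 7, "post_rating": 4},
        ]
        df = pd.DataFrame(rows)
        from peersway.decoding import _adjustment_direction
        direction = _adjustment_direction(df)
        assert list(direction) == ["towards", "away", "none"]

    def test_small_class_raises(self):
        df = _labels_frame().iloc[:7]  # only one disagreement trial
        with pytest.raises(ContrastError):
            build_labels(df, disagreement_vs_agreement(), min_class=6)


def _planted_epochs(n_trials=120, n_channels=8, sfreq=100.0, seed=0,
                    window=(300.0, 500.0), effect=2.0):
    """Epochs whose two classes differ only inside a known time window."""
    rng = np.random.default_rng(seed)
    ep = make_epochs(n_trials=n_trials, n_channels=n_channels, sfreq=sfreq,
                     seed=seed + 1)
    y = np.zeros(n_trials, dtype=int)
    y[: n_trials // 2] = 1
    rng.shuffle(y)
    mask = (ep.times >= window[0]) & (ep.times < window[1])
    pattern = rng.normal(0, 1, n_channels)
    pattern /= np.linalg.norm(pattern)
    ep.data[y == 1] += effect * pattern[:, None] * mask[None, :]
    return ep, y


class TestDecodeTimecourse:
    def test_effect_detected_inside_window_only(self):
        ep, y = _planted_epochs(seed=5)
        tc = decode_timecourse(ep, y, k=10, seed=0)
        inside = (ep.times >= 320) & (ep.times < 480)
        outside = ep.times < 200
        assert tc.auc[inside].mean() > 0.9
        assert abs(tc.auc[outside].mean() - 0.5) < 0.05

    def test_null_labels_near_chance(self):
        ep, y = _planted_epochs(seed=6, effect=0.0)
        tc = decode_timecourse(ep, y, k=10, seed=0)
        assert abs(tc.auc.mean() - 0.5) < 0.04

    def test_seed_determinism(self):
        ep, y = _planted_epochs(n_trials=60, seed=7)
        a = decode_timecourse(ep, y, k=5, seed=3).auc
        b = decode_timecourse(ep, y, k=5, seed=3).auc
        assert np.array_equal(a, b)

    def test_scale_invariance(self):
        ep, y = _planted_epochs(n_trials=60, seed=8)
        a = decode_timecourse(ep, y, k=5, seed=0).auc
        ep_scaled = ep.copy_with(data=ep.data * 37.0)
        b = decode_timecourse(ep_scaled, y, k=5, seed=0).auc
        assert np.abs(a - b).max() < 1e-6

    def test_auc_in_unit_interval(self):
        ep, y = _planted_epochs(n_trials=60, seed=9)
        tc = decode_timecourse(ep, y, k=5, seed=0)
        assert ((tc.auc >= 0) & (tc.auc <= 1)).all()


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse(self):
        ep, y = _planted_epochs(n_trials=60, n_channels=6, seed=10)
        tc = decode_timecourse(ep, y, k=5, seed=4)
        tg = temporal_generalization(ep, y, k=5, seed=4)
        assert np.abs(tg.diagonal - tc.auc).max() < 1e-12

    def test_sustained_component_generalizes_broadly(self):
        ep, y = _planted_epochs(n_trials=80, n_channels=6, seed=11,
                                window=(200.0, 800.0), effect=2.0)
        tg = temporal_generalization(ep, y, k=5, seed=0)
        inside = (ep.times >= 250) & (ep.times < 750)
        block = tg.auc[np.ix_(inside, inside)]
        assert block.mean() > 0.85  # broad off-diagonal square

    def test_sequential_components_stay_on_diagonal(self):
        rng = np.random.default_rng(12)
        ep = make_epochs(n_trials=100, n_channels=8, seed=13)
        y = np.zeros(100, dtype=int)
        y[:50] = 1
        rng.shuffle(y)
        p1 = np.zeros(8); p1[:4] = 1.0; p1 /= np.linalg.norm(p1)
        p2 = np.zeros(8); p2[4:] = 1.0; p2 /= np.linalg.norm(p2)
        m1 = (ep.times >= 200) & (ep.times < 450)
        m2 = (ep.times >= 550) & (ep.times < 800)
        ep.data[y == 1] += 2.5 * (p1[:, None] * m1 + p2[:, None] * m2)
        tg = temporal_generalization(ep, y, k=5, seed=0)
        t1 = (ep.times >= 250) & (ep.times < 400)
        t2 = (ep.times >= 600) & (ep.times < 750)
        on1 = tg.auc[np.ix_(t1, t1)].mean()
        cross = tg.auc[np.ix_(t1, t2)].mean()
        assert on1 > 0.85
        assert cross < 0.65  # orthogonal patterns do not transfer


class TestMedianSplit:
    def test_odd_count_tie_goes_low(self):
        scores = np.arange(1, 18)
        high = median_split(scores)
        assert high.sum() == 8
        assert not high[8]  # the median subject

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning):
            high = median_split(np.full(6, 2.0))
        assert not high.any()

    def test_even_count(self):
        high = median_split(np.array([1.0, 2.0, 3.0, 4.0]))
        assert list(high) == [False, False, True, True]


class TestStageMeanAuc:
    def test_window_average(self):
        ep, y = _planted_epochs(n_trials=60, seed=14)
        tc = decode_timecourse(ep, y, k=5, seed=0)
        mask = ((tc.times >= 200) & (tc.times < 400)) | (
            (tc.times >= 400) & (tc.times < 900))
        assert stage_mean_auc(tc) == pytest.approx(tc.auc[mask].mean())
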