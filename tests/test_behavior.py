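"""Social-influence scoring, outlier filters and the no-feedback control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peersway.behavior import (
    DataIntegrityError,
    mean_rating_change,
    nofeedback_bias_test,
    qc_filter,
    score_table,
    social_influence_score,
)
from .conftest import make_trial_frame


def _pairs(cond, pairs, fictive=None, participant="p1"):
    rows = []
    for i, (test, post) in enumerate(pairs):
        face = f"{cond}_f{i}"
        fict = fictive if fictive is not None else test
        rows.append((participant, "test", face, cond, test, fict, pd.NA))
        rows.append((participant, "post_test", face, cond, test, fict, post))
    return rows


class TestMeanRatingChange:
    def test_single_full_adjustment(self):
        # rating moved from 4 to 1 after a fictive rating 3 points below
        trials = make_trial_frame(_pairs("neg_strong", [(4, 1)], fictive=1))
        assert mean_rating_change(trials, "neg_strong") == -3

    def test_no_change_is_zero(self):
        trials = make_trial_frame(_pairs("agree", [(3, 3), (6, 6)]))
        assert mean_rating_change(trials, "agree") == 0

    def test_arithmetic_mean(self):
        trials = make_trial_frame(_pairs("pos_mod", [(3, 5), (4, 4)], fictive=6))
        assert mean_rating_change(trials, "pos_mod") == pytest.approx(1.0)

    def test_missing_condition_errors(self):
        trials = make_trial_frame(_pairs("agree", [(3, 3)]))
        with pytest.raises(DataIntegrityError):
            mean_rating_change(trials, "neg_mod")

    def test_unmatched_pairs_error(self):
        trials = make_trial_frame(_pairs("agree", [(3, 3)]))
        trials = trials[trials.phase == "test"]
        with pytest.raises(DataIntegrityError):
            mean_rating_change(trials, "agree")


class TestSocialInfluenceScore:
    def test_negative_valence_sign_flip(self):
        trials = make_trial_frame(_pairs("neg_strong", [(5, 3), (6, 4)], fictive=2))
        assert social_influence_score(trials, "neg_strong") == pytest.approx(2.0)

    def test_positive_valence_unflipped(self):
        trials = make_trial_frame(_pairs("pos_mod", [(3, 4), (3, 5)], fictive=5))
        assert social_influence_score(trials, "pos_mod") == pytest.approx(1.5)

    def test_movement_away_is_negative(self):
        trials = make_trial_frame(_pairs("neg_mod", [(5, 6)], fictive=3))
        assert social_influence_score(trials, "neg_mod") == pytest.approx(-1.0)

    def test_rejects_non_disagreement(self):
        trials = make_trial_frame(_pairs("agree", [(3, 3)]))
        with pytest.raises(ValueError):
            social_influence_score(trials, "agree")

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_mirror_symmetry(self, seed):
        """Reflecting the scale r -> 9 - r swaps valences but preserves scores."""
        rng = np.random.default_rng(seed)
        flip = {"pos_mod": "neg_mod", "neg_mod": "pos_mod",
                "pos_strong": "neg_strong", "neg_strong": "pos_strong"}
        rows = []
        for cond, delta in [("pos_mod", 2), ("pos_strong", 3),
                            ("neg_mod", -2), ("neg_strong", -3)]:
            for i in range(4):
                test = int(rng.integers(max(1, 1 - delta), min(8, 8 - delta) + 1))
                post = int(rng.integers(1, 9))
                face = f"{cond}_f{i}"
                rows.append(("p1", "test", face, cond, test, test + delta, pd.NA))
                rows.append(("p1", "post_test", face, cond, test, test + delta, post))
        trials = make_trial_frame(rows)
        mirrored = trials.copy()
        for col in ("test_rating", "post_rating", "fictive_rating"):
            mirrored[col] = 9 - mirrored[col]
        mirrored["condition"] = mirrored["condition"].map(flip)
        for cond in flip:
            assert social_influence_score(trials, cond) == pytest.approx(
                social_influence_score(mirrored, flip[cond]))


def _score_frame(si_overall, nofb=None):
    n = len(si_overall)
    nofb = nofb if nofb is not None else np.zeros(n)
    df = pd.DataFrame({
        "participant": [f"p{i}" for i in range(n)],
        "si_overall": si_overall,
        "change_no_feedback": nofb,
    })
    for c in ("si_pos_mod", "si_pos_strong", "si_neg_mod", "si_neg_strong"):
        df[c] = si_overall
    return df


class TestQCFilter:
    def test_identical_scores_nobody_excluded(self):
        scores = _score_frame(np.full(20, 0.4))
        retained, report = qc_filter(scores)
        assert len(retained) == 20
        assert report.excluded == {}

    def test_single_extreme_outlier_removed(self):
        vals = np.concatenate([np.random.default_rng(0).normal(0.3, 0.05, 50), [5.0]])
        retained, report = qc_filter(_score_frame(vals))
        assert report.n_after_si_filter == 50
        assert "p50" in report.excluded

    def test_planted_outliers_exactly_removed(self):
        """Eleven planted extreme scorers are exactly the stage-1 exclusions."""
        rng = np.random.default_rng(1)
        clean = rng.normal(0.3, 0.08, 100)
        planted = np.full(11, 4.0)
        vals = np.concatenate([clean, planted])
        scores = _score_frame(vals)
        # independent oracle: direct mean ± 2 SD on the contaminated sample
        mean, sd = vals.mean(), vals.std(ddof=1)
        expect = {f"p{i}" for i in np.flatnonzero(np.abs(vals - mean) > 2 * sd)}
        assert expect == {f"p{100 + i}" for i in range(11)}
        retained, report = qc_filter(scores)
        stage1 = {k for k, v in report.excluded.items()
                  if v == "social_influence_outlier"}
        assert stage1 == expect

    def test_sequential_stage2_on_survivors(self):
        rng = np.random.default_rng(2)
        si = rng.normal(0.3, 0.05, 40)
        nofb = np.concatenate([rng.normal(0, 0.05, 39), [3.0]])
        retained, report = qc_filter(_score_frame(si, nofb))
        assert report.excluded.get("p39") == "no_feedback_outlier"
        assert report.n_after_nofeedback_filter < report.n_after_si_filter

    def test_stage1_idempotent_on_survivors(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0.3, 0.1, 60), [3.0, -3.0]])
        scores = _score_frame(vals)
        retained, report = qc_filter(scores)
        mean, sd = vals.mean(), vals.std(ddof=1)
        survivors = retained["si_overall"].to_numpy()
        assert (np.abs(survivors - mean) <= 2 * sd).all()

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            qc_filter(_score_frame(np.array([0.1, 0.2])))


class TestNofeedbackBiasTest:
    def test_all_zero(self):
        res = nofeedback_bias_test(np.zeros(10))
        assert res["mean"] == 0 and res["t"] == 0 and res["p"] == 1

    def test_zero_variance_sentinel(self):
        res = nofeedback_bias_test(np.ones(4))
        assert np.isinf(res["t"]) and res["p"] == 0

    def test_closed_form_t(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.1, 0.3, 9)
        res = nofeedback_bias_test(x)
        expect_t = x.mean() / (x.std(ddof=1) / 3.0)
        assert res["t"] == pytest.approx(expect_t, abs=1e-12)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            nofeedback_bias_test(np.array([0.3]))


class TestScoreTable:
    def test_agreement_unchanged_gives_zero(self):
        rows = []
        for cond, delta in [("pos_mod", 2), ("pos_strong", 3),
                            ("neg_mod", -2), ("neg_strong", -3)]:
            rows += _pairs(cond, [(4, 4), (5, 5)], fictive=4 + delta)
        rows += _pairs("agree", [(4, 4), (6, 6)])
        rows += _pairs("no_feedback", [(4, 4)], fictive=None)
        trials = make_trial_frame(rows)
        trials.loc[trials.condition == "no_feedback", "fictive_rating"] = pd.NA
        table = score_table(trials)
        assert table.loc[0, "change_agree"] == 0
        assert table.loc[0, "si_overall"] == 0
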