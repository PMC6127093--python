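"""Behavioral scoring: mean rating change, social-influence scores, outlier QC.

The social-influence score for a disagreement condition is the mean
post-minus-test rating change, sign-flipped for negative-valence conditions
so that a positive score always means the participant moved *towards* the
peer rating.  Agreement and no-feedback trials keep the plain (unflipped)
mean change; the no-feedback change doubles as a positive control that the
rating criterion is stable in the absence of peer input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .design import DISAGREEMENT_CONDITIONS, NEGATIVE_CONDITIONS


class DataIntegrityError(ValueError):
    """Trial table violates pairing or condition assumptions."""


def _paired_changes(trials: pd.DataFrame, condition: str) -> np.ndarray:
    """Post-minus-test rating differences for one participant's condition."""
    sub = trials[trials["condition"] == condition]
    if sub.empty:
        raise DataIntegrityError(f"no trials for condition {condition!r}")
    test = sub[sub["phase"] == "test"].set_index("face_id")["test_rating"]
    post = sub[sub["phase"] == "post_test"].set_index("face_id")["post_rating"]
    if test.index.duplicated().any() or post.index.duplicated().any():
        raise DataIntegrityError("face repeated within a phase")
    if set(test.index) != set(post.index):
        raise DataIntegrityError("unmatched test/post-test face pairs")
    post = post.reindex(test.index)
    if post.isna().any() or test.isna().any():
        raise DataIntegrityError("missing ratings in paired trials")
    return (post.astype(float) - test.astype(float)).to_numpy()


def mean_rating_change(trials: pd.DataFrame, condition: str) -> float:
    """Mean post-minus-test rating difference over one condition's face pairs."""
    return float(np.mean(_paired_changes(trials, condition)))


def social_influence_score(trials: pd.DataFrame, condition: str) -> float:
    """Signed mean rating change, flipped for negative-valence disagreements.

    Positive values uniformly mean adjustment towards the peer rating.
    Only defined for the four disagreement conditions.
    """
    if condition not in DISAGREEMENT_CONDITIONS:
        raise ValueError(
            f"{condition!r} is not a disagreement condition; use mean_rating_change"
        )
    sign = -1.0 if condition in NEGATIVE_CONDITIONS else 1.0
    return sign * mean_rating_change(trials, condition)


def score_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant score table over all conditions present.

    Returns one row per participant with columns ``si_<cond>`` for the four
    disagreement conditions (sign-corrected), ``change_agree`` and
    ``change_no_feedback`` (plain means), and ``si_overall`` (unweighted mean
    of the four condition scores).
    """
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        row: dict[str, object] = {"participant": pid}
        for cond in DISAGREEMENT_CONDITIONS:
            row[f"si_{cond}"] = social_influence_score(sub, cond)
        for cond in ("agree", "no_feedback"):
            if (sub["condition"] == cond).any():
                row[f"change_{cond}"] = mean_rating_change(sub, cond)
        row["si_overall"] = float(
            np.mean([row[f"si_{c}"] for c in DISAGREEMENT_CONDITIONS])
        )
        rows.append(row)
    return pd.DataFrame(rows)


def scores_long(scores: pd.DataFrame) -> pd.DataFrame:
    """Reshape a wide score table into one row per disagreement condition.

    Valence and strength are deviation-coded (−0.5/+0.5) for mixed models:
    positive valence and strong disagreement get +0.5.
    """
    rows = []
    for _, r in scores.iterrows():
        for cond in DISAGREEMENT_CONDITIONS:
            rows.append({
                "participant": r["participant"],
                "condition": cond,
                "valence": 0.5 if cond.startswith("pos") else -0.5,
                "strength": 0.5 if cond.endswith("strong") else -0.5,
                "score": r[f"si_{cond}"],
            })
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    """Outcome of the two-stage outlier filter."""

    n_input: int
    n_after_si_filter: int
    n_after_nofeedback_filter: int
    excluded: dict[str, str] = field(default_factory=dict)
    nofeedback_mean: float | None = None
    nofeedback_sd: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _two_sd_outliers(values: pd.Series) -> pd.Index:
    """Ids outside sample mean ± 2 SD; degenerate SD = 0 excludes nobody."""
    sd = float(values.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        return pd.Index([])
    mean = float(values.mean())
    mask = (values - mean).abs() > 2.0 * sd
    return values.index[mask]


def qc_filter(scores: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Sequential ±2 SD outlier filter on a wide score table.

    Stage 1 excludes participants whose overall disagreement social-influence
    score (``si_overall``) lies outside the sample mean ± 2 SD.  Stage 2
    recomputes mean ± 2 SD of the survivors' no-feedback rating change and
    excludes a second wave.  Each stage runs once (non-iterative).
    """
    if len(scores) < 3:
        raise ValueError("qc_filter needs at least 3 participants")
    scores = scores.set_index("participant", drop=False)
    excluded: dict[str, str] = {}

    stage1_out = _two_sd_outliers(scores["si_overall"])
    for pid in stage1_out:
        excluded[str(pid)] = "social_influence_outlier"
    survivors = scores.drop(index=stage1_out)

    nofb = survivors["change_no_feedback"]
    stage2_out = _two_sd_outliers(nofb)
    for pid in stage2_out:
        excluded[str(pid)] = "no_feedback_outlier"
    final = survivors.drop(index=stage2_out)

    report = QCReport(
        n_input=len(scores),
        n_after_si_filter=len(survivors),
        n_after_nofeedback_filter=len(final),
        excluded=excluded,
        nofeedback_mean=float(nofb.mean()),
        nofeedback_sd=float(nofb.std(ddof=1)),
    )
    return final.reset_index(drop=True), report


def nofeedback_bias_test(changes: np.ndarray | pd.Series) -> dict[str, float]:
    """One-sample t-test of no-feedback rating changes against zero.

    Returns mean, SD, t and the two-sided p from the t distribution with
    n − 1 df.  A zero-variance sample with nonzero mean reports ``t = ±inf``
    and ``p = 0``.
    """
    x = np.asarray(changes, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return {"mean": 0.0, "sd": 0.0, "t": 0.0, "p": 1.0, "n": n}
        return {"mean": mean, "sd": 0.0, "t": float(np.sign(mean)) * np.inf,
                "p": 0.0, "n": n}
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"mean": mean, "sd": sd, "t": float(t), "p": float(p), "n": n}
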