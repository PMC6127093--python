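"""Time-resolved multivariate decoding of EEG epochs.

At every sample of the epoch an L2-regularized logistic classifier is
trained on the 64-channel voltage vector under stratified 10-fold
cross-validation; out-of-fold class probabilities are summarized as ROC-AUC
(the decoder's *sensitivity*; 0.5 is chance).  The same folds, reused across
all timepoints, also yield temporal-generalization matrices: the classifier
trained at time t is applied to features from every other time t′, so the
matrix diagonal reproduces the canonical decoding time-course exactly.

Features are z-standardized per timepoint with training-fold statistics
only, which makes the AUC time-courses invariant to positive rescaling of
the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochSet


class ContrastError(ValueError):
    """Contrast cannot be formed on the given trial table."""


def auc_score(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """ROC area via the Mann–Whitney rank statistic with midrank ties.

    ``AUC = U / (n1 * n0)`` where U counts pairs in which a positive-class
    probability outranks a negative-class one (ties count one half).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in shape")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _auc_matrix(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized AUC over the last axis of a (..., n_trials) probability array."""
    n1 = int((y == 1).sum())
    n0 = y.size - n1
    ranks = rankdata(prob, axis=-1)  # midranks for ties
    pos = ranks[..., y == 1].sum(axis=-1)
    u = pos - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Test-fold index (0..k-1) per trial, class-balanced within ±1 trial."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} trials, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# contrast construction

@dataclass(frozen=True)
class ContrastSpec:
    """Binary classification problem over a trial-label table.

    ``class_a`` / ``class_b`` are callables mapping the table to boolean
    masks; ``lock`` records whether epochs are feedback- or face-locked.
    """

    name: str
    class_a: object
    class_b: object
    lock: str = "feedback"


def _adjustment_direction(labels: pd.DataFrame) -> pd.Series:
    """'towards' / 'away' / 'none' per trial, from rating geometry.

    A post-test change counts as towards public information when its sign
    matches the sign of (fictive − test); unchanged ratings are 'none'.
    """
    test = labels["test_rating"].astype(float)
    post = labels["post_rating"].astype(float)
    fictive = labels["fictive_rating"].astype(float)
    change = np.sign(post - test)
    pull = np.sign(fictive - test)
    out = np.where(change == 0, "none",
                   np.where(change == pull, "towards", "away"))
    out = np.where(fictive.isna() | post.isna(), "none", out)
    return pd.Series(out, index=labels.index)


def disagreement_vs_agreement() -> ContrastSpec:
    """All four disagreement types (pooled) against agreement trials."""
    return ContrastSpec(
        name="disagreement_vs_agreement",
        class_a=lambda df: df["condition"].isin(
            ["pos_mod", "pos_strong", "neg_mod", "neg_strong"]),
        class_b=lambda df: df["condition"] == "agree",
        lock="feedback",
    )


def test_vs_posttest(condition: str, adjustment: str | None = None) -> ContrastSpec:
    """Faces rated before vs after public information, within one feedback
    condition, optionally restricted to trials adjusted towards/away."""
    def _phase(df, phase):
        mask = (df["condition"] == condition) & (df["phase"] == phase)
        if adjustment is not None:
            mask &= _adjustment_direction(df) == adjustment
        return mask
    suffix = f"_{adjustment}" if adjustment else ""
    return ContrastSpec(
        name=f"test_vs_posttest_{condition}{suffix}",
        class_a=lambda df: _phase(df, "post_test"),
        class_b=lambda df: _phase(df, "test"),
        lock="face",
    )


def build_labels(labels: pd.DataFrame, contrast: ContrastSpec,
                 min_class: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Binary label vector (class A = 1) and the selected trial indices.

    Raises :class:`ContrastError` if the predicates overlap or either class
    is smaller than ``min_class``.
    """
    mask_a = np.asarray(contrast.class_a(labels), dtype=bool)
    mask_b = np.asarray(contrast.class_b(labels), dtype=bool)
    if (mask_a & mask_b).any():
        raise ContrastError(f"contrast {contrast.name}: predicates overlap")
    if mask_a.sum() < min_class or mask_b.sum() < min_class:
        raise ContrastError(
            f"contrast {contrast.name}: class sizes {int(mask_a.sum())}/"
            f"{int(mask_b.sum())} below minimum {min_class}")
    idx = np.flatnonzero(mask_a | mask_b)
    y = mask_a[idx].astype(int)
    return y, idx


# ---------------------------------------------------------------------------
# per-timepoint decoding

@dataclass
class DecodingTimecourse:
    """Per-timepoint decoding sensitivity for one subject."""

    auc: np.ndarray          # (n_timepoints,)
    times: np.ndarray        # ms
    participant: str = "s01"
    contrast: str = ""
    probabilities: np.ndarray | None = None  # (n_timepoints, n_trials) optional


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time × test-time AUC matrix for one subject."""

    auc: np.ndarray          # (n_train_times, n_test_times)
    times: np.ndarray
    participant: str = "s01"
    contrast: str = ""

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.auc)


def fit_logistic(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                 tol: float = 1e-6, max_iter: int = 50):
    """L2-regularized logistic regression by damped Newton iterations.

    Minimizes the negative log-likelihood plus ``||w||² / (2C)`` (intercept
    unpenalized).  Returns ``(coef, intercept)``; agrees with
    scikit-learn's ``LogisticRegression(C=C)`` to solver tolerance.
    """
    n, d = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    w = np.zeros(d + 1)
    penalty = np.full(d + 1, 1.0 / C)
    penalty[-1] = 0.0
    yf = y.astype(float)
    for _ in range(max_iter):
        z = Xa @ w
        p = 1.0 / (1.0 + np.exp(-z))
        grad = Xa.T @ (p - yf) + penalty * w
        if np.max(np.abs(grad)) < tol:
            break
        wgt = np.maximum(p * (1.0 - p), 1e-10)
        H = (Xa * wgt[:, None]).T @ Xa
        H[np.diag_indices_from(H)] += penalty
        step = np.linalg.solve(H, grad)
        # halve the step until the penalized objective decreases
        obj = -np.sum(yf * z - np.logaddexp(0.0, z)) + 0.5 * penalty @ w ** 2
        alpha = 1.0
        for _ in range(20):
            w_new = w - alpha * step
            z_new = Xa @ w_new
            obj_new = (-np.sum(yf * z_new - np.logaddexp(0.0, z_new))
                       + 0.5 * penalty @ w_new ** 2)
            if obj_new <= obj:
                break
            alpha *= 0.5
        w = w - alpha * step
    return w[:d], float(w[d])


def _fold_models(X: np.ndarray, y: np.ndarray, folds: np.ndarray, C: float = 1.0):
    """Fit one standardized logistic model per fold at a single timepoint.

    ``X`` is (n_trials, n_channels).  Returns per-fold (test_idx, mu, sd,
    coef, intercept).  Standardization statistics come from training folds
    only; zero-variance channels get unit scale.
    """
    out = []
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        coef, icpt = fit_logistic(Xtr, y[train], C=C)
        out.append((test, mu, sd, coef, icpt))
    return out


def decode_timecourse(epochs: EpochSet, y: np.ndarray, trial_idx=None,
                      k: int = 10, seed: int = 0, C: float = 1.0,
                      keep_probabilities: bool = False,
                      contrast_name: str = "") -> DecodingTimecourse:
    """Cross-validated AUC at every timepoint of the epoch.

    ``y`` is the binary label vector over selected trials (``trial_idx``
    indexes into the epoch tensor; default all trials).  One stratified fold
    assignment is drawn per call and reused at every timepoint.
    """
    data = epochs.data if trial_idx is None else epochs.data[np.asarray(trial_idx)]
    y = np.asarray(y)
    if data.shape[0] != y.size:
        raise ValueError("labels do not align with selected trials")
    folds = stratified_kfold(y, k=k, seed=seed)
    n_t = data.shape[2]
    prob = np.empty((n_t, y.size))
    for t in range(n_t):
        for test, mu, sd, coef, icpt in _fold_models(data[:, :, t], y, folds, C):
            z = (data[test, :, t] - mu) / sd
            prob[t, test] = 1.0 / (1.0 + np.exp(-(z @ coef + icpt)))
    auc = _auc_matrix(prob, y)
    return DecodingTimecourse(
        auc=auc, times=epochs.times.copy(), participant=epochs.participant,
        contrast=contrast_name,
        probabilities=prob if keep_probabilities else None)


def temporal_generalization(epochs: EpochSet, y: np.ndarray, trial_idx=None,
                            k: int = 10, seed: int = 0, C: float = 1.0,
                            contrast_name: str = "") -> TemporalGeneralizationMatrix:
    """Train at every timepoint, test at every other, same folds throughout.

    The trained pipeline (training-fold scaler + logistic model from train
    time t) is applied unchanged to features from each test time t′, so the
    diagonal equals :func:`decode_timecourse` run with the same seed.
    """
    data = epochs.data if trial_idx is None else epochs.data[np.asarray(trial_idx)]
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    n_t = data.shape[2]
    prob = np.empty((n_t, n_t, y.size))  # train × test × trials
    for t in range(n_t):
        for test, mu, sd, coef, icpt in _fold_models(data[:, :, t], y, folds, C):
            # (n_test_trials, ch, n_t) standardized with train-time statistics
            z = (data[test] - mu[None, :, None]) / sd[None, :, None]
            logits = np.einsum("ict,c->ti", z, coef) + icpt
            prob[t, :, test] = (1.0 / (1.0 + np.exp(-logits))).T
    auc = _auc_matrix(prob, y)
    return TemporalGeneralizationMatrix(
        auc=auc, times=epochs.times.copy(), participant=epochs.participant,
        contrast=contrast_name)


def median_split(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Boolean high-scorer mask: strictly above the median; ties go low."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 subjects")
    high = x > np.median(x)
    if not high.any():
        warnings.warn("all scores at or below the median; high group is empty")
    return high


def stage_mean_auc(tc: DecodingTimecourse,
                   windows=((200.0, 400.0), (400.0, 900.0))) -> float:
    """Mean AUC over the union of processing-stage windows (half-open, ms)."""
    mask = np.zeros(tc.times.size, dtype=bool)
    for start, stop in windows:
        mask |= (tc.times >= start) & (tc.times < stop)
    if not mask.any():
        raise ValueError("stage windows fall outside the epoch")
    return float(tc.auc[mask].mean())
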