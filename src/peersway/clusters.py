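"""Group-level cluster-mass Monte-Carlo permutation inference on time-courses.

Two procedures share the same clustering core:

* **Decoding clusters** — per-timepoint one-tailed t-tests of subject AUC
  against chance (0.5) form clusters of ≥ 2 adjacent sub-threshold samples;
  each cluster's mass is the summed group-mean AUC; the null is built by
  flipping the sign of (AUC − 0.5) independently per subject and taking the
  maximum cluster mass per permutation.
* **Correlation clusters** — Pearson r between subjects' per-timepoint AUC
  and a behavioral/questionnaire score; clusters are runs of ≥ 2 samples
  with r ≥ 0.40 (positive tail only), mass = Σ r; the null permutes the
  score vector across subjects.

``p_star`` is the proportion of permutations whose maximum cluster mass
meets or exceeds the observed mass, floored at 1/n_perm when no permutation
does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ClusterResult:
    """One contiguous supra-threshold interval with its mass statistic."""

    start_idx: int
    end_idx: int            # inclusive
    start_ms: float
    end_ms: float
    mass: float
    p_star: float | None = None
    significant: bool | None = None

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


def timepoint_tests(auc_matrix: np.ndarray, chance: float = 0.5):
    """One-sample t against chance at every timepoint, upper tail.

    ``auc_matrix`` is subjects × timepoints.  Zero-variance timepoints get
    the sentinel p = 0 if the mean exceeds chance, else p = 1.
    Returns ``(t, p)`` arrays of length n_timepoints.
    """
    x = np.asarray(auc_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a subjects × timepoints matrix with ≥ 3 subjects")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - chance) / (sd / np.sqrt(n))
    p = stats.t.sf(t, df=n - 1)
    zero = sd == 0
    if zero.any():
        t[zero] = np.where(mean[zero] > chance, np.inf,
                           np.where(mean[zero] < chance, -np.inf, 0.0))
        p[zero] = np.where(mean[zero] > chance, 0.0,
                           np.where(mean[zero] < chance, 1.0, 0.5))
    return t, p


def _runs(mask: np.ndarray, min_len: int = 2):
    """(start, end-inclusive) index pairs of True runs of length ≥ min_len."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_len]


def find_clusters(p_values: np.ndarray, stat_series: np.ndarray,
                  times: np.ndarray | None = None,
                  forming_alpha: float = 0.05, min_len: int = 2,
                  center: float = 0.0) -> list[ClusterResult]:
    """Maximal runs of ≥ ``min_len`` adjacent samples with p < forming_alpha.

    The mass of a cluster is the sum of ``stat_series − center`` over the
    run (the group-mean AUC or correlation series; ``center`` defaults to 0,
    i.e. the literal sum).
    """
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(stat_series, dtype=float)
    t_axis = np.asarray(times, dtype=float) if times is not None else np.arange(p.size, dtype=float)
    out = []
    for start, end in _runs(p < forming_alpha, min_len):
        mass = float((s[start:end + 1] - center).sum())
        out.append(ClusterResult(start_idx=start, end_idx=end,
                                 start_ms=float(t_axis[start]),
                                 end_ms=float(t_axis[end]), mass=mass))
    return out


def _max_mass(p: np.ndarray, s: np.ndarray, forming_alpha: float,
              min_len: int, center: float) -> float:
    best = 0.0
    for start, end in _runs(p < forming_alpha, min_len):
        best = max(best, float((s[start:end + 1] - center).sum()))
    return best


def _attach_pstar(clusters: list[ClusterResult], null_max: np.ndarray,
                  cluster_alpha: float) -> list[ClusterResult]:
    n_perm = null_max.size
    for c in clusters:
        exceed = int((null_max >= c.mass).sum())
        c.p_star = max(exceed, 1) / n_perm  # floor at 1/n_perm
        c.significant = c.p_star < cluster_alpha
    return clusters


def permutation_null_decoding(auc_matrix: np.ndarray,
                              times: np.ndarray | None = None,
                              chance: float = 0.5,
                              forming_alpha: float = 0.05,
                              cluster_alpha: float = 0.01,
                              n_perm: int = 1000, seed: int = 0,
                              min_len: int = 2,
                              centered: bool = False):
    """Cluster-corrected one-sample decoding test via subject sign flips.

    Each permutation reflects every subject's AUC time-course about chance
    with probability one half, re-runs the t-tests and clustering, and
    records the maximum cluster mass.  Returns ``(clusters, null_max)``.

    ``centered=True`` sums (AUC − chance) instead of the literal AUC when
    massing clusters, for both observed and null statistics.
    """
    x = np.asarray(auc_matrix, dtype=float)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p_star resolution")
    center = chance if centered else 0.0
    t_obs, p_obs = timepoint_tests(x, chance)
    clusters = find_clusters(p_obs, x.mean(axis=0), times=times,
                             forming_alpha=forming_alpha, min_len=min_len,
                             center=center)
    rng = np.random.default_rng(seed)
    n_sub, n_t = x.shape
    dev = x - chance
    null_max = np.empty(n_perm)
    # sign flips only change the sign of each subject's deviation, so the
    # permuted t statistics and means are computable in one batch
    crit_p = forming_alpha
    df = n_sub - 1
    chunk = max(1, int(5e6 // (n_sub * n_t)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_sub))
        flipped = signs[:, :, None] * dev[None, :, :]     # m × sub × t
        mean = flipped.mean(axis=1)
        sd = flipped.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n_sub))
        p = stats.t.sf(t, df=df)
        zero = sd == 0
        if zero.any():
            p[zero] = np.where(mean[zero] > 0, 0.0,
                               np.where(mean[zero] < 0, 1.0, 0.5))
        series = chance + mean                            # permuted group mean
        for i in range(m):
            null_max[done + i] = _max_mass(p[i], series[i], crit_p,
                                           min_len, center)
        done += m
    return _attach_pstar(clusters, null_max, cluster_alpha), null_max


def correlation_timecourse(auc_matrix: np.ndarray,
                           scores: np.ndarray) -> np.ndarray:
    """Pearson r between subjects' AUC and a score, at every timepoint."""
    x = np.asarray(auc_matrix, dtype=float)
    s = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 4:
        raise ValueError("need a subjects × timepoints matrix with ≥ 4 subjects")
    if s.size != x.shape[0]:
        raise ValueError("score vector does not match subject count")
    if s.std() == 0:
        raise ValueError("correlation undefined for constant scores")
    xc = x - x.mean(axis=0)
    sc = s - s.mean()
    num = sc @ xc
    denom = np.sqrt((sc ** 2).sum() * (xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    return np.where(denom == 0, 0.0, r)


def permutation_null_correlation(auc_matrix: np.ndarray, scores: np.ndarray,
                                 times: np.ndarray | None = None,
                                 r_threshold: float = 0.40,
                                 cluster_alpha: float = 0.05,
                                 n_perm: int = 10000, seed: int = 0,
                                 min_len: int = 2):
    """Cluster-corrected brain–behavior correlation via score permutation.

    Observed clusters are runs of ≥ 2 adjacent samples with r ≥ r_threshold
    (positive tail); mass = Σ r.  Each permutation shuffles the score vector
    across subjects and records the maximum cluster mass.  Returns
    ``(clusters, r_series, null_max)``.
    """
    x = np.asarray(auc_matrix, dtype=float)
    s = np.asarray(scores, dtype=float)
    r = correlation_timecourse(x, s)
    t_axis = np.asarray(times, dtype=float) if times is not None else np.arange(r.size, dtype=float)
    clusters = []
    for start, end in _runs(r >= r_threshold, min_len):
        clusters.append(ClusterResult(
            start_idx=start, end_idx=end, start_ms=float(t_axis[start]),
            end_ms=float(t_axis[end]), mass=float(r[start:end + 1].sum())))
    rng = np.random.default_rng(seed)
    # permuted r series in one batch: shuffled centered scores against the
    # fixed centered AUC columns
    xc = x - x.mean(axis=0)
    xnorm = np.sqrt((xc ** 2).sum(axis=0))
    sc = s - s.mean()
    snorm = np.sqrt((sc ** 2).sum())
    perm_idx = np.argsort(rng.random((n_perm, s.size)), axis=1)
    null_max = np.empty(n_perm)
    chunk = max(1, int(5e6 // max(x.size, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm_scores = sc[perm_idx[done:done + m]]          # m × subjects
        num = perm_scores @ xc                             # m × timepoints
        with np.errstate(divide="ignore", invalid="ignore"):
            perm_r = num / (snorm * xnorm)
        perm_r = np.where(xnorm == 0, 0.0, perm_r)
        for i in range(m):
            best = 0.0
            for start, end in _runs(perm_r[i] >= r_threshold, min_len):
                best = max(best, float(perm_r[i, start:end + 1].sum()))
            null_max[done + i] = best
        done += m
    return _attach_pstar(clusters, null_max, cluster_alpha), r, null_max
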