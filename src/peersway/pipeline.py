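"""End-to-end orchestration: simulate → preprocess → score → decode → infer.

Glues the individual stages together the way an analysis notebook would, so
parameter-recovery checks and the reproduction script can run the whole
chain with one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, clusters, decoding, models, preprocess, pvd
from .design import DesignConfig
from .simulate import CohortData, CohortParams, simulate_cohort


@dataclass
class PipelineResult:
    """Outputs of one full analysis run on a (synthetic) cohort."""

    cohort: CohortData
    scores: pd.DataFrame
    qc: behavior.QCReport
    nofeedback_test: dict
    pvd_scores: pd.DataFrame
    alpha_pi: float
    alpha_ga: float
    auc_matrix: np.ndarray            # subjects × timepoints
    times: np.ndarray
    decoding_clusters: list
    correlation_clusters: list
    r_series: np.ndarray
    stage_auc: np.ndarray             # per subject
    combination: np.ndarray
    model_fits: dict                  # from models.model_set on z_pi
    long_table: pd.DataFrame


def decode_cohort(cohort: CohortData, contrast=None, k: int = 10,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-subject AUC time-courses for one contrast (default: disagreement
    vs agreement).  Returns (auc_matrix, times, participant order)."""
    contrast = contrast or decoding.disagreement_vs_agreement()
    rows, pids = [], []
    times = None
    for i, (pid, ep) in enumerate(sorted(cohort.epochs.items())):
        ep = preprocess.baseline_correct(preprocess.average_reference(ep))
        y, idx = decoding.build_labels(ep.labels, contrast)
        tc = decoding.decode_timecourse(ep, y, trial_idx=idx, k=k,
                                        seed=seed + i,
                                        contrast_name=contrast.name)
        rows.append(tc.auc)
        pids.append(pid)
        times = tc.times
    return np.vstack(rows), times, pids


def run_pipeline(params: CohortParams | None = None,
                 design: DesignConfig | None = None,
                 seed: int = 0, k: int = 10,
                 n_perm_decoding: int = 500,
                 n_perm_correlation: int = 1000,
                 decoding_cluster_alpha: float = 0.01,
                 correlation_cluster_alpha: float = 0.05) -> PipelineResult:
    """Run the whole analysis chain on a synthetic cohort."""
    params = params or CohortParams()
    design = design or DesignConfig.lab()
    cohort = simulate_cohort(params, design, seed=seed)

    scores = behavior.score_table(cohort.trials)
    _, qc = behavior.qc_filter(scores)
    nofb = behavior.nofeedback_bias_test(scores["change_no_feedback"])

    pvd_scores = pvd.score_pvd(cohort.pvd_responses)
    alpha_pi = pvd.cronbach_alpha(
        pvd.subscale_matrix(cohort.pvd_responses, pvd.PI_ITEMS, params.likert_max))
    alpha_ga = pvd.cronbach_alpha(
        pvd.subscale_matrix(cohort.pvd_responses, pvd.GA_ITEMS, params.likert_max))

    auc, times, pids = decode_cohort(cohort, k=k, seed=seed)
    dec_clusters, _ = clusters.permutation_null_decoding(
        auc, times=times, n_perm=n_perm_decoding, seed=seed,
        cluster_alpha=decoding_cluster_alpha)

    order = pd.Index(pids)
    z_pi = pvd_scores.set_index("participant").loc[order, "z_pi"].to_numpy()
    corr_clusters, r_series, _ = clusters.permutation_null_correlation(
        auc, z_pi, times=times, n_perm=n_perm_correlation, seed=seed,
        cluster_alpha=correlation_cluster_alpha)

    stage_mask = ((times >= 200.0) & (times < 900.0))
    stage_auc = auc[:, stage_mask].mean(axis=1)
    combination = models.combination_index(stage_auc, z_pi)

    long = behavior.scores_long(scores)
    covars = pvd_scores[["participant", "z_pi", "z_ga"]]
    long = long.merge(covars, on="participant", how="left")
    long = long.merge(
        pd.DataFrame({"participant": pids, "stage_auc": stage_auc,
                      "combination": combination}),
        on="participant", how="left")
    fits = models.model_set(long, "z_pi")

    return PipelineResult(
        cohort=cohort, scores=scores, qc=qc, nofeedback_test=nofb,
        pvd_scores=pvd_scores, alpha_pi=alpha_pi, alpha_ga=alpha_ga,
        auc_matrix=auc, times=times, decoding_clusters=dec_clusters,
        correlation_clusters=corr_clusters, r_series=r_series,
        stage_auc=stage_auc, combination=combination, model_fits=fits,
        long_table=long)
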