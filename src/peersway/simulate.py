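"""Synthetic cohorts with the statistical structure the analysis assumes.

A latent per-subject *vulnerability* trait v ~ N(0, 1) drives everything:

* behavior — each subject adjusts post-test ratings towards the fictive
  peer rating with reliance weight ``w = logistic(a + b·v)``; ratings are
  integer 1–8 after noise, rounding and clipping;
* questionnaire — 15 Likert items load on v (reverse-keyed items with
  inverted sign), with loadings calibrated to the target internal
  consistencies of the two subscales;
* EEG — feedback-locked epochs contain two condition-dependent components
  (fronto-central 200–400 ms; occipito-parietal/right-frontal 400–900 ms)
  whose amplitude grows with disagreement strength and with a per-subject
  gain ``g = c0 + c1·v + noise``, on top of spatially correlated AR(1)
  noise.  Agreement trials carry zero component amplitude and the baseline
  window is signal-free by construction.

Default parameter magnitudes are calibration choices for desk-scale runs
(documented in docs/methods.md), not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, assign_schedule_feedback, generate_schedule
from .epochs import EpochSet, default_times, load_montage
from .pvd import N_ITEMS, PI_ITEMS, REVERSE_ITEMS

#: Named channel groups over the packaged 64-channel montage.
CHANNEL_GROUPS = {
    "fronto_central": ["Fz", "F1", "F2", "FC1", "FC2", "FC3", "FC4",
                       "Cz", "C1", "C2"],
    "occipito_parietal": ["O1", "Oz", "O2", "PO3", "POz", "PO4", "PO7",
                          "PO8", "P1", "Pz", "P2"],
    "right_frontal": ["F4", "F6", "F8", "AF4", "AF8", "FC6", "FT8"],
}


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for one synthetic cohort (the default preset).

    ``influence_intercept``/``influence_slope`` are (a, b) of the reliance
    link ``w = logistic(a + b·v)``; slopes are non-negative in the default
    preset (vulnerability raises both social influence and neural gain).
    """

    n_subjects: int = 17
    # behavior
    initial_rating_mean: float = 4.2
    initial_rating_sd: float = 1.2
    rating_noise_sd: float = 0.7
    influence_intercept: float = -1.7   # mean reliance weight ≈ 0.15
    influence_slope: float = 0.8
    # questionnaire (7-point Likert)
    likert_max: int = 7
    loading_pi: float = 1.45
    loading_ga: float = 0.8
    item_scale: float = 1.2
    # EEG
    sfreq: float = 100.0
    gain_intercept: float = 1.0
    gain_slope: float = 0.4
    gain_noise_sd: float = 0.2
    amp_moderate: float = 0.22
    amp_strong: float = 0.33
    noise_sd: float = 1.0
    noise_spatial_scale: float = 0.05   # meters
    noise_ar_tau_ms: float = 25.0

    def __post_init__(self) -> None:
        if self.influence_slope < 0 or self.gain_slope < 0:
            raise ValueError("the default preset requires non-negative slopes")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass
class TemplateSet:
    """Two spatiotemporal components: unit-norm spatial maps × non-negative
    temporal profiles with bounded support."""

    spatial: np.ndarray    # (2, n_channels), rows unit-norm
    temporal: np.ndarray   # (2, n_samples), zero outside each stage window
    times: np.ndarray
    ch_names: list[str]


def make_templates(times: np.ndarray, montage: pd.DataFrame | None = None) -> TemplateSet:
    """Build the two-stage component set over the packaged montage.

    Stage 1: negative fronto-central map with a Gaussian time profile
    peaking at 300 ms (support 200–400 ms).  Stage 2: positive
    occipito-parietal / negative right-frontal map with a sustained
    raised-cosine plateau over 400–900 ms.
    """
    montage = load_montage() if montage is None else montage
    ch_names = montage["channel"].tolist()
    idx = {c: i for i, c in enumerate(ch_names)}
    n_ch = len(ch_names)

    s1 = np.zeros(n_ch)
    for c in CHANNEL_GROUPS["fronto_central"]:
        s1[idx[c]] = -1.0
    s2 = np.zeros(n_ch)
    for c in CHANNEL_GROUPS["occipito_parietal"]:
        s2[idx[c]] = 1.0
    for c in CHANNEL_GROUPS["right_frontal"]:
        s2[idx[c]] = -0.7
    spatial = np.vstack([s1 / np.linalg.norm(s1), s2 / np.linalg.norm(s2)])

    t = np.asarray(times, dtype=float)
    g = np.exp(-0.5 * ((t - 300.0) / 35.0) ** 2)
    g[(t < 200.0) | (t >= 400.0)] = 0.0

    plateau = np.zeros_like(t)
    ramp = 50.0
    inside = (t >= 400.0) & (t < 900.0)
    plateau[inside] = 1.0
    rise = inside & (t < 400.0 + ramp)
    fall = inside & (t >= 900.0 - ramp)
    plateau[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - 400.0) / ramp))
    plateau[fall] = 0.5 * (1 - np.cos(np.pi * (900.0 - t[fall]) / ramp))
    temporal = np.vstack([g, plateau])
    return TemplateSet(spatial=spatial, temporal=temporal, times=t,
                       ch_names=ch_names)


@dataclass
class CohortData:
    """Everything one synthetic cohort run produces."""

    trials: pd.DataFrame                 # all subjects, long trial table
    pvd_responses: pd.DataFrame
    epochs: dict[str, EpochSet]
    truth: pd.DataFrame                  # per-subject v, w, gain
    params: CohortParams
    design: DesignConfig


def _subject_ids(n: int) -> list[str]:
    return [f"s{i + 1:03d}" for i in range(n)]


def simulate_behavior(params: CohortParams, design: DesignConfig,
                      seed: int, v: np.ndarray | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trial tables for a cohort plus the ground-truth (v, w) per subject.

    Test ratings are ``round(clip(N(mean, sd), 1, 8))``; disagreement
    post-test ratings move a fraction w of the way to the fictive rating
    before noise, rounding and clipping; agreement/no-feedback post-test
    ratings are the test rating plus noise.
    """
    rng = np.random.default_rng(seed)
    ids = _subject_ids(params.n_subjects)
    if v is None:
        v = rng.standard_normal(params.n_subjects)
    w = 1.0 / (1.0 + np.exp(-(params.influence_intercept
                              + params.influence_slope * v)))
    lo, hi = design.scale_min, design.scale_max

    def _to_scale(x):
        return np.clip(np.round(x), lo, hi).astype(int)

    tables = []
    for pid, wi in zip(ids, w):
        sched = generate_schedule(design, rng, participant=pid)
        test_faces = sched.loc[sched["phase"] == "test", "face_id"]
        raw = rng.normal(params.initial_rating_mean, params.initial_rating_sd,
                         size=len(test_faces))
        ratings = dict(zip(test_faces, _to_scale(raw)))
        sched = assign_schedule_feedback(sched, ratings, design, rng)
        post_rows = sched["phase"] == "post_test"
        test_r = sched.loc[post_rows, "test_rating"].astype(float).to_numpy()
        fict = sched.loc[post_rows, "fictive_rating"].astype("Float64").to_numpy(dtype=float)
        noise = rng.normal(0.0, params.rating_noise_sd, size=post_rows.sum())
        target = np.where(np.isnan(fict), test_r, test_r + wi * (fict - test_r))
        # agreement trials have fictive = test, so the pull term vanishes there
        sched.loc[post_rows, "post_rating"] = _to_scale(target + noise)
        tables.append(sched)
    trials = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame({"participant": ids, "v": v, "w": w})
    return trials, truth


def simulate_pvd(params: CohortParams, v: np.ndarray, seed: int,
                 participants=None) -> pd.DataFrame:
    """Likert item responses loading on the latent trait.

    Reverse-keyed items are generated with inverted loading so that
    reverse-scoring recovers a positive loading on v.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(v, dtype=float)
    ids = list(participants) if participants is not None else _subject_ids(v.size)
    mid = (params.likert_max + 1) / 2.0
    data = {"participant": ids}
    for item in range(1, N_ITEMS + 1):
        lam = params.loading_pi if item in PI_ITEMS else params.loading_ga
        if item in REVERSE_ITEMS:
            lam = -lam
        cont = mid + params.item_scale * (lam * v + rng.standard_normal(v.size))
        data[f"item_{item}"] = np.clip(np.round(cont), 1, params.likert_max).astype(int)
    return pd.DataFrame(data)


def _noise_chol(ch_pos: np.ndarray, scale: float) -> np.ndarray:
    d2 = ((ch_pos[:, None, :] - ch_pos[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-0.5 * d2 / scale ** 2)
    return np.linalg.cholesky(cov + 1e-8 * np.eye(len(ch_pos)))


def _ar1_noise(rng, n_trials, n_ch, n_samples, chol, rho, sd):
    """Spatially correlated, temporally AR(1) noise with marginal SD ``sd``."""
    innov = rng.standard_normal((n_trials, n_ch, n_samples))
    innov = np.einsum("ij,njt->nit", chol, innov)
    out = np.empty_like(innov)
    out[:, :, 0] = innov[:, :, 0]
    scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, n_samples):
        out[:, :, t] = rho * out[:, :, t - 1] + scale * innov[:, :, t]
    return sd * out


def simulate_epochs(params: CohortParams, templates: TemplateSet,
                    trials: pd.DataFrame, gain: float, seed: int,
                    participant: str = "s01") -> EpochSet:
    """Feedback-locked epochs for one subject's test-phase feedback trials.

    ``trials`` is the subject's trial table; epochs are generated for test
    rows whose condition shows a fictive rating (agreement + the four
    disagreement types).  The component amplitude is 0 for agreement,
    ``amp_moderate`` or ``amp_strong`` for disagreements, times the subject
    gain.
    """
    rng = np.random.default_rng(seed)
    sel = trials[(trials["phase"] == "test")
                 & (trials["condition"] != "no_feedback")].reset_index(drop=True)
    if sel.empty:
        raise ValueError("no feedback-locked test trials to simulate")
    montage = load_montage()
    if templates.ch_names != montage["channel"].tolist():
        raise ValueError("template channels do not match the montage")
    ch_pos = montage[["x", "y", "z"]].to_numpy()
    times = templates.times
    n_trials, n_ch, n_samp = len(sel), len(ch_pos), times.size

    amp_by_cond = {"agree": 0.0,
                   "pos_mod": params.amp_moderate, "neg_mod": params.amp_moderate,
                   "pos_strong": params.amp_strong, "neg_strong": params.amp_strong}
    amps = sel["condition"].map(amp_by_cond).to_numpy(dtype=float) * gain

    component = np.einsum("kc,kt->ct", templates.spatial, templates.temporal)
    signal = amps[:, None, None] * component[None]
    rho = np.exp(-(1000.0 / params.sfreq) / params.noise_ar_tau_ms)
    noise = _ar1_noise(rng, n_trials, n_ch, n_samp,
                       _noise_chol(ch_pos, params.noise_spatial_scale),
                       rho, params.noise_sd)
    return EpochSet(data=signal + noise, times=times.copy(),
                    ch_names=list(templates.ch_names), ch_pos=ch_pos,
                    labels=sel, participant=participant,
                    sfreq=params.sfreq)


def simulate_cohort(params: CohortParams, design: DesignConfig,
                    seed: int, with_epochs: bool = True) -> CohortData:
    """Full cohort: behavior, questionnaire and (optionally) EEG epochs."""
    root = np.random.SeedSequence(seed)
    s_beh, s_pvd, s_gain, *s_eeg = root.spawn(3 + params.n_subjects)
    trials, truth = simulate_behavior(params, design,
                                      np.random.default_rng(s_beh))
    v = truth["v"].to_numpy()
    pvd = simulate_pvd(params, v, np.random.default_rng(s_pvd),
                       participants=truth["participant"])
    rng_g = np.random.default_rng(s_gain)
    gain = (params.gain_intercept + params.gain_slope * v
            + rng_g.normal(0.0, params.gain_noise_sd, size=v.size))
    truth = truth.assign(gain=gain)
    epochs: dict[str, EpochSet] = {}
    if with_epochs:
        times = default_times(params.sfreq)
        templates = make_templates(times)
        for pid, g, ss in zip(truth["participant"], gain, s_eeg):
            sub = trials[trials["participant"] == pid]
            epochs[pid] = simulate_epochs(params, templates, sub, g,
                                          np.random.default_rng(ss),
                                          participant=pid)
    return CohortData(trials=trials, pvd_responses=pvd, epochs=epochs,
                      truth=truth, params=params, design=design)
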