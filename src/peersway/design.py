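"""Trial schedules and feedback-condition assignment for the face-evaluation task.

The task interleaves *test* blocks (rate an unfamiliar face, then watch the
group's fictive modal rating) with *post-test* blocks in which the same faces
are rated a second time in shuffled order.  Feedback conditions are agreement
(fictive rating equals the participant's), four disagreement types crossing
valence (positive/negative) with strength (moderate ±2 / strong ±3 points),
and no-feedback control trials.

Because a ±2/±3 offset from an extreme rating can fall off the 1–8 scale,
conditions are assigned adaptively once the test rating is known, tracking
per-condition quotas online (:class:`QuotaTracker`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fictive-rating offset for each feedback condition (``None`` = no feedback shown).
DELTAS: dict[str, int | None] = {
    "agree": 0,
    "pos_mod": 2,
    "pos_strong": 3,
    "neg_mod": -2,
    "neg_strong": -3,
    "no_feedback": None,
}

CONDITIONS = tuple(DELTAS)
DISAGREEMENT_CONDITIONS = ("pos_mod", "pos_strong", "neg_mod", "neg_strong")
NEGATIVE_CONDITIONS = ("neg_mod", "neg_strong")

SCHEDULE_COLUMNS = [
    "participant",
    "block_pair",
    "phase",
    "trial_index",
    "face_id",
    "condition",
    "test_rating",
    "fictive_rating",
    "post_rating",
]


class DesignError(ValueError):
    """Raised for an internally inconsistent design configuration."""


@dataclass(frozen=True)
class DesignConfig:
    """Block structure and per-condition trial quotas for one participant.

    Parameters
    ----------
    n_block_pairs
        Number of interleaved test/post-test block pairs (6 online, 60 lab).
    trials_per_block
        Faces per block (8 in both designs).
    quota
        Trials per feedback condition; must sum to
        ``n_block_pairs * trials_per_block``.
    scale_min, scale_max
        Bounds of the integer trustworthiness rating scale.
    """

    n_block_pairs: int
    trials_per_block: int = 8
    scale_min: int = 1
    scale_max: int = 8
    quota: dict[str, int] = field(default_factory=dict)
    deltas: dict[str, int | None] = field(default_factory=lambda: dict(DELTAS))

    def __post_init__(self) -> None:
        unknown = set(self.quota) - set(self.deltas)
        if unknown:
            raise DesignError(f"quota for unknown conditions: {sorted(unknown)}")
        if sum(self.quota.values()) != self.n_trials:
            raise DesignError(
                f"quotas sum to {sum(self.quota.values())}, "
                f"expected {self.n_trials} trials"
            )
        for cond, mag in (("pos_mod", 2), ("neg_mod", 2), ("pos_strong", 3), ("neg_strong", 3)):
            delta = self.deltas.get(cond)
            if delta is None or abs(delta) != mag:
                raise DesignError(f"delta for {cond} must have magnitude {mag}")

    @property
    def n_trials(self) -> int:
        return self.n_block_pairs * self.trials_per_block

    @classmethod
    def online(cls) -> "DesignConfig":
        """The 48-trial crowd-sourced design (6 block pairs)."""
        return cls(
            n_block_pairs=6,
            quota={"agree": 12, "pos_mod": 6, "pos_strong": 6,
                   "neg_mod": 6, "neg_strong": 6, "no_feedback": 12},
        )

    @classmethod
    def lab(cls) -> "DesignConfig":
        """The 480-trial EEG design (60 block pairs)."""
        return cls(
            n_block_pairs=60,
            quota={"agree": 120, "pos_mod": 60, "pos_strong": 60,
                   "neg_mod": 60, "neg_strong": 60, "no_feedback": 120},
        )

    @classmethod
    def scaled(cls, n_block_pairs: int) -> "DesignConfig":
        """A design with the lab's condition proportions at a smaller size.

        ``n_block_pairs`` must be even so each disagreement type gets an
        integer quota (ratios 2:1:1:1:1:2 over 8 trials per pair).
        """
        if n_block_pairs % 2:
            raise DesignError("scaled designs need an even number of block pairs")
        unit = n_block_pairs  # trials per unit share: 8*pairs / 8 shares
        return cls(
            n_block_pairs=n_block_pairs,
            quota={"agree": 2 * unit, "pos_mod": unit, "pos_strong": unit,
                   "neg_mod": unit, "neg_strong": unit, "no_feedback": 2 * unit},
        )


def generate_schedule(
    config: DesignConfig,
    rng_seed: int | np.random.Generator,
    participant: str = "s01",
) -> pd.DataFrame:
    """Lay out test and post-test trials for one participant.

    Faces are unique across the session; each appears once in the test block
    and once, in freshly permuted order, in the matching post-test block.
    Conditions, ratings and fictive ratings are left unassigned (NA): they
    are filled in at run time by :func:`assign_feedback` once test ratings
    exist.

    Returns a DataFrame with :data:`SCHEDULE_COLUMNS`.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    face_counter = 0
    trial_index = 0
    for pair in range(config.n_block_pairs):
        faces = [f"face_{face_counter + i:04d}" for i in range(config.trials_per_block)]
        face_counter += config.trials_per_block
        for face in faces:
            rows.append((participant, pair, "test", trial_index, face))
            trial_index += 1
        for face in rng.permutation(faces):
            rows.append((participant, pair, "post_test", trial_index, face))
            trial_index += 1
    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS[:5])
    for col in ("condition",):
        df[col] = pd.Series([pd.NA] * len(df), dtype="object")
    for col in ("test_rating", "fictive_rating", "post_rating"):
        df[col] = pd.Series([pd.NA] * len(df), dtype="Int64")
    return df


class QuotaTracker:
    """Online bookkeeping of remaining per-condition quotas.

    Draws a condition uniformly among *feasible* conditions (those whose
    fictive rating stays on the scale for the given test rating) that still
    have quota.  If every remaining-quota condition is infeasible for the
    rating at hand, the feasible condition with the largest remaining quota
    (i.e. the least overshot) is assigned and the event is counted in
    :attr:`n_fallbacks`.
    """

    def __init__(self, config: DesignConfig):
        self.config = config
        self.remaining = dict(config.quota)
        self.n_fallbacks = 0

    def feasible(self, test_rating: int) -> list[str]:
        out = []
        for cond in self.config.quota:
            delta = self.config.deltas[cond]
            if delta is None:
                out.append(cond)
            elif self.config.scale_min <= test_rating + delta <= self.config.scale_max:
                out.append(cond)
        return out

    def draw(self, test_rating: int, rng: np.random.Generator) -> str:
        lo, hi = self.config.scale_min, self.config.scale_max
        if not lo <= test_rating <= hi:
            raise ValueError(f"test rating {test_rating} outside [{lo}, {hi}]")
        feasible = self.feasible(test_rating)
        open_conds = [c for c in feasible if self.remaining[c] > 0]
        if open_conds:
            cond = open_conds[rng.integers(len(open_conds))]
        else:
            # quota exhausted for every feasible condition: overshoot the one
            # that keeps totals closest to quota
            self.n_fallbacks += 1
            cond = max(feasible, key=lambda c: (self.remaining[c], c))
        self.remaining[cond] -= 1
        return cond


def assign_feedback(
    test_rating: int,
    tracker: QuotaTracker,
    rng: np.random.Generator,
) -> tuple[str, int | None]:
    """Draw a feedback condition for a test rating and derive the fictive rating.

    Returns ``(condition, fictive_rating)``; the fictive rating is ``None``
    for no-feedback trials and equals the test rating for agreement trials.
    The tracker's quota is decremented.
    """
    cond = tracker.draw(test_rating, rng)
    delta = tracker.config.deltas[cond]
    if delta is None:
        return cond, None
    fictive = test_rating + delta
    lo, hi = tracker.config.scale_min, tracker.config.scale_max
    if not lo <= fictive <= hi:  # pragma: no cover - guarded by feasibility
        raise RuntimeError("infeasible fictive rating emitted")
    return cond, fictive


def assign_schedule_feedback(
    schedule: pd.DataFrame,
    test_ratings: dict[str, int] | pd.Series,
    config: DesignConfig,
    rng_seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Fill conditions and fictive ratings for a whole test-phase schedule.

    ``test_ratings`` maps face id to the integer rating given in the test
    trial; post-test rows inherit the condition of their face.
    """
    rng = np.random.default_rng(rng_seed)
    tracker = QuotaTracker(config)
    out = schedule.copy()
    cond_by_face: dict[str, str] = {}
    fict_by_face: dict[str, int | None] = {}
    test_rows = out.index[out["phase"] == "test"]
    for idx in test_rows:
        face = out.at[idx, "face_id"]
        rating = int(test_ratings[face])
        cond, fictive = assign_feedback(rating, tracker, rng)
        cond_by_face[face] = cond
        fict_by_face[face] = fictive
        out.at[idx, "test_rating"] = rating
        out.at[idx, "condition"] = cond
        out.at[idx, "fictive_rating"] = pd.NA if fictive is None else fictive
    for idx in out.index[out["phase"] == "post_test"]:
        face = out.at[idx, "face_id"]
        if face not in cond_by_face:
            raise DesignError(f"post-test face {face} never shown in test phase")
        out.at[idx, "condition"] = cond_by_face[face]
        fictive = fict_by_face[face]
        out.at[idx, "fictive_rating"] = pd.NA if fictive is None else fictive
        out.at[idx, "test_rating"] = int(test_ratings[face])
    return out


def validate_schedule(schedule: pd.DataFrame, config: DesignConfig) -> None:
    """Check structural invariants of an assigned schedule; raise on violation."""
    test = schedule[schedule["phase"] == "test"]
    post = schedule[schedule["phase"] == "post_test"]
    if test["face_id"].duplicated().any() or post["face_id"].duplicated().any():
        raise DesignError("face repeated within a phase")
    if set(test["face_id"]) != set(post["face_id"]):
        raise DesignError("test and post-test phases show different faces")
    counts = test["condition"].value_counts().to_dict()
    for cond, n in config.quota.items():
        if counts.get(cond, 0) != n:
            raise DesignError(
                f"condition {cond}: {counts.get(cond, 0)} trials, quota {n}"
            )
    fb = test.dropna(subset=["fictive_rating"])
    fict = fb["fictive_rating"].astype(int)
    if ((fict < config.scale_min) | (fict > config.scale_max)).any():
        raise DesignError("fictive rating off scale")
    agree = test[test["condition"] == "agree"]
    if not (agree["fictive_rating"].astype(int) == agree["test_rating"].astype(int)).all():
        raise DesignError("agreement trial with mismatched fictive rating")


def write_schedule(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, sep="\t", index=False)


def read_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"participant": str, "face_id": str})
    for col in ("test_rating", "fictive_rating", "post_rating"):
        df[col] = df[col].astype("Int64")
    return df
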