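"""Perceived Vulnerability to Disease (PVD) questionnaire scoring.

The 15-item PVD scale splits into Perceived Infectability (PI: belief in
one's susceptibility to infection) and Germ Aversion (GA: discomfort in
transmission-risk situations).  Six items are reverse-keyed.  Besides plain
subscale means this module provides Cronbach's alpha and a greedy
alpha-maximization pruning used when a subscale's internal consistency is
unacceptably low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PI_ITEMS = (2, 5, 6, 8, 10, 12, 14)
GA_ITEMS = (1, 3, 4, 7, 9, 11, 13, 15)
REVERSE_ITEMS = frozenset({3, 5, 11, 12, 13, 14})
#: GA items retained by alpha maximization in low-reliability samples.
GA_MAXIMIZED_ITEMS = (1, 3, 7, 13)
N_ITEMS = 15

ITEM_COLUMNS = [f"item_{i}" for i in range(1, N_ITEMS + 1)]


def reverse_score(response, likert_max: int = 7):
    """Reflect a Likert response: ``r -> (L + 1) - r``.  An involution."""
    r = np.asarray(response)
    if np.any((r < 1) | (r > likert_max)):
        raise ValueError(f"response outside [1, {likert_max}]")
    out = (likert_max + 1) - r
    return out if out.ndim else out.item()


def _item_matrix(responses: pd.DataFrame, items, likert_max: int,
                 reverse: bool = True) -> np.ndarray:
    """Extract an items matrix (participants × items), reverse-keyed on request."""
    missing = [c for c in ITEM_COLUMNS if c not in responses.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    mat = responses[[f"item_{i}" for i in items]].to_numpy(dtype=float)
    if np.any((mat < 1) | (mat > likert_max)):
        raise ValueError(f"responses outside [1, {likert_max}]")
    if reverse:
        for j, i in enumerate(items):
            if i in REVERSE_ITEMS:
                mat[:, j] = (likert_max + 1) - mat[:, j]
    return mat


def subscale_matrix(responses: pd.DataFrame, items, likert_max: int = 7) -> np.ndarray:
    """Reverse-keyed participants × items matrix for a subscale (for alpha)."""
    return _item_matrix(responses, items, likert_max)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined: zero variance across participants")
    return (x - x.mean()) / sd


def score_pvd(responses: pd.DataFrame, likert_max: int = 7,
              maximize_ga: bool = True) -> pd.DataFrame:
    """Score PI and GA subscales (means after reverse-keying) plus z-scores.

    ``maximize_ga`` additionally scores GA over the pruned 4-item set used
    when the full subscale is unreliable.  Requires ≥ 2 participants for the
    z-transform.
    """
    if len(responses) < 2:
        raise ValueError("need at least 2 participants for z-scores")
    pi = _item_matrix(responses, PI_ITEMS, likert_max).mean(axis=1)
    ga = _item_matrix(responses, GA_ITEMS, likert_max).mean(axis=1)
    out = pd.DataFrame({
        "participant": responses["participant"].to_numpy(),
        "perceived_infectability": pi,
        "germ_aversion": ga,
        "z_pi": _zscore(pi),
        "z_ga": _zscore(ga),
    })
    if maximize_ga:
        gam = _item_matrix(responses, GA_MAXIMIZED_ITEMS, likert_max).mean(axis=1)
        out["germ_aversion_maximized"] = gam
        out["z_ga_maximized"] = _zscore(gam)
    return out


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: ``(k/(k-1)) * (1 - sum(item var) / var(total))``.

    Variances use ddof=1.  Raises if the total score has zero variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a participants × items matrix, both dims ≥ 2")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass
class AlphaTrajectory:
    """Removal order and alpha value after each pruning step."""

    retained: list[int]
    removed: list[int]
    alphas: list[float]  # alphas[0] = full set; alphas[i] after i removals

    @property
    def final_alpha(self) -> float:
        return self.alphas[-1]


def maximize_alpha(item_matrix: np.ndarray, item_ids=None,
                   target_alpha: float = 0.7) -> AlphaTrajectory:
    """Greedy one-item-at-a-time pruning to raise Cronbach's alpha.

    At each step the single item whose removal most increases alpha is
    dropped (ties go to the lowest item id).  Stops when alpha reaches
    ``target_alpha``, when no removal improves alpha, or when only 2 items
    remain.  The alpha trajectory is non-decreasing by construction.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 items to prune")
    ids = list(item_ids) if item_ids is not None else list(range(1, x.shape[1] + 1))
    if len(ids) != x.shape[1]:
        raise ValueError("item_ids length mismatch")
    cols = list(range(x.shape[1]))
    alphas = [cronbach_alpha(x[:, cols])]
    removed: list[int] = []
    while len(cols) > 2 and alphas[-1] < target_alpha:
        best_alpha, best_j = -np.inf, None
        for j in cols:
            rest = [c for c in cols if c != j]
            a = cronbach_alpha(x[:, rest])
            if a > best_alpha or (a == best_alpha and ids[j] < ids[best_j]):
                best_alpha, best_j = a, j
        if best_alpha <= alphas[-1]:
            break
        cols.remove(best_j)
        removed.append(ids[best_j])
        alphas.append(best_alpha)
    return AlphaTrajectory(retained=[ids[c] for c in cols],
                           removed=removed, alphas=alphas)
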