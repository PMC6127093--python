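"""Random-intercept linear mixed models, BIC Bayes factors, combination index.

Social-influence scores (4 rows per participant: valence × strength, both
deviation-coded −0.5/+0.5) are modelled with participant as a random
intercept, fitted by maximum likelihood.  Competing models — a baseline
with the two within-subject factors, a *type-1* model adding a
between-subject covariate as a main effect, and a *type-2* model crossing
the covariate with both factors — are compared with the BIC approximation
to the Bayes factor, ``BF10 = exp((BIC_base − BIC_alt) / 2)``.  This is an
explicit stand-in for JZS-prior Bayes factors: model *orderings* are the
meaningful output, not the BF magnitudes themselves.

The fit profiles the likelihood over the variance ratio ψ = σ²_b/σ²_e: for
a given ψ the GLS fixed effects, the ML residual variance and the profiled
log-likelihood are all closed-form (the per-group covariance is
I + ψ·11ᵀ, inverted by Sherman–Morrison), leaving a one-dimensional
maximization over ψ ≥ 0.

t-test degrees of freedom follow the inner–outer convention: terms constant
within participants are tested against between-subject df
(``n_groups − 1 − n_between_terms``); terms varying within participants
against ``n_obs − n_groups − n_within_terms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats


@dataclass
class ModelFit:
    """Fixed effects, variance components and information criteria of one fit."""

    formula: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    dfs: pd.Series
    pvalues: pd.Series
    loglik: float
    bic: float
    n_obs: int
    n_groups: int
    group_var: float
    resid_var: float
    psi: float                       # fitted variance ratio σ²_b / σ²_e
    response: np.ndarray = field(repr=False, default=None)


class _RandomInterceptML:
    """Profiled ML machinery for one grouped design."""

    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray):
        self.X, self.y = X, y
        self.groups = [np.flatnonzero(group_idx == g)
                       for g in np.unique(group_idx)]
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise np.linalg.LinAlgError("rank-deficient fixed-effect design")

    def _gls(self, psi: float):
        """GLS β, ML σ²_e, Σ log|V_i| and the normal matrix at a given ψ."""
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        logdet = 0.0
        for idx in self.groups:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            shrink = psi / (1.0 + psi * ni)
            XtVX += Xi.T @ Xi - shrink * np.outer(Xi.sum(0), Xi.sum(0))
            XtVy += Xi.T @ yi - shrink * Xi.sum(0) * yi.sum()
            logdet += np.log1p(psi * ni)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = 0.0
        for idx in self.groups:
            ri = self.y[idx] - self.X[idx] @ beta
            ni = len(idx)
            shrink = psi / (1.0 + psi * ni)
            rss += ri @ ri - shrink * ri.sum() ** 2
        sigma2 = rss / self.n
        return beta, sigma2, logdet, XtVX

    def loglik(self, psi: float) -> float:
        _, sigma2, logdet, _ = self._gls(psi)
        return -0.5 * (self.n * np.log(2 * np.pi * sigma2) + logdet + self.n)

    def fit(self):
        # coarse grid (including the ψ = 0 boundary), then local refinement
        grid = np.concatenate([[0.0], np.logspace(-4, 3, 40)])
        lls = np.array([self.loglik(p) for p in grid])
        i = int(np.argmax(lls))
        if i == 0:
            psi = 0.0
            res = optimize.minimize_scalar(lambda p: -self.loglik(p),
                                           bounds=(0.0, grid[1]),
                                           method="bounded")
            if -res.fun > lls[0]:
                psi = float(res.x)
        else:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(lambda p: -self.loglik(p),
                                           bounds=(lo, hi), method="bounded")
            psi = float(res.x)
            if self.loglik(0.0) >= -res.fun:
                psi = 0.0
        beta, sigma2, _, XtVX = self._gls(psi)
        cov_beta = sigma2 * np.linalg.inv(XtVX)
        return beta, cov_beta, sigma2, psi, self.loglik(psi)


def _term_dfs(design_info, X: np.ndarray, group_idx: np.ndarray) -> dict[str, int]:
    """Inner–outer df per design column."""
    names = design_info.column_names
    within = {}
    for j, name in enumerate(names):
        col = X[:, j]
        varies = False
        for g in np.unique(group_idx):
            v = col[group_idx == g]
            if np.ptp(v) > 1e-12:
                varies = True
                break
        within[name] = varies
    n_obs = X.shape[0]
    n_groups = len(np.unique(group_idx))
    n_within = sum(within.values())
    n_between = sum(1 for nm, w in within.items()
                    if not w and nm != "Intercept")
    return {nm: (n_obs - n_groups - n_within) if w
            else (n_groups - 1 - n_between)
            for nm, w in within.items()}


def fit_random_intercept(data: pd.DataFrame, fixed_spec: str,
                         response: str = "score",
                         groups: str = "participant") -> ModelFit:
    """ML fit of ``response ~ fixed_spec`` with a participant random intercept.

    ``fixed_spec`` is a formula right-hand side, e.g.
    ``"valence * strength + z_pi"``.  Requires ≥ 2 participants with ≥ 2
    rows each for the variance decomposition to be identified.
    """
    y = np.asarray(data[response], dtype=float)
    X = patsy.dmatrix(fixed_spec, data, return_type="matrix")
    design_info = X.design_info
    X = np.asarray(X)
    group_codes, _ = pd.factorize(data[groups])
    if len(np.unique(group_codes)) < 2:
        raise ValueError("need at least 2 participants")
    beta, cov_beta, sigma2, psi, llf = _RandomInterceptML(X, y, group_codes).fit()

    names = design_info.column_names
    params = pd.Series(beta, index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    tvals = params / bse
    dfs = pd.Series(_term_dfs(design_info, X, group_codes)).reindex(names)
    pvals = pd.Series(
        {nm: 2.0 * stats.t.sf(abs(tvals[nm]), df=max(dfs[nm], 1))
         for nm in names})
    n_obs = len(y)
    k_total = len(names) + 2  # fixed effects + two variance components
    return ModelFit(
        formula=f"{response} ~ {fixed_spec}",
        params=params,
        bse=bse,
        tvalues=tvals,
        dfs=dfs,
        pvalues=pvals.reindex(names),
        loglik=float(llf),
        bic=float(-2.0 * llf + k_total * np.log(n_obs)),
        n_obs=n_obs,
        n_groups=len(np.unique(group_codes)),
        group_var=float(psi * sigma2),
        resid_var=float(sigma2),
        psi=float(psi),
        response=y,
    )


def bayes_factor(model_alt: ModelFit, model_base: ModelFit) -> float:
    """BIC-approximate BF10; > 1 favors the alternative model."""
    if model_alt.n_obs != model_base.n_obs or (
            model_alt.response is not None and model_base.response is not None
            and not np.allclose(model_alt.response, model_base.response)):
        raise ValueError("models were fitted to different responses")
    return float(np.exp((model_base.bic - model_alt.bic) / 2.0))


BASELINE_SPEC = "valence * strength"


def model_set(data: pd.DataFrame, covariate: str,
              baseline_spec: str = BASELINE_SPEC) -> dict:
    """Baseline, type-1 (main effect) and type-2 (fully crossed) fits.

    Returns a dict with the three :class:`ModelFit` objects and the BF10 of
    each alternative against the baseline.
    """
    base = fit_random_intercept(data, baseline_spec)
    type1 = fit_random_intercept(data, f"{baseline_spec} + {covariate}")
    type2 = fit_random_intercept(data, f"{baseline_spec} * {covariate}")
    return {
        "baseline": base,
        "type1": type1,
        "type2": type2,
        "bf10_type1": bayes_factor(type1, base),
        "bf10_type2": bayes_factor(type2, base),
    }


def combination_index(mean_stage_auc: np.ndarray,
                      pvd_score: np.ndarray) -> np.ndarray:
    """z(mean stage AUC) + z(PVD subscale score), per subject.

    The AUC input is each subject's decoding sensitivity averaged over the
    two processing-stage windows (200–400 and 400–900 ms by default
    upstream).  Sample mean of the index is 0 by construction.
    """
    a = np.asarray(mean_stage_auc, dtype=float)
    s = np.asarray(pvd_score, dtype=float)
    if a.size != s.size or a.size < 3:
        raise ValueError("need aligned vectors of at least 3 subjects")
    for name, v in (("mean_stage_auc", a), ("pvd_score", s)):
        if v.std(ddof=1) == 0:
            raise ValueError(f"z-score undefined: {name} is constant")
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    return z(a) + z(s)
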