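"""Boldness scoring and repeatability.

Novel-object tests record the proportion of a 60 s exposure a bird spends in
five mutually exclusive states (sitting, raised up, standing, off the nest,
off the ledge). A covariance-matrix PCA collapses the five proportions to a
single axis (PC1), oriented so that sitting tight (the bold response) scores
high. Because the five proportions sum to one, the compositional constraint
forces a zero-variance fifth component whose loadings are all 1/sqrt(5) in
magnitude — a structural check on any such dataset.

Adjusted repeatability R = sigma2_bird / (sigma2_bird + sigma2_residual) is
estimated from a linear mixed model with a random intercept per bird and
optional fixed covariates, with parametric-bootstrap confidence intervals and
a likelihood-ratio test of the between-bird variance against the
0.5*chi2(0) + 0.5*chi2(1) boundary mixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

log = logging.getLogger(__name__)

BEHAVIOUR_COLS = ["p_sit", "p_raised", "p_stand", "p_off_nest", "p_off_ledge"]


# ---------------------------------------------------------------------------
# PCA boldness

@dataclass
class PCAResult:
    loadings: np.ndarray            # (5, 5), columns = components
    eigenvalues: np.ndarray         # descending
    variance_explained: np.ndarray  # eigenvalues / total variance
    scores: np.ndarray              # (n_tests, 5)

    @property
    def pc1_scores(self) -> np.ndarray:
        return self.scores[:, 0]


def pca_boldness(tests: pd.DataFrame) -> PCAResult:
    """Covariance PCA of the five behaviour proportions.

    Proportions are centred but not rescaled. PC1 is oriented so that the
    sitting proportion loads positively (bold = sat tight); the remaining
    components are sign-fixed by their largest-magnitude loading for
    determinism.
    """
    X = tests[BEHAVIOUR_COLS].to_numpy(dtype=float)
    if len(X) < 6:
        raise ValueError("need at least 6 tests for a 5-variable PCA")
    sums = X.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("behaviour proportions must sum to 1")
    Xc = X - X.mean(axis=0)
    C = np.cov(Xc, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    L = evecs[:, order]
    # orientation: PC1 by the sitting loading, others by dominant loading
    if L[0, 0] < 0:
        L[:, 0] = -L[:, 0]
    for j in range(1, L.shape[1]):
        k = int(np.argmax(np.abs(L[:, j])))
        if L[k, j] < 0:
            L[:, j] = -L[:, j]
    return PCAResult(loadings=L, eigenvalues=evals,
                     variance_explained=evals / evals.sum(),
                     scores=Xc @ L)


# ---------------------------------------------------------------------------
# repeatability (shared estimator, also used for trip metrics)

@dataclass
class RepeatabilityResult:
    R: float
    var_between: float
    var_within: float
    ci: dict = field(default_factory=dict)   # level -> (lo, hi)
    p: float = np.nan
    n_boot: int = 0
    boot_R: np.ndarray | None = None

    @property
    def ci95(self):
        return self.ci.get(0.95)

    @property
    def ci84(self):
        return self.ci.get(0.84)


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    X = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(n), X])


class _RandomInterceptLMM:
    """Profiled (RE)ML for the one-random-intercept linear mixed model.

    For variance ratio lam = var_between / var_within the covariance is
    sigma2 * (I + lam Z Z') with Z the group-indicator matrix, whose inverse
    and determinant decompose per group (Woodbury), so the profiled (RE)ML
    criterion is a cheap scalar function of log(lam). Used instead of a
    generic mixed-model fitter because the bootstrap refits this model
    thousands of times.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        self.X = X
        self.n, self.p = X.shape
        self.uniq, self.inv = np.unique(groups, return_inverse=True)
        self.G = len(self.uniq)
        self.ng = np.bincount(self.inv)
        self.XtX = X.T @ X
        # per-group column sums of X: (G, p)
        self.Xg = np.zeros((self.G, self.p))
        np.add.at(self.Xg, self.inv, X)

    def _suff(self, y: np.ndarray):
        yg = np.bincount(self.inv, weights=y)
        return y @ y, self.X.T @ y, yg

    def _crit(self, loglam: float, y, yty, Xty, yg, reml: bool) -> float:
        lam = np.exp(loglam)
        w = lam / (1.0 + self.ng * lam)                  # (G,)
        A = self.XtX - (self.Xg.T * w) @ self.Xg         # X' V*^-1 X
        b = Xty - self.Xg.T @ (w * yg)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return 1e12
        # r' V*^-1 r = y'V*^-1 y - 2 beta'X'V*^-1 y + beta'X'V*^-1 X beta
        q = (yty - np.sum(w * yg * yg)) - 2.0 * b @ beta + beta @ A @ beta
        if q <= 0:
            return 1e12
        logdetV = float(np.sum(np.log1p(self.ng * lam)))
        if reml:
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            return logdetV + logdetA + (self.n - self.p) * np.log(q)
        return logdetV + self.n * np.log(q)

    def fit(self, y: np.ndarray, reml: bool = True):
        """Returns (var_between, var_within, beta, loglik_at_mode)."""
        # optimise the variance ratio on the standardised response so the
        # estimate is exactly invariant to affine rescaling of y
        scale = float(np.std(y)) or 1.0
        ys = (y - float(np.mean(y))) / scale
        yty, Xty, yg = self._suff(ys)

        def f(ll):
            return self._crit(ll, ys, yty, Xty, yg, reml)

        grid = np.linspace(-12.0, 12.0, 25)
        vals = [f(g) for g in grid]
        k = int(np.argmin(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-9})
        loglam = float(res.x)
        # allow the boundary lam -> 0 to win
        if f(-30.0) <= res.fun + 1e-9:
            loglam = -30.0
        lam = np.exp(loglam)
        yty, Xty, yg = self._suff(y)   # back on the original scale
        w = lam / (1.0 + self.ng * lam)
        A = self.XtX - (self.Xg.T * w) @ self.Xg
        b = Xty - self.Xg.T @ (w * yg)
        beta = np.linalg.solve(A, b)
        q = (yty - np.sum(w * yg * yg)) - 2.0 * b @ beta + beta @ A @ beta
        dof = self.n - self.p if reml else self.n
        sigma2 = max(q / dof, 0.0)
        var_b = lam * sigma2 if lam > 1e-12 else 0.0
        logdetV = float(np.sum(np.log1p(self.ng * lam)))
        llf = -0.5 * (self.n * np.log(2.0 * np.pi * max(sigma2, 1e-300))
                      + logdetV + q / max(sigma2, 1e-300))
        return var_b, sigma2, beta, llf


def adjusted_repeatability(values, bird_ids, covariates: pd.DataFrame | None = None,
                           n_boot: int = 1000, seed: int = 0,
                           ci_levels: tuple[float, ...] = (0.95,)) -> RepeatabilityResult:
    """Adjusted repeatability of ``values`` across ``bird_ids``.

    Fits value ~ covariates + (1 | bird) by REML; R is the between-bird share
    of the residual variance after fixed effects. Confidence intervals are
    percentile intervals over ``n_boot`` parametric-bootstrap refits; the p
    value is a boundary-corrected likelihood-ratio test of sigma2_bird = 0
    against the 0.5*chi2(0) + 0.5*chi2(1) mixture.
    """
    y = np.asarray(values, dtype=float)
    groups = pd.Series(bird_ids).astype(str).to_numpy()
    counts = pd.Series(groups).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 birds with >= 2 observations for repeatability")
    X = _covariate_matrix(covariates, len(y))
    lmm = _RandomInterceptLMM(X, groups)

    var_b, var_e, beta, _ = _guarded_fit(lmm, y)
    R = _ratio(var_b, var_e)

    _, _, _, llf_full = lmm.fit(y, reml=False)
    llf_null = sm.OLS(y, X).fit().llf
    lrt = max(2.0 * (llf_full - llf_null), 0.0)
    p = 1.0 if lrt <= 0 else 0.5 * stats.chi2.sf(lrt, df=1)

    ci: dict = {}
    boot_R = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = X @ beta
        boot = np.empty(n_boot)
        for b in range(n_boot):
            re = rng.normal(0.0, np.sqrt(max(var_b, 0.0)), size=lmm.G)
            yb = fitted + re[lmm.inv] + rng.normal(0.0, np.sqrt(max(var_e, 1e-300)),
                                                   size=len(y))
            vb, ve, _, _ = _guarded_fit(lmm, yb)
            boot[b] = _ratio(vb, ve)
        boot_R = boot
        for level in ci_levels:
            a = (1.0 - level) / 2.0
            ci[level] = (float(np.quantile(boot, a)), float(np.quantile(boot, 1.0 - a)))
    return RepeatabilityResult(R=R, var_between=var_b, var_within=var_e,
                               ci=ci, p=float(p), n_boot=n_boot, boot_R=boot_R)


def _ratio(var_b: float, var_e: float) -> float:
    tot = var_b + var_e
    if tot <= 0:
        return 0.0
    return float(np.clip(var_b / tot, 0.0, 1.0))


def _guarded_fit(lmm: _RandomInterceptLMM, y: np.ndarray):
    """REML fit with shortcuts for degenerate (zero-variance) data."""
    ols = sm.OLS(y, lmm.X).fit()
    resid = np.asarray(ols.resid)
    tot = float(np.var(resid, ddof=0))
    if tot <= 1e-300:
        return 0.0, 0.0, np.asarray(ols.params), ols.llf
    means = np.bincount(lmm.inv, weights=resid) / lmm.ng
    within = float(np.mean((resid - means[lmm.inv]) ** 2))
    if within <= 1e-12 * tot:  # every bird repeats itself exactly
        return tot, 0.0, np.asarray(ols.params), np.inf
    return lmm.fit(y, reml=True)


# ---------------------------------------------------------------------------
# per-bird boldness and bold/shy split

def individual_boldness(pc1_scores, bird_ids,
                        covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """One boldness estimate per bird from a linear model on PC1.

    Bird identity enters as a factor without a global intercept, so each
    bird's coefficient is its boldness; covariates (test date, stage,
    observer, test number) are centred so estimates are at average covariate
    values. Aliased covariate columns are dropped with a warning.
    """
    y = np.asarray(pc1_scores, dtype=float)
    birds = pd.Series(bird_ids).astype(str)
    dummies = pd.get_dummies(birds)
    uniq = list(dummies.columns)
    B = dummies.to_numpy(dtype=float)
    X = B
    if covariates is not None and covariates.shape[1] > 0:
        Cdf = pd.get_dummies(covariates, drop_first=True)
        # covariates aliased with bird identity (e.g. one observer per bird)
        # cannot be separated from the boldness estimates: drop them
        for col in Cdf.columns:
            c = Cdf[col].to_numpy(dtype=float)
            cand = np.column_stack([X, c - c.mean()])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
                X = cand
            else:
                log.warning("dropping covariate '%s': aliased with bird identity",
                            col)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    n_tests = birds.value_counts()
    return pd.DataFrame({"bird_id": uniq,
                         "boldness": coef[: len(uniq)],
                         "n_tests": [int(n_tests[b]) for b in uniq]})


def classify_bold_shy(scores: pd.DataFrame, column: str = "boldness") -> pd.DataFrame:
    """Median-split birds into bold (strictly above) and shy (at or below).

    Birds exactly at the median go to shy — an explicit tie rule, so an odd
    number of distinct scores yields one more shy bird than bold.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 birds to split")
    med = float(scores[column].median())
    out = scores.copy()
    out["group"] = np.where(out[column] > med, "bold", "shy")
    return out
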