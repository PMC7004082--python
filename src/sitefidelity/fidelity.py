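"""Randomization-based foraging-site fidelity.

Each foraging site is taken in turn as the focal site and randomly paired
with (a) one site of the same bird from a *different* trip (within-individual
pair) and (b) one site from each other bird of the same colony and breeding
stage (between-individual pairs). A between-pair scores 1 when the bird's own
paired site is closer to the focal site than the other bird's site (ties
score 0), so the per-bird proportion of 1s is a site-fidelity index on
[0, 1]: 1 means no other individual foraged closer than the bird's own
repeat visits. Single-trip birds are never focal but still donate
between-individual sites.

Repeating the randomization (default 1,000 iterations) yields a distribution
of per-bird fidelity estimates. Within an iteration the pooled Bernoulli
outcomes are modelled by a binomial GLM with bird identity as a factor (no
global intercept) plus the centred focal-to-within time difference in days;
each bird's fidelity is the inverse-logit of its coefficient, with a
delta-method standard error. Birds with all-0 or all-1 outcomes (complete
separation) are clamped to 1/(2m) or 1 - 1/(2m) and flagged. With the time
covariate disabled the estimate reduces to the raw per-bird proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .geo import haversine_m

SITE_COLUMNS = ["site_id", "bird_id", "trip_id", "colony_id", "stage",
                "lat_c", "lon_c", "t_mid"]


@dataclass
class PairDraw:
    focal_site_id: str
    within_site_id: str
    between_site_ids: dict  # other bird_id -> site_id
    iteration: int = 0


# ---------------------------------------------------------------------------
# precomputed per-colony structures

class _ColonyGroup:
    """Distance matrix and index bookkeeping for one colony x stage."""

    def __init__(self, sites: pd.DataFrame):
        self.sites = sites.reset_index(drop=True)
        lat = self.sites["lat_c"].to_numpy(dtype=float)
        lon = self.sites["lon_c"].to_numpy(dtype=float)
        self.dmat = np.asarray(haversine_m(lat[:, None], lon[:, None],
                                           lat[None, :], lon[None, :]))
        t = pd.to_datetime(self.sites["t_mid"])
        self.t_days = (t - t.min()).dt.total_seconds().to_numpy() / 86400.0
        birds = self.sites["bird_id"].astype(str)
        self.bird_of = birds.to_numpy()
        self.trip_of = self.sites["trip_id"].astype(str).to_numpy()
        self.bird_sites: dict[str, np.ndarray] = {
            b: np.flatnonzero(birds.to_numpy() == b) for b in birds.unique()}
        if len(self.bird_sites) < 2:
            raise ValueError("colony needs >= 2 birds with sites for pairing")
        # focal birds: more than one trip with sites
        self.focal_birds = [b for b, idx in self.bird_sites.items()
                            if len(np.unique(self.trip_of[idx])) >= 2]
        # within-pair candidates per focal site
        self.focal_sites: list[int] = []
        self.within_cands: list[np.ndarray] = []
        for b in self.focal_birds:
            for f in self.bird_sites[b]:
                cands = self.bird_sites[b][self.trip_of[self.bird_sites[b]]
                                           != self.trip_of[f]]
                if len(cands) > 0:
                    self.focal_sites.append(int(f))
                    self.within_cands.append(cands)
        self.other_birds: list[list[str]] = [
            [b for b in self.bird_sites if b != self.bird_of[f]]
            for f in self.focal_sites]


def _stage_groups(sites: pd.DataFrame, stage: str) -> list[_ColonyGroup]:
    sub = sites[sites["stage"] == stage]
    return [_ColonyGroup(g) for _, g in sub.groupby("colony_id", sort=True)]


# ---------------------------------------------------------------------------
# single-draw operations

def draw_pairs(sites: pd.DataFrame, focal_site_id: str, rng: np.random.Generator,
               iteration: int = 0) -> PairDraw:
    """One random pairing for one focal site.

    The within-individual site is drawn uniformly from the focal bird's sites
    on other trips; one site is drawn uniformly from each other bird of the
    focal site's colony and stage.
    """
    focal = sites.loc[sites["site_id"] == focal_site_id].iloc[0]
    group = sites[(sites["colony_id"] == focal["colony_id"]) &
                  (sites["stage"] == focal["stage"])]
    mine = group[group["bird_id"] == focal["bird_id"]]
    if mine["trip_id"].nunique() < 2:
        raise ValueError(f"bird {focal['bird_id']} has sites on a single trip; "
                         "not eligible as focal")
    if group["bird_id"].nunique() < 2:
        raise ValueError("colony has fewer than 2 birds with sites")
    cands = mine[mine["trip_id"] != focal["trip_id"]]
    within = cands.iloc[int(rng.integers(len(cands)))]
    between = {}
    for b, g in group[group["bird_id"] != focal["bird_id"]].groupby("bird_id", sort=True):
        between[str(b)] = str(g.iloc[int(rng.integers(len(g)))]["site_id"])
    return PairDraw(focal_site_id=str(focal_site_id),
                    within_site_id=str(within["site_id"]),
                    between_site_ids=between, iteration=iteration)


def similarity_outcomes(pair: PairDraw, sites: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Bernoulli outcomes for one pair draw, plus the time-difference covariate.

    Outcome 1 means the bird's own within-individual paired site is strictly
    closer to the focal site than the other bird's site (high fidelity); ties
    score 0. The covariate is |days| between the focal and within sites.
    """
    tab = sites.set_index("site_id")
    f = tab.loc[pair.focal_site_id]
    w = tab.loc[pair.within_site_id]
    d_within = float(haversine_m(f["lat_c"], f["lon_c"], w["lat_c"], w["lon_c"]))
    outcomes = []
    for b_site in pair.between_site_ids.values():
        s = tab.loc[b_site]
        d_b = float(haversine_m(f["lat_c"], f["lon_c"], s["lat_c"], s["lon_c"]))
        outcomes.append(1 if d_within < d_b else 0)
    dt = abs((pd.to_datetime(f["t_mid"]) - pd.to_datetime(w["t_mid"]))
             / pd.Timedelta(days=1))
    return np.asarray(outcomes, dtype=int), float(dt)


# ---------------------------------------------------------------------------
# one full iteration (vectorised over focal sites)

def _iteration_rows(groups: list[_ColonyGroup], rng: np.random.Generator) -> pd.DataFrame:
    """Draw pairs for every focal site; returns per-focal-site outcome counts."""
    rows = []
    for g in groups:
        for k, f in enumerate(g.focal_sites):
            cands = g.within_cands[k]
            w = int(cands[rng.integers(len(cands))])
            d_within = g.dmat[f, w]
            succ = 0
            for b in g.other_birds[k]:
                idx = g.bird_sites[b]
                s = int(idx[rng.integers(len(idx))])
                if d_within < g.dmat[f, s]:
                    succ += 1
            rows.append({"bird_id": g.bird_of[f], "successes": succ,
                         "trials": len(g.other_birds[k]),
                         "time_diff_days": abs(g.t_days[f] - g.t_days[w])})
    return pd.DataFrame(rows)


def fidelity_iteration(sites: pd.DataFrame, rng: np.random.Generator,
                       stage: str | None = None,
                       include_time: bool = True, iteration: int = 0) -> pd.DataFrame:
    """Per-bird fidelity estimates from one randomization iteration."""
    if stage is None:
        stages = sites["stage"].unique()
        if len(stages) != 1:
            raise ValueError("pass stage= when sites span several breeding stages")
        stage = str(stages[0])
    groups = _stage_groups(sites, stage)
    rows = _iteration_rows(groups, rng)
    est = _estimate_from_rows(rows, include_time=include_time)
    est.insert(0, "stage", stage)
    est.insert(0, "iteration", iteration)
    return est


def _estimate_from_rows(rows: pd.DataFrame, include_time: bool) -> pd.DataFrame:
    agg = rows.groupby("bird_id", sort=True).agg(
        successes=("successes", "sum"), trials=("trials", "sum"))
    out = []
    separated = {}
    for b, r in agg.iterrows():
        m = int(r["trials"])
        if r["successes"] == 0 or r["successes"] == m:
            p_raw = r["successes"] / m
            if include_time:  # GLM cannot estimate a separated bird: clamp
                p_hat = min(max(p_raw, 1.0 / (2 * m)), 1.0 - 1.0 / (2 * m))
            else:
                p_hat = p_raw
            separated[b] = (p_hat, np.sqrt(max(p_hat * (1 - p_hat), 0.0) / m))
    if not include_time:
        for b, r in agg.iterrows():
            p = r["successes"] / r["trials"]
            out.append({"bird_id": b, "fidelity": float(p),
                        "se": float(np.sqrt(p * (1 - p) / r["trials"])),
                        "flagged": False})
        return pd.DataFrame(out)

    keep = rows[~rows["bird_id"].isin(separated)]
    glm_est: dict[str, tuple[float, float]] = {}
    if len(keep) > 0 and keep["bird_id"].nunique() > 0:
        dummies = pd.get_dummies(keep["bird_id"].astype(str))
        td = keep["time_diff_days"].to_numpy(dtype=float)
        X = np.column_stack([dummies.to_numpy(dtype=float), td - td.mean()])
        endog = np.column_stack([keep["successes"].to_numpy(dtype=float),
                                 (keep["trials"] - keep["successes"]).to_numpy(dtype=float)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        for j, b in enumerate(dummies.columns):
            p = float(expit(fit.params[j]))
            glm_est[b] = (p, float(fit.bse[j] * p * (1 - p)))
    for b in agg.index:
        if b in separated:
            p, se = separated[b]
            out.append({"bird_id": b, "fidelity": p, "se": se, "flagged": True})
        else:
            p, se = glm_est[b]
            out.append({"bird_id": b, "fidelity": p, "se": se, "flagged": False})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full randomization

def run_fidelity_randomization(sites: pd.DataFrame, n_iter: int = 1000,
                               seed: int = 0, stage: str | None = None,
                               include_time: bool = True) -> pd.DataFrame:
    """``n_iter`` independent randomization iterations for one breeding stage.

    Iteration i draws from its own RNG substream derived from (seed, i), so
    runs are reproducible and iterations independent. Returns the stacked
    per-iteration, per-bird estimates.
    """
    if stage is None:
        stages = sites["stage"].unique()
        if len(stages) != 1:
            raise ValueError("pass stage= when sites span several breeding stages")
        stage = str(stages[0])
    groups = _stage_groups(sites, stage)
    frames = []
    for i in range(n_iter):
        rng = np.random.default_rng([seed % (2 ** 31), i])
        rows = _iteration_rows(groups, rng)
        est = _estimate_from_rows(rows, include_time=include_time)
        est.insert(0, "stage", stage)
        est.insert(0, "iteration", i)
        frames.append(est)
    return pd.concat(frames, ignore_index=True)


def summarize_fidelity(estimates: pd.DataFrame) -> pd.DataFrame:
    """Per-bird mean and spread of fidelity across iterations."""
    return estimates.groupby(["stage", "bird_id"], sort=True).agg(
        fidelity_mean=("fidelity", "mean"),
        fidelity_sd=("fidelity", "std"),
        se_mean=("se", "mean"),
        n_iter=("iteration", "nunique")).reset_index()


def exact_fidelity_expectation(sites: pd.DataFrame, stage: str | None = None) -> pd.Series:
    """Exact per-bird expected fidelity by enumerating all possible pairings.

    Independent oracle for small configurations: averages the outcome
    indicator over every (within candidate, other-bird site) combination for
    every focal site. Matches the Monte-Carlo mean of the raw-proportion
    estimator (time covariate disabled).
    """
    if stage is None:
        stages = sites["stage"].unique()
        if len(stages) != 1:
            raise ValueError("pass stage= when sites span several breeding stages")
        stage = str(stages[0])
    groups = _stage_groups(sites, stage)
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for g in groups:
        for k, f in enumerate(g.focal_sites):
            b = g.bird_of[f]
            cands = g.within_cands[k]
            for other in g.other_birds[k]:
                idx = g.bird_sites[other]
                p = np.mean([(g.dmat[f, w] < g.dmat[f, s])
                             for w in cands for s in idx])
                num[b] = num.get(b, 0.0) + float(p)
                den[b] = den.get(b, 0.0) + 1.0
    return pd.Series({b: num[b] / den[b] for b in sorted(num)})


# ---------------------------------------------------------------------------
# boldness -> fidelity model over iterations

@dataclass
class FidelityModelResult:
    """Looped linear-model results across randomization iterations."""

    terms: dict                      # term -> {F_mean, df_num, df_den, p}
    coefficients: pd.DataFrame       # name, mean, ci_lo, ci_hi
    interactions_kept: list = field(default_factory=list)
    n_iter: int = 0


def _design(birds: pd.DataFrame, interactions: list[str]) -> tuple[np.ndarray, dict, list]:
    """Design matrix with named term -> column-index blocks."""
    n = len(birds)
    cols = [np.ones(n)]
    names = ["intercept"]
    terms: dict[str, list[int]] = {}

    def add(block: np.ndarray, block_names: list[str], term: str) -> None:
        start = len(names)
        for j in range(block.shape[1]):
            cols.append(block[:, j])
            names.append(block_names[j])
        terms[term] = list(range(start, len(names)))

    bold = birds["boldness"].to_numpy(dtype=float)[:, None]
    add(bold, ["boldness"], "boldness")
    sex_d = pd.get_dummies(birds["sex"].astype(str), prefix="sex", drop_first=True)
    if sex_d.shape[1] > 0:
        add(sex_d.to_numpy(dtype=float), list(sex_d.columns), "sex")
    col_d = pd.get_dummies(birds["colony_id"].astype(str), prefix="colony", drop_first=True)
    if col_d.shape[1] > 0:
        add(col_d.to_numpy(dtype=float), list(col_d.columns), "colony")
    date = birds["date"].to_numpy(dtype=float)
    add((date - date.mean())[:, None], ["date"], "date")
    if "boldness:sex" in interactions and sex_d.shape[1] > 0:
        add(bold * sex_d.to_numpy(dtype=float),
            [f"boldness:{c}" for c in sex_d.columns], "boldness:sex")
    if "boldness:colony" in interactions and col_d.shape[1] > 0:
        add(bold * col_d.to_numpy(dtype=float),
            [f"boldness:{c}" for c in col_d.columns], "boldness:colony")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"aliased covariates in fidelity model: {names}")
    return X, terms, names


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(res[0]) if len(res) else float(np.sum((y - X @ beta) ** 2))
    return beta, rss


def _term_f(X: np.ndarray, terms: dict, y: np.ndarray, term: str,
            beta_rss: tuple[np.ndarray, float] | None = None) -> tuple[float, int, int]:
    beta, rss_f = beta_rss if beta_rss is not None else _ols_rss(X, y)
    keep = [j for j in range(X.shape[1]) if j not in terms[term]]
    _, rss_r = _ols_rss(X[:, keep], y)
    df_num = len(terms[term])
    df_den = X.shape[0] - X.shape[1]
    if df_den <= 0 or rss_f <= 0:
        return np.nan, df_num, df_den
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return float(F), df_num, df_den


def boldness_fidelity_model(estimates: pd.DataFrame, birds: pd.DataFrame,
                            alpha: float = 0.05,
                            test_interactions: bool = True) -> FidelityModelResult:
    """Model fidelity against boldness, sex, colony and date across iterations.

    ``estimates`` holds one fidelity value per bird per iteration (one
    breeding stage); ``birds`` holds bird-level covariates (boldness, sex,
    colony_id, date as a number of days). The boldness x sex and boldness x
    colony interactions are screened on the iteration-mean fidelity and kept
    only when significant at ``alpha``. The model is then refitted to every
    iteration's estimates; coefficients are summarised by their mean and
    2.5% / 97.5% quantiles across iterations, and term significance by
    F-tests from comparisons of models with and without each term.
    """
    from scipy import stats

    birds = birds.copy()
    birds["bird_id"] = birds["bird_id"].astype(str)
    mean_fid = estimates.groupby("bird_id")["fidelity"].mean()
    birds = birds[birds["bird_id"].isin(mean_fid.index)].reset_index(drop=True)
    if birds["bird_id"].nunique() != len(birds):
        raise ValueError("one covariate row per bird required")
    y_mean = mean_fid.loc[birds["bird_id"]].to_numpy(dtype=float)

    kept: list[str] = []
    if test_interactions:
        for inter in ("boldness:sex", "boldness:colony"):
            try:
                X, terms, _ = _design(birds, [inter])
            except ValueError:
                continue
            if inter not in terms:
                continue
            F, dn, dd = _term_f(X, terms, y_mean, inter)
            if np.isfinite(F) and stats.f.sf(F, dn, dd) < alpha:
                kept.append(inter)
    X, terms, names = _design(birds, kept)

    wide = estimates.pivot_table(index="iteration", columns="bird_id",
                                 values="fidelity")[birds["bird_id"]]
    Y = wide.to_numpy(dtype=float)
    n_iter = Y.shape[0]
    betas = np.empty((n_iter, X.shape[1]))
    ses = np.empty((n_iter, X.shape[1]))
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    df_resid = X.shape[0] - X.shape[1]
    Fs = {t: np.empty(n_iter) for t in terms}
    dfs = {}
    for i in range(n_iter):
        y = Y[i]
        br = _ols_rss(X, y)
        betas[i] = br[0]
        ses[i] = np.sqrt(xtx_inv_diag * br[1] / max(df_resid, 1))
        for t in terms:
            F, dn, dd = _term_f(X, terms, y, t, beta_rss=br)
            Fs[t][i] = F
            dfs[t] = (dn, dd)
    coef = pd.DataFrame({
        "name": names,
        "mean": betas.mean(axis=0),
        "se_mean": ses.mean(axis=0),     # sampling SE from the model fits
        "ci_lo": np.quantile(betas, 0.025, axis=0),   # iteration range
        "ci_hi": np.quantile(betas, 0.975, axis=0)})
    term_res = {}
    for t in terms:
        F_mean = float(np.nanmean(Fs[t]))
        dn, dd = dfs[t]
        term_res[t] = {"F_mean": F_mean, "df_num": dn, "df_den": dd,
                       "p": float(stats.f.sf(F_mean, dn, dd))}
    return FidelityModelResult(terms=term_res, coefficients=coef,
                               interactions_kept=kept, n_iter=n_iter)
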