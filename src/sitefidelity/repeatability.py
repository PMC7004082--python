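"""Group-level trip repeatability and spatial-partitioning models.

Bold and shy birds are compared on the repeatability of log10 trip distance,
duration and maximum range. Repeatability per group uses the same
mixed-model variance-ratio estimator as the boldness analysis, with
parametric-bootstrap 84% and 95% intervals; two groups are declared
different when their 84% intervals fail to overlap, which for normal
estimates is equivalent to a z test at the 0.05 level.

Spatial partitioning is probed by linear mixed models of foraging-site
central latitude (log2) and longitude (square root) on boldness, sex,
colony and date, with random intercepts for trip nested within bird, and
likelihood-ratio tests per fixed term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .personality import adjusted_repeatability

log = logging.getLogger(__name__)

METRIC_COLUMNS = {"distance": "distance_km", "duration": "duration_hr",
                  "max_range": "max_range_km"}


@dataclass
class GroupRepeatability:
    group: str
    metric: str
    R: float
    ci84: tuple[float, float]
    ci95: tuple[float, float]
    n_birds: int
    n_trips: int


def group_repeatability(trip_table: pd.DataFrame, n_boot: int = 1000,
                        seed: int = 0,
                        metrics: tuple[str, ...] = ("distance", "duration", "max_range"),
                        ) -> list[GroupRepeatability]:
    """Repeatability of log10 trip metrics for each bold/shy group.

    ``trip_table`` has one row per trip with columns bird_id, group and the
    metric columns (distance_km, duration_hr, max_range_km); rows with a
    missing metric (e.g. incomplete trips) are dropped per metric.
    """
    out = []
    for gi, (group, gtab) in enumerate(sorted(trip_table.groupby("group"))):
        for mi, metric in enumerate(metrics):
            col = METRIC_COLUMNS[metric]
            sub = gtab.dropna(subset=[col])
            vals = np.log10(sub[col].to_numpy(dtype=float))
            counts = sub["bird_id"].value_counts()
            if (counts >= 2).sum() < 2:
                raise ValueError(f"group '{group}' has no repeated measures for {metric}")
            res = adjusted_repeatability(vals, sub["bird_id"], covariates=None,
                                         n_boot=n_boot, seed=seed + 7919 * gi + 104729 * mi,
                                         ci_levels=(0.84, 0.95))
            out.append(GroupRepeatability(group=group, metric=metric, R=res.R,
                                          ci84=res.ci84, ci95=res.ci95,
                                          n_birds=int(sub["bird_id"].nunique()),
                                          n_trips=int(len(sub))))
    return out


def ci_overlap_test(a, b) -> str:
    """'different' iff the two 84% intervals are disjoint (shared endpoint overlaps)."""
    a_ci = a.ci84 if hasattr(a, "ci84") else tuple(a)
    b_ci = b.ci84 if hasattr(b, "ci84") else tuple(b)
    if a_ci[1] < b_ci[0] or b_ci[1] < a_ci[0]:
        return "different"
    return "not_different"


def overlap_type1_rate(n_rep: int = 100_000, level: float = 0.84,
                       seed: int = 0) -> float:
    """Monte-Carlo type-I error of the interval-overlap rule.

    Simulates pairs of independent normal estimates with equal true means and
    equal known standard errors, builds ``level`` normal confidence intervals
    (mean +/- z * se) and returns the fraction of pairs whose intervals are
    disjoint. For 84% intervals this sits just under the nominal 0.05.
    """
    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(0.5 + level / 2.0)
    x1 = rng.standard_normal(n_rep)
    x2 = rng.standard_normal(n_rep)
    return float(np.mean(np.abs(x1 - x2) > 2.0 * z))


# ---------------------------------------------------------------------------
# spatial partitioning LMMs

@dataclass
class SpatialModelResult:
    response: str
    transform: str
    coefficients: pd.DataFrame         # name, estimate, se
    lrt: dict = field(default_factory=dict)  # term -> {chi2, df, p}
    var_bird: float = np.nan
    var_trip: float = np.nan
    var_resid: float = np.nan
    interactions_kept: list = field(default_factory=list)
    longitude_offset: float = 0.0


class _OLSFit:
    """Adapter giving an OLS fit the slice of the MixedLM interface we use."""

    def __init__(self, fit):
        self.llf = fit.llf
        self.fe_params = fit.params
        self.bse_fe = fit.bse
        self.scale = float(fit.scale)
        self.cov_re = np.array([[0.0]])
        self.vcomp = []


def _fit_lmm(data: pd.DataFrame, fixed: str, reml: bool):
    # the trip-within-bird component is identifiable only if some trip has
    # several sites and some bird several trips; the bird intercept only if
    # some bird has several sites — degenerate hierarchies reduce to OLS
    use_vc = (data.groupby("trip_id").size().max() > 1 and
              data.groupby("bird_id")["trip_id"].nunique().max() > 1)
    use_re = data.groupby("bird_id").size().max() > 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not use_re:
            return _OLSFit(smf.ols(f"y ~ {fixed}", data=data).fit())
        vc = {"trip": "0 + C(trip_id)"} if use_vc else None
        md = smf.mixedlm(f"y ~ {fixed}", data=data, groups=data["bird_id"],
                         re_formula="1", vc_formula=vc)
        return md.fit(reml=reml)


def _lrt(data: pd.DataFrame, full: str, reduced: str, df: int) -> dict:
    llf_f = _fit_lmm(data, full, reml=False).llf
    llf_r = _fit_lmm(data, reduced, reml=False).llf
    chi2 = max(2.0 * (llf_f - llf_r), 0.0)
    return {"chi2": float(chi2), "df": df, "p": float(stats.chi2.sf(chi2, df))}


def spatial_partition_models(sites: pd.DataFrame, birds: pd.DataFrame,
                             alpha: float = 0.05,
                             test_interactions: bool = True) -> list[SpatialModelResult]:
    """LMMs of transformed site latitude and longitude per breeding stage input.

    ``sites`` has one row per foraging site (bird_id, trip_id, colony_id,
    lat_c, lon_c); ``birds`` carries boldness, sex and date per bird. The
    latitude response is log2-transformed and the longitude square-root
    transformed; negative longitudes get an automatic +360 offset (logged)
    so the square root is defined. Interactions boldness x sex and boldness x
    colony are tested first and dropped when non-significant.
    """
    df = sites.merge(birds[["bird_id", "boldness", "sex", "date"]], on="bird_id",
                     validate="many_to_one")
    df = df.copy()
    df["date"] = df["date"].astype(float) - float(df["date"].astype(float).mean())
    results = []
    for response, transform in (("latitude", "log2"), ("longitude", "sqrt")):
        d = df.copy()
        offset = 0.0
        if response == "latitude":
            if (d["lat_c"] <= 0).any():
                raise ValueError("log2 latitude transform requires positive latitudes")
            d["y"] = np.log2(d["lat_c"])
        else:
            if (d["lon_c"] < 0).any():
                offset = 360.0
                log.info("negative longitudes: applying +360 offset before sqrt")
            d["y"] = np.sqrt(d["lon_c"] + offset)

        n_colonies = d["colony_id"].nunique()
        base_terms = ["boldness", "C(sex)"] + \
            (["C(colony_id)"] if n_colonies > 1 else []) + ["date"]
        base = " + ".join(base_terms)
        kept = []
        lrt: dict = {}
        if test_interactions:
            for inter, df_i in (("boldness:C(sex)", max(d["sex"].nunique() - 1, 1)),
                                ("boldness:C(colony_id)", max(n_colonies - 1, 1))):
                if "colony" in inter and n_colonies < 2:
                    continue
                try:
                    res = _lrt(d, f"{base} + {inter}", base, df_i)
                except Exception as e:  # singular fits on degenerate designs
                    log.warning("interaction LRT failed (%s): %s", inter, e)
                    continue
                lrt[inter] = res
                if res["p"] < alpha:
                    kept.append(inter)
        fixed = " + ".join([base] + kept)
        fit = _fit_lmm(d, fixed, reml=True)
        fe = fit.fe_params
        coef = pd.DataFrame({"name": fe.index, "estimate": fe.to_numpy(),
                             "se": fit.bse_fe.to_numpy()})
        term_df = {"boldness": 1, "C(sex)": max(d["sex"].nunique() - 1, 1),
                   "date": 1}
        if n_colonies > 1:
            term_df["C(colony_id)"] = n_colonies - 1
        for term, k in term_df.items():
            others = [t for t in base_terms if t != term] + kept
            lrt[term.replace("C(", "").replace(")", "").replace("_id", "")] = \
                _lrt(d, fixed, " + ".join(others) if others else "1", k)
        results.append(SpatialModelResult(
            response=response,
            transform=transform if response == "latitude" else
            ("sqrt" if offset == 0 else "sqrt(+360)"),
            coefficients=coef, lrt=lrt,
            var_bird=float(np.asarray(fit.cov_re)[0, 0]),
            var_trip=float(list(fit.vcomp)[0]) if len(fit.vcomp) else np.nan,
            var_resid=float(fit.scale),
            interactions_kept=kept, longitude_offset=offset))
    return results
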