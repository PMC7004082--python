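"""End-to-end pipeline: files in, report out.

Stages (each a pure function of inputs, config and seed, writing delimited
text and JSON under the working directory):

simulate -> segment -> hmm-fit -> decode -> sites -> personality ->
fidelity -> repeatability -> spatial -> report

The report reconciles bookkeeping: every segmented trip is either kept or
dropped with a reason (below minimum duration at segmentation; no decoded
foraging state, i.e. no evidence of area-restricted search, after decoding).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import fidelity as fid
from . import hmm as hm
from . import personality as pers
from . import repeatability as rep
from . import synthetic as syn
from . import tracks as trk

log = logging.getLogger(__name__)

FIXES_SCHEMA = ["bird_id", "colony_id", "stage", "t", "lat", "lon"]
COLONY_SCHEMA = ["colony_id", "lat", "lon"]
PERSONALITY_SCHEMA = ["bird_id", "date", "stage", "observer", "test_number",
                      *pers.BEHAVIOUR_COLS]


class PipelineError(RuntimeError):
    def __init__(self, code: str, message: str):
        super().__init__(f"[{code}] {message}")
        self.code = code


@dataclass
class PipelineConfig:
    workdir: str = "results/pipeline"
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    buffer_m: float = 300.0
    min_trip_hr: float = 1.0
    interp_minutes: dict = field(default_factory=lambda: {"incubation": 10.0,
                                                          "chick_rearing": 2.0})
    hmm_n_states: int = 3
    hmm_n_restarts: int = 2
    hmm_maxiter: int = 300
    fidelity_n_iter: int = 1000
    n_boot: int = 1000

    def validate(self) -> None:
        for name in ("buffer_m", "min_trip_hr", "hmm_n_states", "hmm_n_restarts",
                     "hmm_maxiter", "fidelity_n_iter", "n_boot"):
            if not getattr(self, name) > 0:
                raise PipelineError("config", f"{name} must be positive")
        if self.seed is None:
            raise PipelineError("config", "seed must be set; unseeded runs are "
                                "not reproducible")

    @property
    def datadir(self) -> Path:
        return Path(self.workdir) / "data"

    @property
    def outdir(self) -> Path:
        return Path(self.workdir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError("config", f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PipelineError("schema", f"{name} is missing columns {missing}")


def _sim_config(cfg: PipelineConfig) -> syn.SimConfig:
    return syn.SimConfig(rng_seed=cfg.seed, **cfg.sim)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> dict:
    truth = syn.write_dataset(_sim_config(cfg), cfg.datadir)
    return {"n_birds": len(truth["birds"])}


def _read_fixes(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    fixes = pd.read_csv(cfg.datadir / "fixes.csv", parse_dates=["t"])
    _require_columns(fixes, FIXES_SCHEMA, "fixes.csv")
    colonies = pd.read_csv(cfg.datadir / "colonies.csv")
    _require_columns(colonies, COLONY_SCHEMA, "colonies.csv")
    cmap = {str(r["colony_id"]): (float(r["lat"]), float(r["lon"]))
            for _, r in colonies.iterrows()}
    missing = set(fixes["colony_id"].astype(str)) - set(cmap)
    if missing:
        raise PipelineError("missing_colony",
                            f"no coordinates for colonies {sorted(missing)}")
    return fixes, cmap


def stage_segment(cfg: PipelineConfig) -> dict:
    """Segment, interpolate and summarise trips; writes trips.csv, trip_fixes.csv."""
    fixes, cmap = _read_fixes(cfg)
    trips: list[trk.Trip] = []
    dropped_frames = []
    for (bird_id, stage), g in fixes.groupby(["bird_id", "stage"], sort=True):
        colony_id = str(g["colony_id"].iloc[0])
        colony = cmap[colony_id]
        t, d = trk.segment_trips(g, colony, buffer_m=cfg.buffer_m,
                                 min_duration_hr=cfg.min_trip_hr,
                                 bird_id=str(bird_id), stage=str(stage),
                                 colony_id=colony_id, with_dropped=True)
        trips += t
        dropped_frames.append(d)
    dropped = pd.concat(dropped_frames, ignore_index=True) if dropped_frames \
        else trk._empty_dropped()
    rows, fix_rows = [], []
    for trip in trips:
        interval = float(cfg.interp_minutes.get(trip.stage, 10.0))
        itrip = trk.interpolate_trip(trip, interval)
        colony = cmap[trip.colony_id]
        m = trk.trip_metrics(itrip, colony)
        rows.append({"trip_id": trip.trip_id, "bird_id": trip.bird_id,
                     "colony_id": trip.colony_id, "stage": trip.stage,
                     "start": itrip.fixes["t"].iloc[0], "end": itrip.fixes["t"].iloc[-1],
                     "complete": trip.complete, "n_fixes": itrip.n_fixes,
                     "distance_km": m.distance_km, "duration_hr": m.duration_hr,
                     "max_range_km": m.max_range_km})
        ff = itrip.fixes.copy()
        ff.insert(0, "trip_id", trip.trip_id)
        ff.insert(1, "bird_id", trip.bird_id)
        ff.insert(2, "colony_id", trip.colony_id)
        ff.insert(3, "stage", trip.stage)
        fix_rows.append(ff)
    trips_df = pd.DataFrame(rows)
    trips_df.to_csv(cfg.outdir / "trips.csv", index=False)
    if fix_rows:
        pd.concat(fix_rows, ignore_index=True).to_csv(
            cfg.outdir / "trip_fixes.csv", index=False)
    dropped.to_csv(cfg.outdir / "dropped_excursions.csv", index=False)
    return {"trips_segmented": int(len(trips_df)),
            "excursions_below_min_duration": int(len(dropped))}


def _trip_obs(cfg: PipelineConfig) -> tuple[dict, pd.DataFrame]:
    tf = pd.read_csv(cfg.outdir / "trip_fixes.csv", parse_dates=["t"])
    trips_df = pd.read_csv(cfg.outdir / "trips.csv", parse_dates=["start", "end"])
    obs = {}
    for trip_id, g in tf.groupby("trip_id", sort=True):
        trip = trk.Trip(trip_id=str(trip_id), bird_id=str(g["bird_id"].iloc[0]),
                        fixes=g[["t", "lat", "lon"]].reset_index(drop=True),
                        complete=True, stage=str(g["stage"].iloc[0]),
                        colony_id=str(g["colony_id"].iloc[0]))
        obs[str(trip_id)] = (trip, trk.steps_and_angles(trip))
    return obs, trips_df


def stage_hmm_fit(cfg: PipelineConfig) -> dict:
    """One HMM per breeding stage (stages have different fix intervals)."""
    obs, trips_df = _trip_obs(cfg)
    models = {}
    for stage in sorted(trips_df["stage"].unique()):
        ids = trips_df.loc[trips_df["stage"] == stage, "trip_id"].astype(str)
        seqs = [obs[i][1] for i in ids if len(obs[i][1]) > 0]
        if not seqs:
            raise PipelineError("empty_stage", f"no observations for stage {stage}")
        interval = float(cfg.interp_minutes.get(stage, 10.0))
        f = hm.fit_hmm(seqs, n_states=cfg.hmm_n_states,
                       n_restarts=cfg.hmm_n_restarts, seed=cfg.seed,
                       maxiter=cfg.hmm_maxiter, interval_min=interval)
        models[stage] = {"model": f.model.to_dict(), "loglik": f.loglik,
                         "aic": f.aic, "n_obs": f.n_obs,
                         "labels": {str(k): v for k, v in
                                    hm.label_states(f.model).items()}}
    (cfg.outdir / "hmm.json").write_text(json.dumps(models, indent=1, sort_keys=True))
    return {"hmm_loglik": {s: models[s]["loglik"] for s in models}}


def stage_decode(cfg: PipelineConfig) -> dict:
    obs, trips_df = _trip_obs(cfg)
    models = json.loads((cfg.outdir / "hmm.json").read_text())
    rows = []
    for trip_id, (trip, sa) in sorted(obs.items()):
        m = hm.MovementHMM.from_dict(models[trip.stage]["model"])
        labels = {int(k): v for k, v in models[trip.stage]["labels"].items()}
        states = hm.viterbi(m, sa)
        for i, s in enumerate(states):
            rows.append({"trip_id": trip_id, "index": i, "state": int(s),
                         "label": labels[int(s)]})
    pd.DataFrame(rows).to_csv(cfg.outdir / "states.csv", index=False)
    return {"n_decoded_steps": len(rows)}


def stage_sites(cfg: PipelineConfig) -> dict:
    """Aggregate foraging runs into sites; drop trips with no foraging state."""
    obs, trips_df = _trip_obs(cfg)
    models = json.loads((cfg.outdir / "hmm.json").read_text())
    states_df = pd.read_csv(cfg.outdir / "states.csv")
    site_frames, no_ars = [], []
    for trip_id, (trip, sa) in sorted(obs.items()):
        labels = {int(k): v for k, v in models[trip.stage]["labels"].items()}
        st = states_df.loc[states_df["trip_id"] == trip_id].sort_values("index")
        sites = hm.extract_sites(trip, st["state"].to_numpy(), labels)
        if len(sites) == 0:
            no_ars.append(trip_id)
        else:
            site_frames.append(sites)
    sites_df = pd.concat(site_frames, ignore_index=True) if site_frames else \
        pd.DataFrame(columns=["site_id", "bird_id", "trip_id", "colony_id",
                              "stage", "lat_c", "lon_c", "t_mid", "n_fixes"])
    sites_df.to_csv(cfg.outdir / "sites.csv", index=False)
    kept = trips_df[~trips_df["trip_id"].isin(no_ars)]
    kept.to_csv(cfg.outdir / "trips_kept.csv", index=False)
    return {"trips_no_ars": int(len(no_ars)), "trips_kept": int(len(kept)),
            "n_sites": int(len(sites_df))}


def stage_personality(cfg: PipelineConfig) -> dict:
    tests = pd.read_csv(cfg.datadir / "personality.csv", parse_dates=["date"])
    _require_columns(tests, PERSONALITY_SCHEMA, "personality.csv")
    pca = pers.pca_boldness(tests)
    cov = pd.DataFrame({
        "date": (tests["date"] - tests["date"].min()) / pd.Timedelta(days=1),
        "test_number": tests["test_number"].astype(float)})
    for c in ("stage", "observer"):
        if tests[c].nunique() > 1:
            cov[c] = tests[c].astype(str)
    res = pers.adjusted_repeatability(pca.pc1_scores, tests["bird_id"], cov,
                                      n_boot=cfg.n_boot, seed=cfg.seed,
                                      ci_levels=(0.95,))
    boldness = pers.individual_boldness(pca.pc1_scores, tests["bird_id"], cov)
    boldness = pers.classify_bold_shy(boldness)
    boldness.to_csv(cfg.outdir / "boldness.csv", index=False)
    report = {"pc1_variance_explained": float(pca.variance_explained[0]),
              "repeatability": {"R": res.R, "ci95": list(res.ci95), "p": res.p},
              "n_bold": int((boldness["group"] == "bold").sum()),
              "n_shy": int((boldness["group"] == "shy").sum())}
    (cfg.outdir / "personality_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return report


def _bird_covariates(cfg: PipelineConfig, boldness: pd.DataFrame) -> pd.DataFrame:
    birds = pd.read_csv(cfg.datadir / "birds.csv", parse_dates=["deploy_date"])
    birds["date"] = (birds["deploy_date"] - birds["deploy_date"].min()) / \
        pd.Timedelta(days=1)
    return birds.merge(boldness[["bird_id", "boldness", "group"]], on="bird_id")


def stage_fidelity(cfg: PipelineConfig) -> dict:
    sites = pd.read_csv(cfg.outdir / "sites.csv", parse_dates=["t_mid"])
    boldness = pd.read_csv(cfg.outdir / "boldness.csv")
    birds = _bird_covariates(cfg, boldness)
    out = {}
    est_frames, sum_frames = [], []
    for stage in sorted(sites["stage"].unique()):
        est = fid.run_fidelity_randomization(sites, n_iter=cfg.fidelity_n_iter,
                                             seed=cfg.seed, stage=stage)
        est_frames.append(est)
        sum_frames.append(fid.summarize_fidelity(est))
        model = fid.boldness_fidelity_model(est, birds)
        out[stage] = {
            "terms": model.terms,
            "coefficients": model.coefficients.to_dict(orient="list"),
            "interactions_kept": model.interactions_kept,
            "n_iter": model.n_iter}
    pd.concat(est_frames, ignore_index=True).to_csv(
        cfg.outdir / "fidelity_estimates.csv", index=False)
    pd.concat(sum_frames, ignore_index=True).to_csv(
        cfg.outdir / "fidelity_summary.csv", index=False)
    (cfg.outdir / "fidelity_models.json").write_text(
        json.dumps(out, indent=1, sort_keys=True))
    return out


def stage_repeatability(cfg: PipelineConfig) -> dict:
    trips = pd.read_csv(cfg.outdir / "trips_kept.csv")
    boldness = pd.read_csv(cfg.outdir / "boldness.csv")
    trips = trips.merge(boldness[["bird_id", "group"]], on="bird_id")
    rows, overlap = [], {}
    for stage in sorted(trips["stage"].unique()):
        res = rep.group_repeatability(trips[trips["stage"] == stage],
                                      n_boot=cfg.n_boot, seed=cfg.seed)
        by = {(r.group, r.metric): r for r in res}
        for r in res:
            rows.append({"stage": stage, "group": r.group, "metric": r.metric,
                         "R": r.R, "ci84_lo": r.ci84[0], "ci84_hi": r.ci84[1],
                         "ci95_lo": r.ci95[0], "ci95_hi": r.ci95[1],
                         "n_birds": r.n_birds, "n_trips": r.n_trips})
        for metric in ("distance", "duration", "max_range"):
            if ("bold", metric) in by and ("shy", metric) in by:
                overlap[f"{stage}:{metric}"] = rep.ci_overlap_test(
                    by[("bold", metric)], by[("shy", metric)])
    pd.DataFrame(rows).to_csv(cfg.outdir / "repeatability.csv", index=False)
    return {"overlap_tests": overlap}


def stage_spatial(cfg: PipelineConfig) -> dict:
    sites = pd.read_csv(cfg.outdir / "sites.csv", parse_dates=["t_mid"])
    boldness = pd.read_csv(cfg.outdir / "boldness.csv")
    birds = _bird_covariates(cfg, boldness)
    out = {}
    for stage in sorted(sites["stage"].unique()):
        res = rep.spatial_partition_models(sites[sites["stage"] == stage], birds)
        out[stage] = {r.response: {
            "transform": r.transform,
            "coefficients": r.coefficients.to_dict(orient="list"),
            "lrt": r.lrt, "var_bird": r.var_bird, "var_trip": r.var_trip,
            "var_resid": r.var_resid,
            "interactions_kept": r.interactions_kept} for r in res}
    (cfg.outdir / "spatial_models.json").write_text(
        json.dumps(out, indent=1, sort_keys=True))
    return out


STAGES = ("simulate", "segment", "hmm_fit", "decode", "sites", "personality",
          "fidelity", "repeatability", "spatial")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write report.json; returns the report dict."""
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    stage_fns = {"simulate": stage_simulate, "segment": stage_segment,
                 "hmm_fit": stage_hmm_fit, "decode": stage_decode,
                 "sites": stage_sites, "personality": stage_personality,
                 "fidelity": stage_fidelity, "repeatability": stage_repeatability,
                 "spatial": stage_spatial}
    for name in STAGES:
        if name == "simulate" and not cfg.simulate:
            continue
        log.info("pipeline stage=%s seed=%s", name, cfg.seed)
        report["stages"][name] = stage_fns[name](cfg)
    seg = report["stages"]["segment"]
    sit = report["stages"]["sites"]
    report["counts"] = {
        "excursions_below_min_duration": seg["excursions_below_min_duration"],
        "trips_segmented": seg["trips_segmented"],
        "dropped_no_ars": sit["trips_no_ars"],
        "trips_kept": sit["trips_kept"],
    }
    assert report["counts"]["trips_segmented"] == \
        report["counts"]["trips_kept"] + report["counts"]["dropped_no_ars"]
    (cfg.outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return report
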