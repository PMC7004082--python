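"""Synthetic study data with known ground truth.

Emulates the sampling design of a multi-colony GPS-tracking study of a
central-place foraging seabird: each bird makes repeated foraging trips from
its colony, travelling out to a target site, dwelling there in a
foraging/resting mixture, and returning. Trip targets implement planted site
fidelity: with per-bird probability ``fidelity_level`` a trip revisits the
bird's preferred site, otherwise a fresh site is drawn uniformly in a
5-60 km annulus around the colony. Step lengths are drawn from the true
HMM's state gamma distributions and dwell headings evolve by the state's von
Mises turning angles, so the downstream model fit has a known answer.

Novel-object tests are generated from a latent per-bird boldness value whose
between-bird variance share equals the configured repeatability; each test's
five behaviour proportions are a softmax of a sitting-to-leaving gradient in
the latent test score, so the first principal component recovers boldness.

Positions are propagated on a local tangent plane around each colony and
converted to latitude/longitude, adequate below ~300 km ranges. All
randomness flows from one seeded generator per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geo import enu_to_latlon
from .hmm import MovementHMM

# state order of the generating model
TRAVEL, FORAGE, REST = 0, 1, 2

DEFAULT_COLONIES = [
    ("C1", 78.99, 12.12),
    ("C2", 78.88, 12.18),
    ("C3", 78.93, 12.27),
    ("C4", 78.17, 15.08),
]

# softmax gradient from sitting (bold) to off-ledge (shy) and baseline mix
_BEHAVIOUR_GRADIENT = np.array([0.5, 0.25, 0.0, -0.25, -0.5])
_BEHAVIOUR_BASELINE = np.array([0.6, 0.1, -0.1, -0.4, -0.8])


def default_true_hmm(fix_interval_min: float = 10.0) -> MovementHMM:
    """Well-separated 3-state truth; step scale proportional to fix interval."""
    s = fix_interval_min / 10.0
    return MovementHMM(
        step_mean=np.array([3000.0, 300.0, 60.0]) * s,
        step_sd=np.array([1500.0, 250.0, 50.0]) * s,
        angle_mean=np.array([0.0, np.pi, 0.0]),
        angle_kappa=np.array([8.0, 1.5, 0.3]),
        tpm=np.array([[0.92, 0.05, 0.03],
                      [0.06, 0.90, 0.04],
                      [0.05, 0.10, 0.85]]),
        delta=np.array([1.0, 0.0, 0.0]),
    )


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``fidelity_levels`` / ``boldness_means`` may be set explicitly (scalar or
    one value per bird); by default fidelity is tied to latent boldness as
    clip(fidelity_base + boldness_fidelity_slope * boldness, 0.02, 0.98) and
    boldness is drawn with between-bird SD sqrt(R) * boldness_sd_total.
    """

    colony_coords: list = field(default_factory=lambda: list(DEFAULT_COLONIES))
    n_birds_per_colony: int = 12
    n_trips_per_bird: int = 3
    stage: str = "incubation"
    fix_interval_min: float | None = None     # default: 10 incubation, 2 chick_rearing
    true_hmm: MovementHMM | None = None
    fidelity_base: float = 0.6
    boldness_fidelity_slope: float = 0.086
    fidelity_levels: object = None            # scalar or per-bird array override
    boldness_means: object = None             # per-bird array override
    boldness_sd_total: float = 1.0
    boldness_repeatability: float = 0.678
    site_annulus_km: tuple[float, float] = (5.0, 60.0)
    site_scatter_m: float = 1200.0
    dwell_steps: tuple[int, int] = (20, 40)
    colony_gap_fixes: int = 3
    rng_seed: int = 0

    @property
    def n_colonies(self) -> int:
        return len(self.colony_coords)

    @property
    def interval_min(self) -> float:
        if self.fix_interval_min is not None:
            return float(self.fix_interval_min)
        return 10.0 if self.stage == "incubation" else 2.0

    def validate(self) -> None:
        if self.n_birds_per_colony < 0 or self.n_trips_per_bird < 0:
            raise ValueError("counts must be >= 0")
        for c in self.colony_coords:
            _, lat, lon = c
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid colony coordinates {c}")
        if not (0.0 <= self.boldness_repeatability <= 1.0):
            raise ValueError("boldness_repeatability must be in [0, 1]")
        if self.stage not in ("incubation", "chick_rearing"):
            raise ValueError("stage must be incubation or chick_rearing")
        hmm = self.hmm
        if not np.allclose(hmm.tpm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("true HMM transition matrix must be row-stochastic")

    @property
    def hmm(self) -> MovementHMM:
        return self.true_hmm if self.true_hmm is not None else \
            default_true_hmm(self.interval_min)


def _per_bird(value, n: int, default: np.ndarray) -> np.ndarray:
    if value is None:
        return default
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
    return arr


def make_birds(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Bird-level truth: colony, sex, latent boldness, fidelity, preferred site."""
    config.validate()
    rows = []
    n_total = config.n_colonies * config.n_birds_per_colony
    sd_b = np.sqrt(config.boldness_repeatability) * config.boldness_sd_total
    latent = rng.normal(0.0, sd_b, size=n_total) if sd_b > 0 else np.zeros(n_total)
    latent = _per_bird(config.boldness_means, n_total, latent)
    fid = np.clip(config.fidelity_base + config.boldness_fidelity_slope * latent,
                  0.02, 0.98)
    fid = np.clip(_per_bird(config.fidelity_levels, n_total, fid), 0.0, 1.0)
    base_date = pd.Timestamp("2017-06-15" if config.stage == "incubation"
                             else "2017-07-10")
    k = 0
    for (colony_id, clat, clon) in config.colony_coords:
        for _ in range(config.n_birds_per_colony):
            pref = _annulus_point(config, rng)
            rows.append({
                "bird_id": f"{colony_id}_b{k:03d}", "colony_id": colony_id,
                "colony_lat": clat, "colony_lon": clon,
                "sex": str(rng.choice(["F", "M"])),
                "boldness_true": float(latent[k]),
                "fidelity_level": float(fid[k]),
                "pref_x": pref[0], "pref_y": pref[1],
                "deploy_date": base_date + pd.Timedelta(days=int(rng.integers(0, 10))),
            })
            k += 1
    return pd.DataFrame(rows)


def _annulus_point(config: SimConfig, rng: np.random.Generator) -> tuple[float, float]:
    r_lo, r_hi = (1000.0 * r for r in config.site_annulus_km)
    r = np.sqrt(rng.uniform(r_lo ** 2, r_hi ** 2))  # uniform by area
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return (r * np.sin(theta), r * np.cos(theta))


# ---------------------------------------------------------------------------
# GPS tracks

def simulate_tracks(config: SimConfig, rng: np.random.Generator | None = None,
                    birds: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the fix table for every bird.

    Returns (fixes, birds). Fixes carry a ``true_state`` column (-1 for
    at-colony fixes between trips) aligned so that a fix's state is the state
    of the step leaving it, matching the decoder's convention.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if birds is None:
        birds = make_birds(config, rng)
    hmm = config.hmm
    frames = []
    for _, bird in birds.iterrows():
        if config.n_trips_per_bird == 0:
            continue
        xs, ys, states = [], [], []
        for trip in range(config.n_trips_per_bird):
            if rng.uniform() < bird["fidelity_level"]:
                target = (bird["pref_x"], bird["pref_y"])
            else:
                target = _annulus_point(config, rng)
            txs, tys, tst = _one_trip(config, hmm, target, rng)
            xs += txs
            ys += tys
            states += tst
            # colony dwell between trips (inside the 300 m buffer)
            for _ in range(config.colony_gap_fixes):
                xs.append(float(rng.normal(0.0, 20.0)))
                ys.append(float(rng.normal(0.0, 20.0)))
                states.append(-1)
        lat, lon = enu_to_latlon(bird["colony_lat"], bird["colony_lon"],
                                 np.array(xs), np.array(ys))
        t0 = pd.Timestamp(bird["deploy_date"]) + pd.Timedelta(hours=6)
        t = t0 + pd.to_timedelta(np.arange(len(xs)) * config.interval_min, unit="m")
        frames.append(pd.DataFrame({
            "bird_id": bird["bird_id"], "colony_id": bird["colony_id"],
            "stage": config.stage, "t": t, "lat": lat, "lon": lon,
            "true_state": states}))
    if not frames:
        fixes = pd.DataFrame(columns=["bird_id", "colony_id", "stage", "t",
                                      "lat", "lon", "true_state"])
    else:
        fixes = pd.concat(frames, ignore_index=True)
    return fixes, birds


def _one_trip(config: SimConfig, hmm: MovementHMM, target: tuple[float, float],
              rng: np.random.Generator) -> tuple[list, list, list]:
    """One out-dwell-return trip in tangent-plane metres; starts/ends at (0,0)."""

    def gamma_step(state: int) -> float:
        m, s = hmm.step_mean[state], hmm.step_sd[state]
        return float(rng.gamma(m * m / (s * s), s * s / m))

    xs, ys, states = [0.0], [0.0], []
    x, y = 0.0, 0.0
    heading = np.arctan2(target[0] - x, target[1] - y)

    def advance(state: int, hd: float) -> None:
        nonlocal x, y
        step = gamma_step(state)
        x += step * np.sin(hd)
        y += step * np.cos(hd)
        xs.append(x)
        ys.append(y)
        states.append(state)

    # out-leg: directed travel toward the target
    guard = 0
    while np.hypot(target[0] - x, target[1] - y) > 1.5 * hmm.step_mean[TRAVEL]:
        heading = np.arctan2(target[0] - x, target[1] - y) + \
            rng.vonmises(0.0, hmm.angle_kappa[TRAVEL])
        advance(TRAVEL, heading)
        guard += 1
        if guard > 500:
            break
    # dwell: forage/rest sub-chain with von Mises turning
    sub = hmm.tpm[np.ix_([FORAGE, REST], [FORAGE, REST])]
    sub = sub / sub.sum(axis=1, keepdims=True)
    state = FORAGE
    for _ in range(int(rng.integers(config.dwell_steps[0], config.dwell_steps[1] + 1))):
        turn = rng.vonmises(hmm.angle_mean[state], max(hmm.angle_kappa[state], 1e-8))
        heading = heading - turn  # CCW-positive turning convention
        advance(state, heading)
        state = [FORAGE, REST][int(rng.choice(2, p=sub[[FORAGE, REST].index(state)]))]
    # return-leg
    guard = 0
    while np.hypot(x, y) > 1.5 * hmm.step_mean[TRAVEL]:
        heading = np.arctan2(-x, -y) + rng.vonmises(0.0, hmm.angle_kappa[TRAVEL])
        advance(TRAVEL, heading)
        guard += 1
        if guard > 500:
            break
    # closing step back to the exact colony position is not a gamma draw:
    # mark it -2 (boundary) so per-state step accounting stays exact
    xs.append(0.0)
    ys.append(0.0)
    states.append(-2)
    states.append(-2)  # final fix inherits the closing step's marker
    return xs, ys, states


# ---------------------------------------------------------------------------
# direct site-level generator (for fidelity analyses without track decoding)

def simulate_sites(config: SimConfig, rng: np.random.Generator | None = None,
                   birds: pd.DataFrame | None = None,
                   sites_per_trip: tuple[int, int] = (1, 2)) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Foraging sites drawn directly from the trip-target process.

    Bypasses track generation and decoding: each trip's sites scatter around
    its target with SD ``site_scatter_m``. Useful when only the similarity
    index and its models are under study.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if birds is None:
        birds = make_birds(config, rng)
    rows = []
    for _, bird in birds.iterrows():
        for trip in range(config.n_trips_per_bird):
            if rng.uniform() < bird["fidelity_level"]:
                target = (bird["pref_x"], bird["pref_y"])
            else:
                target = _annulus_point(config, rng)
            n_sites = int(rng.integers(sites_per_trip[0], sites_per_trip[1] + 1))
            for s in range(n_sites):
                x = target[0] + rng.normal(0.0, config.site_scatter_m)
                y = target[1] + rng.normal(0.0, config.site_scatter_m)
                lat, lon = enu_to_latlon(bird["colony_lat"], bird["colony_lon"], x, y)
                rows.append({
                    "site_id": f"{bird['bird_id']}_t{trip:02d}_s{s}",
                    "bird_id": bird["bird_id"], "trip_id": f"{bird['bird_id']}_t{trip:02d}",
                    "colony_id": bird["colony_id"], "stage": config.stage,
                    "lat_c": float(lat), "lon_c": float(lon),
                    "t_mid": pd.Timestamp(bird["deploy_date"]) +
                    pd.Timedelta(days=2 * trip, hours=6 + 3 * s),
                    "n_fixes": int(rng.integers(3, 12))})
    cols = ["site_id", "bird_id", "trip_id", "colony_id", "stage",
            "lat_c", "lon_c", "t_mid", "n_fixes"]
    return pd.DataFrame(rows, columns=cols), birds


# ---------------------------------------------------------------------------
# personality tests

def simulate_personality(config: SimConfig, rng: np.random.Generator | None = None,
                         birds: pd.DataFrame | None = None,
                         n_tests_probs: tuple = (0.60, 0.22, 0.11, 0.07),
                         logit_noise_sd: float = 0.05
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Novel-object tests: 1-4 per bird, five proportions summing to 1.

    The latent test score is the bird's boldness plus within-bird noise with
    variance (1 - R) * boldness_sd_total^2, shifted by small habituation
    (test number) and observer effects; proportions are a softmax along the
    sitting-to-leaving gradient, so they sum to 1 exactly and PC1 tracks the
    latent score monotonically.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if birds is None:
        birds = make_birds(config, rng)
    sd_w = np.sqrt(1.0 - config.boldness_repeatability) * config.boldness_sd_total
    observers = {c[0]: f"obs{1 + (i >= config.n_colonies / 2)}"
                 for i, c in enumerate(config.colony_coords)}
    rows = []
    for _, bird in birds.iterrows():
        n_tests = 1 + int(rng.choice(len(n_tests_probs), p=n_tests_probs))
        for k in range(n_tests):
            u = bird["boldness_true"] + rng.normal(0.0, sd_w) \
                - 0.05 * k + (0.1 if observers[bird["colony_id"]] == "obs2" else 0.0)
            logits = _BEHAVIOUR_BASELINE + _BEHAVIOUR_GRADIENT * u \
                + rng.normal(0.0, logit_noise_sd, size=5)
            p = np.exp(logits - logits.max())
            p /= p.sum()
            rows.append({
                "bird_id": bird["bird_id"], "colony_id": bird["colony_id"],
                "date": pd.Timestamp(bird["deploy_date"]) +
                pd.Timedelta(days=3 * k + int(rng.integers(0, 3))),
                "stage": config.stage, "observer": observers[bird["colony_id"]],
                "test_number": k + 1,
                "p_sit": p[0], "p_raised": p[1], "p_stand": p[2],
                "p_off_nest": p[3], "p_off_ledge": p[4]})
    cols = ["bird_id", "colony_id", "date", "stage", "observer", "test_number",
            "p_sit", "p_raised", "p_stand", "p_off_nest", "p_off_ledge"]
    return pd.DataFrame(rows, columns=cols), birds


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write fixes.csv, personality.csv, colonies.csv, birds.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    birds = make_birds(config, rng)
    fixes, _ = simulate_tracks(config, rng, birds)
    tests, _ = simulate_personality(config, rng, birds)
    fixes.drop(columns=["true_state"]).to_csv(outdir / "fixes.csv", index=False)
    tests.to_csv(outdir / "personality.csv", index=False)
    pd.DataFrame([{"colony_id": c[0], "lat": c[1], "lon": c[2]}
                  for c in config.colony_coords]).to_csv(outdir / "colonies.csv",
                                                         index=False)
    birds[["bird_id", "colony_id", "sex", "deploy_date"]].to_csv(
        outdir / "birds.csv", index=False)
    truth = {
        "hmm": config.hmm.to_dict(),
        "stage": config.stage,
        "fix_interval_min": config.interval_min,
        "boldness_repeatability": config.boldness_repeatability,
        "boldness_fidelity_slope": config.boldness_fidelity_slope,
        "birds": {r["bird_id"]: {"boldness_true": r["boldness_true"],
                                 "fidelity_level": r["fidelity_level"],
                                 "sex": r["sex"]}
                  for _, r in birds.iterrows()},
        "rng_seed": int(config.rng_seed),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth
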