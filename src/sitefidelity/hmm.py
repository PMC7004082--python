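"""3-state movement hidden Markov model.

Observed step lengths follow state-specific gamma distributions
(parameterised by mean m and standard deviation s, i.e. shape k = m^2/s^2 and
scale theta = s^2/m) and turning angles follow state-specific von Mises
distributions (mean direction mu, concentration kappa). Hidden states evolve
as a first-order Markov chain with initial distribution delta and transition
matrix Gamma. States are interpreted post hoc as travelling (long, directed
steps), foraging (short steps, reversed / diffuse headings: area-restricted
search) and resting (short drifting steps).

Fitting maximises the pooled forward-algorithm log-likelihood (each trip an
independent chain sharing parameters) by quasi-Newton optimisation on
unconstrained working parameters, with multi-start jitter. Decoding uses the
Viterbi algorithm. Zero step lengths are floored at 0.1 m so the gamma
density stays finite; the first angle of each trip is treated as missing and
contributes step density only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises

from .geo import wrap_angle

STEP_FLOOR_M = 0.1


@dataclass
class MovementHMM:
    """Parameters of an n-state step/turn HMM."""

    step_mean: np.ndarray   # (S,) gamma mean, metres
    step_sd: np.ndarray     # (S,) gamma sd, metres
    angle_mean: np.ndarray  # (S,) von Mises mean, radians in (-pi, pi]
    angle_kappa: np.ndarray  # (S,) von Mises concentration, >= 0
    tpm: np.ndarray         # (S, S) row-stochastic transition matrix
    delta: np.ndarray       # (S,) initial distribution

    def __post_init__(self) -> None:
        for name in ("step_mean", "step_sd", "angle_mean", "angle_kappa", "tpm", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    def validate(self) -> None:
        s = self.n_states
        if not (len(self.step_sd) == len(self.angle_mean) == len(self.angle_kappa) == s):
            raise ValueError("inconsistent state dimensions")
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma mean and sd must be positive")
        if np.any(self.angle_kappa < 0):
            raise ValueError("von Mises concentration must be >= 0")
        if self.tpm.shape != (s, s) or np.any(self.tpm < 0) or \
                not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix must be row-stochastic")
        if len(self.delta) != s or np.any(self.delta < 0) or \
                not np.isclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ValueError("delta must be a probability vector")

    def permuted(self, order: Sequence[int]) -> "MovementHMM":
        """Relabel states by ``order`` (new state i = old state order[i])."""
        o = np.asarray(order)
        return MovementHMM(self.step_mean[o], self.step_sd[o], self.angle_mean[o],
                           self.angle_kappa[o], self.tpm[np.ix_(o, o)], self.delta[o])

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist()
                for k in ("step_mean", "step_sd", "angle_mean", "angle_kappa", "tpm", "delta")}

    @classmethod
    def from_dict(cls, d: dict) -> "MovementHMM":
        return cls(**{k: np.asarray(d[k]) for k in
                      ("step_mean", "step_sd", "angle_mean", "angle_kappa", "tpm", "delta")})


def n_free_params(n_states: int) -> int:
    """delta: S-1, transitions: S(S-1), emissions: 4 per state."""
    return (n_states - 1) + n_states * (n_states - 1) + 4 * n_states


# ---------------------------------------------------------------------------
# observations

def as_obs(seq) -> tuple[np.ndarray, np.ndarray]:
    """Coerce one trip's observations to (steps, angles) float arrays."""
    if isinstance(seq, pd.DataFrame):
        return (seq["step_m"].to_numpy(dtype=float),
                seq["angle_rad"].to_numpy(dtype=float))
    steps, angles = seq
    return np.asarray(steps, dtype=float), np.asarray(angles, dtype=float)


def _log_emission(model: MovementHMM, steps: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(T, S) log emission densities; NaN angles contribute step density only."""
    s = np.maximum(steps, STEP_FLOOR_M)[:, None]
    shape = (model.step_mean ** 2 / model.step_sd ** 2)[None, :]
    scale = (model.step_sd ** 2 / model.step_mean)[None, :]
    logp = gamma_dist.logpdf(s, a=shape, scale=scale)
    ok = np.isfinite(angles)
    if ok.any():
        logp[ok] += vonmises.logpdf(angles[ok, None],
                                    kappa=np.maximum(model.angle_kappa, 1e-10)[None, :],
                                    loc=model.angle_mean[None, :])
    return logp


# ---------------------------------------------------------------------------
# likelihood and decoding

def _forward_pooled(model: MovementHMM, logb_pad: np.ndarray,
                    lengths: np.ndarray) -> float:
    """Scaled forward algorithm, vectorised across padded chains.

    ``logb_pad`` is (n_seq, T_max, S) with arbitrary values beyond each
    chain's length; finished chains are frozen by masking.
    """
    n_seq, t_max, S = logb_pad.shape
    m = logb_pad[:, 0, :].max(axis=1)
    alpha = model.delta[None, :] * np.exp(logb_pad[:, 0, :] - m[:, None])
    c = alpha.sum(axis=1)
    ll = m + np.log(c)
    alpha /= c[:, None]
    for t in range(1, t_max):
        active = lengths > t
        if not active.any():
            break
        m = logb_pad[:, t, :].max(axis=1)
        a_new = (alpha @ model.tpm) * np.exp(logb_pad[:, t, :] - m[:, None])
        c = a_new.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = np.where(active, ll + m + np.log(c), ll)
            alpha = np.where(active[:, None], a_new / c[:, None], alpha)
    return float(ll.sum())


def _pad_obs(seqs: list[tuple[np.ndarray, np.ndarray]]
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate (steps, angles) pairs and record chain lengths."""
    lengths = np.array([len(s) for s, _ in seqs])
    steps = np.concatenate([s for s, _ in seqs])
    angles = np.concatenate([a for _, a in seqs])
    return steps, angles, lengths


def _padded_logb(model: MovementHMM, steps: np.ndarray, angles: np.ndarray,
                 lengths: np.ndarray) -> np.ndarray:
    """(n_seq, T_max, S) padded log emission array from pooled observations."""
    logb = _log_emission(model, steps, angles)
    n_seq, t_max, S = len(lengths), int(lengths.max()), logb.shape[1]
    out = np.zeros((n_seq, t_max, S))
    offs = np.concatenate([[0], np.cumsum(lengths)])
    for i in range(n_seq):
        out[i, : lengths[i]] = logb[offs[i]: offs[i + 1]]
    return out


def hmm_loglik(model: MovementHMM, obs) -> float:
    """Forward-algorithm log marginal likelihood.

    ``obs`` is one trip's observations (DataFrame from
    :func:`~sitefidelity.tracks.steps_and_angles`, or a (steps, angles) pair)
    or an iterable of trips; trips are independent chains sharing parameters.
    """
    seqs = [s for s in _as_obs_list(obs) if len(s[0]) > 0]
    if not seqs:
        raise ValueError("empty observation sequence")
    steps, angles, lengths = _pad_obs(seqs)
    return _forward_pooled(model, _padded_logb(model, steps, angles, lengths),
                           lengths)


def _as_obs_list(obs) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(obs, pd.DataFrame) or (isinstance(obs, tuple) and len(obs) == 2
                                         and not isinstance(obs[0], (pd.DataFrame, tuple, list))):
        return [as_obs(obs)]
    return [as_obs(o) for o in obs]


def viterbi(model: MovementHMM, obs) -> np.ndarray:
    """Most probable state path for one trip (global decoding)."""
    steps, angles = as_obs(obs)
    logb = _log_emission(model, steps, angles)
    T, S = logb.shape
    with np.errstate(divide="ignore"):
        log_delta = np.log(model.delta)
        log_tpm = np.log(model.tpm)
    score = log_delta + logb[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = score[:, None] + log_tpm
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(S)] + logb[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# fitting

def _pack(model: MovementHMM) -> np.ndarray:
    S = model.n_states
    parts = [np.log(model.step_mean), np.log(model.step_sd),
             model.angle_mean, np.log(np.maximum(model.angle_kappa, 1e-8))]
    if S > 1:
        off = np.log(np.maximum(model.tpm, 1e-12) /
                     np.maximum(np.diag(model.tpm), 1e-12)[:, None])
        parts.append(off[~np.eye(S, dtype=bool)])
        parts.append(np.log(np.maximum(model.delta[1:], 1e-12) /
                            np.maximum(model.delta[0], 1e-12)))
    return np.concatenate(parts)


def _unpack(x: np.ndarray, S: int) -> MovementHMM:
    step_mean = np.exp(x[0:S])
    step_sd = np.exp(x[S:2 * S])
    angle_mean = wrap_angle(x[2 * S:3 * S])
    angle_kappa = np.exp(x[3 * S:4 * S])
    if S == 1:
        tpm = np.ones((1, 1))
        delta = np.ones(1)
    else:
        off = x[4 * S:4 * S + S * (S - 1)]
        logits = np.zeros((S, S))
        logits[~np.eye(S, dtype=bool)] = off
        logits -= logits.max(axis=1, keepdims=True)
        tpm = np.exp(logits)
        tpm /= tpm.sum(axis=1, keepdims=True)
        dl = np.concatenate([[0.0], x[4 * S + S * (S - 1):]])
        dl -= dl.max()
        delta = np.exp(dl)
        delta /= delta.sum()
    return MovementHMM(step_mean, step_sd, angle_mean, angle_kappa, tpm, delta)


def default_starting_values(n_states: int, interval_min: float = 10.0) -> MovementHMM:
    """Generic starting model, step scale proportional to the fix interval.

    Base per-minute step-mean magnitudes (300, 60, 15)/min cover
    travelling / intermediate / slow movement; angle means (0, 0, pi) with
    concentrations (5, 1, 0.5) start the slowest state as turn-reversing.
    """
    base = {1: [60.0], 2: [300.0, 15.0], 3: [300.0, 60.0, 15.0]}
    if n_states not in base:
        raise ValueError("supported state counts: 1, 2, 3")
    means = np.asarray(base[n_states]) * float(interval_min)
    mus = {1: [0.0], 2: [0.0, np.pi], 3: [0.0, 0.0, np.pi]}[n_states]
    kappas = {1: [1.0], 2: [5.0, 0.5], 3: [5.0, 1.0, 0.5]}[n_states]
    S = n_states
    tpm = np.full((S, S), 0.1 / max(S - 1, 1)) + np.eye(S) * (0.9 - 0.1 / max(S - 1, 1))
    tpm /= tpm.sum(axis=1, keepdims=True)
    return MovementHMM(means, means.copy(), mus, kappas, tpm, np.full(S, 1.0 / S))


@dataclass
class HMMFit:
    """Result of :func:`fit_hmm`."""

    model: MovementHMM
    loglik: float
    n_obs: int
    converged: bool
    restart_logliks: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * n_free_params(self.model.n_states) - 2.0 * self.loglik


def fit_hmm(obs_set, n_states: int = 3, starting_values: MovementHMM | None = None,
            n_restarts: int = 5, seed: int | None = None, maxiter: int = 500,
            interval_min: float = 10.0) -> HMMFit:
    """Maximum-likelihood fit by direct numerical maximisation.

    ``obs_set`` is an iterable of per-trip observations (DataFrames from
    :func:`~sitefidelity.tracks.steps_and_angles` or (steps, angles) pairs),
    pooled as independent chains with shared parameters. The best of
    ``n_restarts`` jittered starts is returned; the first start is unjittered.
    """
    seqs = [s for s in _as_obs_list(obs_set) if len(s[0]) > 0]
    if not seqs:
        raise ValueError("no observations to fit")
    n_obs = sum(len(s) for s, _ in seqs)
    start = starting_values if starting_values is not None else \
        default_starting_values(n_states, interval_min)
    if start.n_states != n_states:
        raise ValueError("starting values have wrong number of states")
    rng = np.random.default_rng(seed)
    x0 = _pack(start)
    steps, angles, lengths = _pad_obs(seqs)

    def nll(x: np.ndarray) -> float:
        try:
            model = _unpack(x, n_states)
            logb = _padded_logb(model, steps, angles, lengths)
            val = -_forward_pooled(model, logb, lengths)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return val

    best = None
    restart_lls = []
    any_ok = False
    for r in range(max(n_restarts, 1)):
        xr = x0 if r == 0 else x0 + rng.normal(0.0, 0.3, size=x0.shape)
        res = optimize.minimize(nll, xr, method="L-BFGS-B",
                                options={"maxiter": maxiter, "maxfun": 10 * maxiter})
        restart_lls.append(-res.fun)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        any_ok = any_ok or res.success
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"HMM fit failed in all {n_restarts} restarts: {restart_lls}")
    model = _unpack(best.x, n_states)
    return HMMFit(model=model, loglik=-float(best.fun), n_obs=n_obs,
                  converged=bool(any_ok), restart_logliks=restart_lls)


def select_n_states(obs_set, candidates: Iterable[int] = (2, 3), **fit_kw) -> tuple[int, dict]:
    """Pick the state count minimising AIC; returns (n_states, fits by n)."""
    fits = {n: fit_hmm(obs_set, n_states=n, **fit_kw) for n in candidates}
    n_best = min(fits, key=lambda n: fits[n].aic)
    return n_best, fits


# ---------------------------------------------------------------------------
# state labelling and site extraction

def label_states(model: MovementHMM) -> dict[int, str]:
    """Map state indices to travelling / foraging / resting.

    Travelling is the state with the largest mean step. Among the rest,
    foraging is the state whose turning angles concentrate away from zero
    (largest kappa * (1 - cos mu) / 2, the strength of turn reversal typical
    of area-restricted search); resting is the remainder. For a 2-state model
    the non-travelling state is foraging; a 1-state model is all foraging.
    """
    S = model.n_states
    if S == 1:
        return {0: "foraging"}
    travel = int(np.argmax(model.step_mean))
    rest_idx = [i for i in range(S) if i != travel]
    if S == 2:
        return {travel: "travelling", rest_idx[0]: "foraging"}
    score = model.angle_kappa * (1.0 - np.cos(model.angle_mean)) / 2.0
    ranked = sorted(rest_idx, key=lambda i: (score[i], -model.step_mean[i]))
    labels = {travel: "travelling", ranked[-1]: "foraging"}
    for i in ranked[:-1]:
        labels[i] = "resting"
    return labels


def states_per_fix(states: np.ndarray, n_fixes: int) -> np.ndarray:
    """Align a step-level state path (length n-1) to fixes (length n).

    Fix i takes the state of the step leaving it; the final fix inherits the
    last step's state.
    """
    states = np.asarray(states)
    if len(states) != n_fixes - 1:
        raise ValueError("state path must have n_fixes - 1 entries")
    return np.append(states, states[-1])


def extract_sites(trip, states: np.ndarray, label_map: dict[int, str]) -> pd.DataFrame:
    """Aggregate runs of consecutive foraging-state fixes into foraging sites.

    Each maximal run becomes one site with central coordinates the arithmetic
    mean of member fix latitudes and longitudes and ``t_mid`` the midpoint of
    the run's time span. Returns an empty frame if the trip has no foraging
    fixes (such trips are subsequently dropped as showing no area-restricted
    search).
    """
    fix_states = states_per_fix(states, trip.n_fixes)
    foraging = np.array([label_map[int(s)] == "foraging" for s in fix_states])
    rows = []
    i = 0
    n = len(foraging)
    k = 0
    while i < n:
        if not foraging[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and foraging[j + 1]:
            j += 1
        run = trip.fixes.iloc[i: j + 1]
        k += 1
        t0, t1 = run["t"].iloc[0], run["t"].iloc[-1]
        rows.append({"site_id": f"{trip.trip_id}_s{k:02d}",
                     "bird_id": trip.bird_id, "trip_id": trip.trip_id,
                     "colony_id": trip.colony_id, "stage": trip.stage,
                     "lat_c": float(run["lat"].mean()),
                     "lon_c": float(run["lon"].mean()),
                     "t_mid": t0 + (t1 - t0) / 2, "n_fixes": int(len(run))})
        i = j + 1
    cols = ["site_id", "bird_id", "trip_id", "colony_id", "stage",
            "lat_c", "lon_c", "t_mid", "n_fixes"]
    return pd.DataFrame(rows, columns=cols)
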