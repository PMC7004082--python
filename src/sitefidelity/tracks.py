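"""Raw GPS fixes -> foraging trips.

A central-place forager's recording is split into foraging trips: maximal runs
of fixes farther than a colony buffer (default 300 m) whose elapsed time
exceeds a minimum duration (default 1 h). Trips are linearly interpolated to a
regular time grid, summarised by distance / duration / maximum range, and
converted to step-length / turning-angle observations for the movement model.

Conventions fixed here:

* a trip consists of outside-buffer fixes only; boundary crossings are not
  interpolated onto the buffer circle;
* a run that touches the start or end of the recording without returning
  inside the buffer is an *incomplete* trip (logger failed mid-trip);
* turning angles are signed bearing changes, counter-clockwise positive,
  wrapped to (-pi, pi]; the first step of a trip has no angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geo import haversine_m, initial_bearing_rad, wrap_angle

FIX_COLUMNS = ["t", "lat", "lon"]


@dataclass
class Trip:
    """One foraging trip: ordered outside-buffer fixes of one bird."""

    trip_id: str
    bird_id: str
    fixes: pd.DataFrame  # columns t (datetime64), lat, lon
    complete: bool
    stage: str = ""
    colony_id: str = ""

    def __post_init__(self) -> None:
        t = self.fixes["t"].to_numpy()
        if len(t) > 1 and not (np.diff(t).astype("timedelta64[ns]") > np.timedelta64(0)).all():
            raise ValueError(f"trip {self.trip_id}: fixes not strictly increasing in time")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def duration_hr(self) -> float:
        t = self.fixes["t"]
        return (t.iloc[-1] - t.iloc[0]) / pd.Timedelta(hours=1)


@dataclass
class TripMetrics:
    """Summary metrics of a trip; fields are None where the trip does not qualify."""

    trip_id: str
    complete: bool
    distance_km: Optional[float] = None
    duration_hr: Optional[float] = None
    max_range_km: Optional[float] = None


def colony_distance_m(fixes: pd.DataFrame, colony: tuple[float, float]) -> np.ndarray:
    return np.asarray(haversine_m(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(),
                                  colony[0], colony[1]))


def segment_trips(
    fixes: pd.DataFrame,
    colony: tuple[float, float],
    buffer_m: float = 300.0,
    min_duration_hr: float = 1.0,
    bird_id: str = "",
    stage: str = "",
    colony_id: str = "",
    with_dropped: bool = False,
):
    """Split one bird's fix table into foraging trips.

    Every maximal run of consecutive fixes farther than ``buffer_m`` from the
    colony whose elapsed time (last minus first fix) is strictly longer than
    ``min_duration_hr`` becomes a :class:`Trip`. Runs touching the start or end
    of the recording are flagged ``complete=False``.

    With ``with_dropped=True`` also returns a bookkeeping DataFrame of
    excursions discarded for being too short.
    """
    if len(fixes) == 0:
        return ([], _empty_dropped()) if with_dropped else []
    fixes = fixes.sort_values("t").reset_index(drop=True)
    t = fixes["t"].to_numpy()
    if len(t) > 1 and not (np.diff(t) > np.timedelta64(0)).all():
        raise ValueError("fixes must be strictly increasing in time")

    outside = colony_distance_m(fixes, colony) > buffer_m
    trips: list[Trip] = []
    dropped = []
    n = len(fixes)
    i = 0
    k = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outside[j + 1]:
            j += 1
        run = fixes.iloc[i: j + 1].reset_index(drop=True)
        elapsed_hr = (run["t"].iloc[-1] - run["t"].iloc[0]) / pd.Timedelta(hours=1)
        complete = not (i == 0 or j == n - 1)
        if elapsed_hr > min_duration_hr:
            k += 1
            trips.append(Trip(trip_id=f"{bird_id}_t{k:03d}", bird_id=bird_id,
                              fixes=run[FIX_COLUMNS].copy(), complete=complete,
                              stage=stage, colony_id=colony_id))
        else:
            dropped.append({"bird_id": bird_id, "start": run["t"].iloc[0],
                            "end": run["t"].iloc[-1], "n_fixes": len(run),
                            "duration_hr": elapsed_hr,
                            "reason": "below_min_duration"})
        i = j + 1
    if with_dropped:
        return trips, (pd.DataFrame(dropped) if dropped else _empty_dropped())
    return trips


def _empty_dropped() -> pd.DataFrame:
    return pd.DataFrame(columns=["bird_id", "start", "end", "n_fixes",
                                 "duration_hr", "reason"])


def interpolate_trip(trip: Trip, interval_min: float) -> Trip:
    """Linearly interpolate a trip onto a regular time grid.

    The grid is anchored at the first fix with spacing ``interval_min``
    minutes; latitude and longitude are interpolated linearly in time. The
    last original fix is appended if it falls off-grid, so trip endpoints are
    always preserved.
    """
    if trip.n_fixes < 2:
        raise ValueError(f"trip {trip.trip_id}: need >= 2 fixes to interpolate")
    t = trip.fixes["t"]
    t0, t1 = t.iloc[0], t.iloc[-1]
    step = pd.Timedelta(minutes=interval_min)
    n_steps = int(np.floor((t1 - t0) / step))
    grid = pd.Series([t0 + i * step for i in range(n_steps + 1)])
    if grid.iloc[-1] < t1:
        grid = pd.concat([grid, pd.Series([t1])], ignore_index=True)
    sec = (t - t0).dt.total_seconds().to_numpy()
    gsec = (grid - t0).dt.total_seconds().to_numpy()
    lat = np.interp(gsec, sec, trip.fixes["lat"].to_numpy())
    lon = np.interp(gsec, sec, trip.fixes["lon"].to_numpy())
    out = pd.DataFrame({"t": grid, "lat": lat, "lon": lon})
    return Trip(trip_id=trip.trip_id, bird_id=trip.bird_id, fixes=out,
                complete=trip.complete, stage=trip.stage, colony_id=trip.colony_id)


def trip_metrics(trip: Trip, colony: tuple[float, float],
                 return_fraction: float = 0.75) -> TripMetrics:
    """Distance, duration and maximum range of a trip.

    Complete trips get all three metrics. Incomplete recordings (logger failed
    away from the colony) are excluded from distance and duration; their
    maximum range is kept only if the final recorded fix lies within
    ``return_fraction`` (default 75%) of the trip's maximum colony distance,
    i.e. the bird had largely returned before the logger failed.
    """
    d_colony = colony_distance_m(trip.fixes, colony)
    max_range_km = float(d_colony.max()) / 1000.0
    lat = trip.fixes["lat"].to_numpy()
    lon = trip.fixes["lon"].to_numpy()
    path_km = float(np.sum(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]))) / 1000.0
    if trip.complete:
        return TripMetrics(trip.trip_id, True, distance_km=path_km,
                           duration_hr=trip.duration_hr, max_range_km=max_range_km)
    if d_colony[-1] <= return_fraction * d_colony.max():
        return TripMetrics(trip.trip_id, False, max_range_km=max_range_km)
    return TripMetrics(trip.trip_id, False)


def steps_and_angles(trip: Trip) -> pd.DataFrame:
    """Step lengths (m) and signed turning angles (rad) along a trip.

    ``n`` fixes yield ``n - 1`` steps and ``n - 2`` defined angles; the first
    step's angle is NaN. Turning angle is the change in bearing between
    successive steps, counter-clockwise positive, in (-pi, pi].
    """
    lat = trip.fixes["lat"].to_numpy()
    lon = trip.fixes["lon"].to_numpy()
    n = len(lat)
    if n < 2:
        return pd.DataFrame({"trip_id": [], "index": [], "step_m": [], "angle_rad": []})
    step = np.asarray(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]), dtype=float)
    angle = np.full(n - 1, np.nan)
    if n >= 3:
        brg = np.asarray(initial_bearing_rad(lat[:-1], lon[:-1], lat[1:], lon[1:]))
        # bearings are clockwise-from-north; CCW-positive turn = previous - next
        angle[1:] = wrap_angle(brg[:-1] - brg[1:])
    return pd.DataFrame({"trip_id": trip.trip_id, "index": np.arange(n - 1),
                         "step_m": step, "angle_rad": angle})
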