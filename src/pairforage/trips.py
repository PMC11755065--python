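"""Dive detection, foraging-trip segmentation, and per-bird metrics.

A dive is a maximal run of depth samples at or below ``min_depth`` (default
1 m, comfortably above the 0.1-m sensor resolution and surface splash) that
lasts at least ``min_duration`` seconds.  A foraging trip is a maximal
excursion farther than 1 km from the colony that lasts longer than 20 min and
contains at least one dive.  Per-trip and per-deployment metrics (distances,
durations, azimuths, dive statistics, differential depth, activity budgets)
follow the conventional central-place-foraging summary set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import initial_bearing_deg
from .hmm import StatePath, StepSeries

#: UTC offset (hours) of colony local time, used for the hour-of-day of dives
DEFAULT_TZ_OFFSET_H = -5.0


@dataclass
class Dive:
    start: np.datetime64
    end: np.datetime64
    duration_min: float
    max_depth_m: float
    mean_depth_m: float
    hour_of_day: int

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("dive end must be after start")
        if not self.max_depth_m >= self.mean_depth_m:
            raise ValueError("max depth must be >= mean depth")


@dataclass
class Trip:
    bird_id: str
    start: np.datetime64
    end: np.datetime64
    duration_h: float
    step_slice: tuple            # [i0, i1) indices into the StepSeries
    max_colony_distance_km: float
    total_path_km: float
    azimuth_deg: float           # colony -> farthest point, [0, 360)
    dive_count: int
    partial: bool = False        # truncated by a deployment boundary


def detect_dives(
    depths: pd.DataFrame,
    min_depth: float = 1.0,
    min_duration_s: float = 3.0,
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H,
) -> list[Dive]:
    """Find maximal contiguous runs with depth >= min_depth lasting at least
    ``min_duration_s``.  ``depths`` needs columns time, depth_m."""
    if len(depths) == 0:
        return []
    t = depths["time"].to_numpy().astype("datetime64[ms]")
    d = depths["depth_m"].to_numpy(dtype=float)
    if (d < 0).any():
        raise ValueError("depths must be >= 0")
    wet = d >= min_depth
    if not wet.any():
        return []
    edges = np.flatnonzero(np.diff(wet.astype(np.int8)))
    starts = list(edges[~wet[edges]] + 1) if len(edges) else []
    ends = list(edges[wet[edges]] + 1) if len(edges) else []
    if wet[0]:
        starts = [0] + starts
    if wet[-1]:
        ends = ends + [len(d)]
    dives = []
    for i0, i1 in zip(starts, ends):
        dur_s = (t[i1 - 1] - t[i0]).astype("timedelta64[ms]").astype(float) / 1000.0
        # a run of k samples at rate r spans (k-1)/r between first and last
        # sample; include one sample interval so a k-sample run at 1 Hz
        # counts as k seconds submerged
        if i1 - i0 >= 2:
            dur_s += (t[i1 - 1] - t[i1 - 2]).astype("timedelta64[ms]").astype(float) / 1000.0
        if dur_s < min_duration_s:
            continue
        seg = d[i0:i1]
        local = t[i0] + np.timedelta64(int(tz_offset_h * 3600 * 1000), "ms")
        hour = int(pd.Timestamp(local).hour)
        dives.append(
            Dive(
                start=t[i0],
                end=t[i0] + np.timedelta64(int(dur_s * 1000), "ms"),
                duration_min=dur_s / 60.0,
                max_depth_m=float(seg.max()),
                mean_depth_m=float(seg.mean()),
                hour_of_day=hour,
            )
        )
    return dives


def segment_trips(
    series: StepSeries,
    dives: list[Dive],
    min_dist_km: float = 1.0,
    min_duration_min: float = 20.0,
) -> list[Trip]:
    """Candidate excursions are maximal runs of steps with colony distance
    beyond ``min_dist_km``; kept iff longer than ``min_duration_min`` and at
    least one dive overlaps the excursion window.  Excursions touching a
    deployment boundary are flagged partial."""
    away = series.colony_dist_km > min_dist_km
    if not away.any():
        return []
    edges = np.flatnonzero(np.diff(away.astype(np.int8)))
    starts = list(edges[~away[edges]] + 1) if len(edges) else []
    ends = list(edges[away[edges]] + 1) if len(edges) else []
    if away[0]:
        starts = [0] + starts
    if away[-1]:
        ends = ends + [len(away)]
    dive_starts = np.array([d.start for d in dives], dtype="datetime64[ms]") if dives else np.array([], dtype="datetime64[ms]")
    dive_ends = np.array([d.end for d in dives], dtype="datetime64[ms]") if dives else np.array([], dtype="datetime64[ms]")

    trips = []
    iv = np.timedelta64(int(series.interval_s * 1000), "ms")
    for i0, i1 in zip(starts, ends):
        t_start = series.times[i0]
        t_end = series.times[i1 - 1] + iv
        dur_min = (t_end - t_start).astype("timedelta64[ms]").astype(float) / 60000.0
        if dur_min <= min_duration_min:
            continue
        n_dives = int(((dive_starts < t_end) & (dive_ends > t_start)).sum()) if len(dive_starts) else 0
        if n_dives < 1:
            continue
        summary = trip_summary_indices(series, i0, i1)
        trips.append(
            Trip(
                bird_id=series.bird_id,
                start=t_start,
                end=t_end,
                duration_h=dur_min / 60.0,
                step_slice=(i0, i1),
                max_colony_distance_km=summary["max_colony_distance_km"],
                total_path_km=summary["total_path_km"],
                azimuth_deg=summary["azimuth_deg"],
                dive_count=n_dives,
                partial=(i0 == 0 or i1 == len(away)),
            )
        )
    return trips


def trip_summary_indices(series: StepSeries, i0: int, i1: int, colony_lonlat=None) -> dict:
    """Max colony distance, along-track path length and colony-to-farthest
    azimuth for the step range [i0, i1).  Steps imputed across long gaps are
    excluded from the path-length numerator."""
    cd = series.colony_dist_km[i0:i1]
    k_far = int(np.argmax(cd))
    ok = ~series.interpolated[i0:i1]
    path = float(np.sum(series.step_km[i0:i1][ok]))
    colony = colony_lonlat if colony_lonlat is not None else series.colony_lonlat
    if colony is None:
        # last resort: the track's nearest-to-colony position approximates it
        j = int(np.argmin(series.colony_dist_km))
        colony = (series.lon[j], series.lat[j])
    az = float(initial_bearing_deg(colony[0], colony[1], series.lon[i0 + k_far], series.lat[i0 + k_far]))
    return {
        "max_colony_distance_km": float(cd[k_far]),
        "total_path_km": path,
        "azimuth_deg": az,
    }


def hourly_mean_depth(dives: list[Dive]) -> np.ndarray:
    """24-vector of mean dive mean-depths by local hour; NaN where no dives.

    Computed population-wide (pass all dives of a year) by default; pass any
    subset to switch to per-individual or per-sex averaging.
    """
    if not dives:
        raise ValueError("hourly_mean_depth needs at least one dive")
    out = np.full(24, np.nan)
    depths = np.array([d.mean_depth_m for d in dives])
    hours = np.array([d.hour_of_day for d in dives])
    for h in range(24):
        m = hours == h
        if m.any():
            out[h] = depths[m].mean()
    return out


def differential_depth(dive: Dive, hourly_means: np.ndarray) -> float:
    """Dive mean depth minus the hourly mean at the dive's hour (signed;
    absolute values are taken at the modelling stage)."""
    ref = hourly_means[dive.hour_of_day]
    if not np.isfinite(ref):
        raise ValueError(f"no hourly mean depth defined for hour {dive.hour_of_day}")
    return float(dive.mean_depth_m - ref)


_ACTIVITY = ("colony", "diving", "flying", "swimming")


@dataclass
class BirdMetrics:
    """Deployment-level foraging/diving summary for one bird."""

    bird_id: str
    values: dict = field(default_factory=dict)
    single_trip: bool = False     # SDs over a single trip are reported as 0

    def as_series(self) -> pd.Series:
        s = pd.Series(self.values, name=self.bird_id)
        s["single_trip_flag"] = float(self.single_trip)
        return s


def _mean_sd(x) -> tuple:
    x = np.asarray(x, dtype=float)
    if len(x) == 1:
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1))


def deployment_summary(
    trips: list[Trip],
    dives: list[Dive],
    path: StatePath,
    series: StepSeries,
    hourly_means: np.ndarray,
    warn_azimuth_span: float = 180.0,
) -> BirdMetrics:
    """All per-deployment metrics.

    Trip-level metrics are averaged over kept trips; "per day" denominators
    use the exact deployment span in days.  A single-trip deployment reports
    SD = 0 with a flag rather than missing, so pairwise differencing keeps
    the bird.  Azimuth summaries are arithmetic means of bearings in
    [0, 360); trips spanning more than ``warn_azimuth_span`` degrees trigger
    a warning (a circular mean would then be the better summary).
    """
    if not trips:
        raise ValueError("deployment_summary requires at least one kept trip")
    span_days = (series.times[-1] - series.times[0]).astype("timedelta64[ms]").astype(float) / 86400000.0
    if span_days <= 0:
        raise ValueError("zero-length deployment")

    md = [t.max_colony_distance_km for t in trips]
    pathkm = [t.total_path_km for t in trips]
    dur = [t.duration_h for t in trips]
    az = [t.azimuth_deg for t in trips]
    if max(az) - min(az) > warn_azimuth_span:
        import warnings

        warnings.warn("trip azimuths span > 180 degrees; arithmetic mean may mislead")

    v: dict[str, float] = {}
    v["max_colony_distance_km_mean"], v["max_colony_distance_km_sd"] = _mean_sd(md)
    v["total_distance_km"] = float(np.sum(pathkm))
    v["mean_trip_distance_km"], v["mean_trip_distance_km_sd"] = _mean_sd(pathkm)
    v["trip_duration_h_mean"], v["trip_duration_h_sd"] = _mean_sd(dur)
    v["trip_duration_h_max"] = float(np.max(dur))
    v["total_trip_duration_h"] = float(np.sum(dur))
    v["azimuth_deg_mean"], v["azimuth_deg_sd"] = _mean_sd(az)
    v["azimuth_deg_max"] = float(np.max(az))
    v["azimuth_deg_min"] = float(np.min(az))
    v["daily_distance_km"] = v["total_distance_km"] / span_days
    v["trips_per_day"] = len(trips) / span_days
    v["n_trips"] = float(len(trips))

    if dives:
        maxd = [d.max_depth_m for d in dives]
        meand = [d.mean_depth_m for d in dives]
        durs = [d.duration_min for d in dives]
        diffs = [differential_depth(d, hourly_means) for d in dives]
        v["max_dive_depth_m"], v["max_dive_depth_m_sd"] = _mean_sd(maxd)
        v["mean_dive_depth_m"], v["mean_dive_depth_m_sd"] = _mean_sd(meand)
        v["total_dive_duration_h"] = float(np.sum(durs)) / 60.0
        v["max_dive_duration_min"] = float(np.max(durs))
        v["mean_dive_duration_min"], v["mean_dive_duration_min_sd"] = _mean_sd(durs)
        v["max_differential_depth_m"] = float(np.max(diffs))
        v["mean_differential_depth_m"], v["mean_differential_depth_m_sd"] = _mean_sd(diffs)
        v["dives_per_day"] = len(dives) / span_days
    else:
        for key in (
            "max_dive_depth_m", "max_dive_depth_m_sd", "mean_dive_depth_m", "mean_dive_depth_m_sd",
            "total_dive_duration_h", "max_dive_duration_min", "mean_dive_duration_min",
            "mean_dive_duration_min_sd", "max_differential_depth_m", "mean_differential_depth_m",
            "mean_differential_depth_m_sd", "dives_per_day",
        ):
            v[key] = np.nan

    counts = pd.Series(path.states).value_counts()
    total = float(len(path.states))
    for a in _ACTIVITY:
        v[f"prop_{a}"] = float(counts.get(a, 0)) / total

    return BirdMetrics(bird_id=series.bird_id, values=v, single_trip=(len(trips) == 1))


def audit_trips(trips: list[Trip], min_dist_km: float = 1.0, min_duration_min: float = 20.0) -> bool:
    """Post-hoc check that every kept trip satisfies the three predicates."""
    for t in trips:
        assert t.max_colony_distance_km > min_dist_km, t
        assert t.duration_h * 60.0 > min_duration_min, t
        assert t.dive_count >= 1, t
    return True


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bird_id": [t.bird_id for t in trips],
            "start": [t.start for t in trips],
            "end": [t.end for t in trips],
            "duration_h": [t.duration_h for t in trips],
            "max_colony_distance_km": [t.max_colony_distance_km for t in trips],
            "total_path_km": [t.total_path_km for t in trips],
            "azimuth_deg": [t.azimuth_deg for t in trips],
            "dive_count": [t.dive_count for t in trips],
            "partial": [t.partial for t in trips],
        }
    )


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [d.start for d in dives],
            "end": [d.end for d in dives],
            "duration_min": [d.duration_min for d in dives],
            "max_depth_m": [d.max_depth_m for d in dives],
            "mean_depth_m": [d.mean_depth_m for d in dives],
            "hour_of_day": [d.hour_of_day for d in dives],
        }
    )
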