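"""Synthetic colony generator for paired central-place foragers.

Emulates a two-season GPS/TDR deployment study on breeding pairs of a
pursuit-diving seabird: per-bird GPS fixes (one per 3 min), a 1-Hz depth
trace, a per-fix flight-intensity scalar standing in for wing-beat frequency,
and morphometrics.  Pairing structure is configurable: each trait can be made
disassortative (mates more different than random) or assortative (more
similar), so the downstream inference can be validated by parameter recovery.

Disassortment construction
--------------------------
For a trait with disassortment ``d > 0`` the two mates receive opposite role
offsets ``±δ`` (a "near/far specialist" split) on top of independent Gaussian
variation; δ is solved numerically so that, at equal sex means,

    E|trait_F − trait_M|  =  (1 + d) · E|difference of two independent draws|

holds exactly.  A coupling that preserves the Gaussian marginals cannot
exceed ratio √2, so the role construction is what makes strong disassortment
(d up to 1) representable.  For ``d < 0`` mates' deviations are positively
correlated Gaussians with ρ = 1 − (1+d)², which preserves marginals and gives
the identity exactly.  Wing length uses a plain correlation coefficient
(``wing_assortment``) instead, since assortment in size is conventionally
reported as a correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .geo import ColonyProjection

TRAITS = (
    "mean_trip_distance_km",
    "dives_per_day",
    "mean_dive_depth_m",
    "preferred_azimuth_deg",
    "wing_mm",
    "head_bill_mm",
    "body_mass_g",
)

_DEFAULT_MEANS = {
    "F": {
        "mean_trip_distance_km": 40.0,
        "dives_per_day": 120.0,
        "mean_dive_depth_m": 30.0,
        "preferred_azimuth_deg": 267.0,
        "wing_mm": 220.0,
        "head_bill_mm": 110.0,
        "body_mass_g": 981.0,
    },
    "M": {
        "mean_trip_distance_km": 30.0,
        "dives_per_day": 90.0,
        "mean_dive_depth_m": 34.0,
        "preferred_azimuth_deg": 242.0,
        "wing_mm": 221.0,
        "head_bill_mm": 110.5,
        "body_mass_g": 975.0,
    },
}

_DEFAULT_SD = {
    "mean_trip_distance_km": 10.0,
    "dives_per_day": 25.0,
    "mean_dive_depth_m": 8.0,
    "preferred_azimuth_deg": 30.0,
    "wing_mm": 4.0,
    "head_bill_mm": 2.5,
    "body_mass_g": 55.0,
}

# Recovery-study conditions: strong but plausible complementary specialisation
# in trip distance and dive rate, and positive size assortment in wing length.
_DEFAULT_DISASSORTMENT = {
    "mean_trip_distance_km": 0.5,
    "dives_per_day": 0.5,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic colony.

    Defaults reproduce the reference deployment design: 19 + 21 pairs across
    two seasons, 72-h deployments, a GPS fix every 180 s and 1-Hz depth.
    """

    n_pairs_per_year: dict = field(default_factory=lambda: {"2022": 19, "2023": 21})
    deployment_hours: float = 72.0
    gps_interval_s: float = 180.0
    depth_rate_hz: float = 1.0
    colony_lonlat: tuple = (-82.019, 62.948)
    trait_means_by_sex: dict = field(default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_MEANS.items()})
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_SD))
    disassortment: dict = field(default_factory=lambda: dict(_DEFAULT_DISASSORTMENT))
    wing_assortment: float = 0.7
    dive_miss_prob: float = 0.01      # ε: chance a trip carries no dive
    measurement_sd_frac: float = 0.2  # measurement noise as a fraction of the trait's population SD
    flight_speed_kmh: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_pairs_per_year, int):
            self.n_pairs_per_year = {"2022": self.n_pairs_per_year}
        for year, n in self.n_pairs_per_year.items():
            if n < 2:
                raise ValueError(f"n_pairs_per_year[{year}] must be >= 2, got {n}")
        if not self.deployment_hours > 0:
            raise ValueError("deployment_hours must be > 0")
        if not self.gps_interval_s > 0:
            raise ValueError("gps_interval_s must be > 0")
        if not self.depth_rate_hz > 0:
            raise ValueError("depth_rate_hz must be > 0")
        for sex in ("F", "M"):
            for t, v in self.trait_means_by_sex[sex].items():
                if not math.isfinite(v):
                    raise ValueError(f"trait_means_by_sex[{sex}][{t}] is not finite")
        for t, v in self.noise_sd.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"noise_sd[{t}] must be finite and >= 0")
        for t, v in self.disassortment.items():
            if not math.isfinite(v) or v < -1 or v >= 1:
                raise ValueError(f"disassortment[{t}] must be finite and in [-1, 1), got {v}")
        if not -1.0 <= self.wing_assortment <= 1.0:
            raise ValueError("wing_assortment must be in [-1, 1]")


@dataclass
class Phenotype:
    """Latent foraging/morphological phenotype of one bird."""

    mean_trip_distance_km: float
    dives_per_day: float
    mean_dive_depth_m: float
    preferred_azimuth_deg: float
    wing_mm: float
    head_bill_mm: float
    body_mass_g: float

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or (f.name != "preferred_azimuth_deg" and v <= 0):
                raise ValueError(f"phenotype field {f.name} must be finite and positive, got {v}")
        self.preferred_azimuth_deg = self.preferred_azimuth_deg % 360.0

    def as_dict(self):
        return dataclasses.asdict(self)


@dataclass
class Deployment:
    """One bird's deployment: track, depth trace, identity and morphometrics.

    ``fixes`` columns: time (datetime64), lon, lat, flight_intensity.
    ``depths`` columns: time (datetime64), depth_m.
    ``true_states`` holds the generator's per-fix activity label (ground
    truth for classifier validation; not part of the field-data contract).
    """

    bird_id: str
    sex: str
    year: str
    pair_id: str
    fixes: pd.DataFrame
    depths: pd.DataFrame
    wing_mm: float
    head_bill_mm: float
    mass_pre_g: float
    mass_post_g: float
    true_states: np.ndarray | None = None

    def __post_init__(self):
        for df, col in ((self.fixes, "time"), (self.depths, "time")):
            if len(df) > 1 and not df[col].is_monotonic_increasing:
                raise ValueError("timestamps must be increasing")
        if len(self.depths) and (self.depths["depth_m"] < 0).any():
            raise ValueError("depths must be >= 0")


def _folded_mean(mu: float, sd: float) -> float:
    """Mean of |X| for X ~ Normal(mu, sd)."""
    return sd * math.sqrt(2.0 / math.pi) * math.exp(-(mu**2) / (2 * sd**2)) + mu * (
        1.0 - 2.0 * norm.cdf(-mu / sd)
    )


def role_offset_for(d: float) -> float:
    """Role offset δ (in units of the trait SD) realizing disassortment d > 0.

    Solves  g(2δ) = (1+d)·g(0)/(1−d)  where g(t) = E|t + √2·Z|, the mean
    absolute real-pair difference when mates take opposite ±δ roles.
    """
    if d <= 0:
        return 0.0
    g0 = _folded_mean(0.0, math.sqrt(2.0))
    target = (1.0 + d) * g0 / (1.0 - d)
    f = lambda u: _folded_mean(2.0 * u, math.sqrt(2.0)) - target
    return brentq(f, 0.0, target + 10.0)


def _positive(x: np.ndarray, mean: float) -> np.ndarray:
    floor = max(0.02 * abs(mean), 1e-6)
    return np.maximum(x, floor)


def draw_phenotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw latent phenotypes for every pair in every season.

    Returns ``{pair_id: (female Phenotype, male Phenotype)}`` with pair ids of
    the form ``"<year>P<k>"``.  Reproducible: the stream is derived from
    ``config.seed`` unless an explicit generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    out: dict[str, tuple[Phenotype, Phenotype]] = {}
    for year in sorted(config.n_pairs_per_year):
        n = config.n_pairs_per_year[year]
        cols_f, cols_m = {}, {}
        for trait in TRAITS:
            mu_f = config.trait_means_by_sex["F"][trait]
            mu_m = config.trait_means_by_sex["M"][trait]
            sd = config.noise_sd[trait]
            z_f = rng.standard_normal(n)
            z_m = rng.standard_normal(n)
            if trait == "wing_mm":
                rho = config.wing_assortment
                f = mu_f + sd * z_f
                m = mu_m + sd * (rho * z_f + math.sqrt(max(0.0, 1 - rho**2)) * z_m)
            else:
                d = config.disassortment.get(trait, 0.0)
                if d > 0:
                    delta = role_offset_for(d)
                    roles = rng.choice([-1.0, 1.0], size=n)
                    f = mu_f + sd * (roles * delta + z_f)
                    m = mu_m + sd * (-roles * delta + z_m)
                elif d < 0:
                    rho = 1.0 - (1.0 + d) ** 2
                    f = mu_f + sd * z_f
                    m = mu_m + sd * (rho * z_f + math.sqrt(max(0.0, 1 - rho**2)) * z_m)
                else:
                    f = mu_f + sd * z_f
                    m = mu_m + sd * z_m
            if trait == "preferred_azimuth_deg":
                f, m = f % 360.0, m % 360.0
            else:
                f = _positive(f, mu_f)
                m = _positive(m, mu_m)
            cols_f[trait], cols_m[trait] = f, m
        for k in range(n):
            pid = f"{year}P{k + 1:02d}"
            out[pid] = (
                Phenotype(**{t: float(cols_f[t][k]) for t in TRAITS}),
                Phenotype(**{t: float(cols_m[t][k]) for t in TRAITS}),
            )
    return out


def observed_trait_table(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-bird measured traits: phenotype plus measurement noise.

    Noise SD per trait is ``measurement_sd_frac`` times the trait's
    between-individual SD — measurement reliability stated relative to
    population variation, so a 4-mm-SD wing is measured to ~1 mm while a
    10-km-SD trip distance carries ~2 km of deployment sampling error.  The
    fast stand-in for running the full track → metrics chain when only the
    pairing inference is under study; one row per bird with identity columns
    and one column per trait.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    phen = draw_phenotypes(config, rng)
    rows = []
    for pid, (ph_f, ph_m) in phen.items():
        year = pid.split("P")[0]
        for sex, ph in (("F", ph_f), ("M", ph_m)):
            row = {"bird_id": f"{pid}{sex}", "sex": sex, "year": year, "pair_id": pid}
            for t in TRAITS:
                v = getattr(ph, t)
                row[t] = v + rng.normal(0.0, config.measurement_sd_frac * config.noise_sd[t])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track / depth simulation
# ---------------------------------------------------------------------------

_STATE_INTENSITY = {"colony": (0.6, 0.2), "flying": (8.0, 0.6), "swimming": (1.5, 0.3), "diving": (3.0, 0.4)}


def _deployment_start(year: str) -> np.datetime64:
    return np.datetime64(f"{year}-07-25T00:00:00")


def simulate_track(
    phenotype: Phenotype,
    config: SimConfig,
    seed,
    bird_id: str = "B000",
    sex: str = "F",
    year: str = "2022",
    pair_id: str = "P00",
) -> Deployment:
    """Simulate one deployment: bouts at the colony alternating with
    out-and-back foraging excursions along the bird's preferred azimuth.

    Movement is a biased correlated walk in the colony-centred tangent plane
    (commute legs track a straight bearing with lateral noise; the foraging
    phase is a mean-reverting walk around the trip target), projected back to
    lon/lat.  Dives are V-shaped excursions in the 1-Hz depth trace placed
    inside foraging windows at the phenotype's daily rate; every trip carries
    at least one dive with probability 1 − ``config.dive_miss_prob``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    dt = config.gps_interval_s
    n_steps = int(round(config.deployment_hours * 3600.0 / dt)) + 1
    t0 = _deployment_start(year)
    times = t0 + (np.arange(n_steps) * dt * 1000).astype("timedelta64[ms]")

    xy = np.zeros((n_steps, 2))           # km east/north of colony
    state = np.empty(n_steps, dtype=object)
    step_speed = config.flight_speed_kmh * dt / 3600.0  # km per GPS step

    # forage windows as (start_idx, end_idx) step index ranges, per trip
    forage_windows: list[tuple[int, int]] = []
    i = 0
    while i < n_steps:
        # colony bout
        bout = max(1, int(round(rng.uniform(1.5, 3.5) * 3600.0 / dt)))
        j = min(n_steps, i + bout)
        xy[i:j] = rng.normal(0.0, 0.05, size=(j - i, 2))
        state[i:j] = "colony"
        i = j
        if i >= n_steps:
            break
        # trip
        target_d = max(1.5, rng.normal(phenotype.mean_trip_distance_km, 0.12 * phenotype.mean_trip_distance_km))
        target_d = min(target_d, 1.6 * phenotype.mean_trip_distance_km)
        brg = np.radians(phenotype.preferred_azimuth_deg + rng.normal(0.0, 15.0))
        target = target_d * np.array([np.sin(brg), np.cos(brg)])
        n_out = max(1, int(np.ceil(target_d / step_speed)))
        n_forage = max(2, int(round(rng.uniform(0.75, 2.0) * 3600.0 / dt)))
        # outbound commute
        j = min(n_steps, i + n_out)
        frac = np.arange(1, j - i + 1) / n_out
        xy[i:j] = frac[:, None] * target + rng.normal(0.0, 0.2, size=(j - i, 2))
        state[i:j] = "flying"
        i = j
        if i >= n_steps:
            break
        # foraging: mean-reverting walk around the target
        j = min(n_steps, i + n_forage)
        pos = target.copy()
        for k in range(i, j):
            pos = target + 0.7 * (pos - target) + rng.normal(0.0, 0.4, size=2)
            xy[k] = pos
        state[i:j] = "swimming"
        forage_windows.append((i, j))
        i = j
        if i >= n_steps:
            break
        # inbound commute
        start = xy[i - 1]
        n_in = max(1, int(np.ceil(np.linalg.norm(start) / step_speed)))
        j = min(n_steps, i + n_in)
        frac = np.arange(1, j - i + 1) / n_in
        xy[i:j] = (1 - frac)[:, None] * start + rng.normal(0.0, 0.15, size=(j - i, 2))
        state[i:j] = "flying"
        i = j

    # --- dives ----------------------------------------------------------
    span_days = config.deployment_hours / 24.0
    n_dives = rng.poisson(phenotype.dives_per_day * span_days) if phenotype.dives_per_day > 0 else 0
    dive_events = []  # (start_s, duration_s, depth_m)
    if forage_windows and (n_dives > 0 or phenotype.dives_per_day > 0):
        lengths = np.array([b - a for a, b in forage_windows], dtype=float)
        probs = lengths / lengths.sum()
        counts = rng.multinomial(n_dives, probs)
        for (a, b), c in zip(forage_windows, counts):
            if c == 0 and phenotype.dives_per_day > 0 and rng.random() > config.dive_miss_prob:
                c = 1  # trips essentially always contain at least one dive
            win_start = a * dt
            win_len = (b - a) * dt
            starts = np.sort(rng.uniform(win_start, win_start + max(win_len - 150.0, 1.0), size=c))
            last_end = -1.0
            for s in starts:
                dur = rng.uniform(45.0, 120.0)
                if s <= last_end + 5.0:
                    s = last_end + 5.0
                if s + dur > win_start + win_len:
                    continue
                depth = max(1.5, rng.normal(phenotype.mean_dive_depth_m, 0.2 * phenotype.mean_dive_depth_m))
                dive_events.append((s, dur, depth))
                last_end = s + dur

    # depth trace
    n_depth = int(round(config.deployment_hours * 3600.0 * config.depth_rate_hz)) + 1
    tsec = np.arange(n_depth) / config.depth_rate_hz
    depth = np.abs(rng.normal(0.0, 0.05, size=n_depth))
    for s, dur, dmax in dive_events:
        mask = (tsec >= s) & (tsec <= s + dur)
        if mask.any():
            ph = (tsec[mask] - s) / dur          # 0→1 over the dive: V shape
            depth[mask] = dmax * (1.0 - np.abs(2.0 * ph - 1.0))
    depth_times = t0 + (tsec * 1000).astype("timedelta64[ms]")

    # per-step dive overlap → refine "swimming" to "diving"
    for s, dur, _ in dive_events:
        k0 = int(s // dt)
        k1 = int((s + dur) // dt)
        for k in range(k0, min(k1 + 1, n_steps)):
            if state[k] == "swimming":
                state[k] = "diving"

    intensity = np.empty(n_steps)
    for st, (mu, sd) in _STATE_INTENSITY.items():
        m = state == st
        intensity[m] = rng.normal(mu, sd, size=int(m.sum()))

    proj = ColonyProjection(*config.colony_lonlat)
    lon, lat = proj.to_lonlat(xy[:, 0] * 1000.0, xy[:, 1] * 1000.0)
    fixes = pd.DataFrame({"time": times, "lon": lon, "lat": lat, "flight_intensity": intensity})
    depths = pd.DataFrame({"time": depth_times, "depth_m": depth})

    mass_pre = phenotype.body_mass_g
    mass_post = max(1.0, mass_pre - rng.normal(20.0, 34.0))
    return Deployment(
        bird_id=bird_id, sex=sex, year=year, pair_id=pair_id,
        fixes=fixes, depths=depths,
        wing_mm=phenotype.wing_mm, head_bill_mm=phenotype.head_bill_mm,
        mass_pre_g=mass_pre, mass_post_g=mass_post,
        true_states=state.astype(str),
    )


def simulate_colony(config: SimConfig):
    """Simulate every bird in the study; returns (deployments, ground_truth).

    ``ground_truth`` maps bird_id → phenotype dict, plus the config under
    ``"_config"``.  All sub-streams derive deterministically from config.seed.
    """
    phen = draw_phenotypes(config)
    deployments = []
    truth = {"_config": config_to_dict(config), "phenotypes": {}}
    ss = np.random.SeedSequence([config.seed, 303])
    child_seeds = ss.spawn(2 * len(phen))
    k = 0
    for pid in sorted(phen):
        year = pid.split("P")[0]
        for sex, ph in zip(("F", "M"), phen[pid]):
            bid = f"{pid}{sex}"
            dep = simulate_track(ph, config, child_seeds[k], bird_id=bid, sex=sex, year=year, pair_id=pid)
            deployments.append(dep)
            truth["phenotypes"][bid] = ph.as_dict()
            k += 1
    return deployments, truth


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["colony_lonlat"] = list(d["colony_lonlat"])
    return d


def write_fixture_set(config: SimConfig, directory) -> dict:
    """Write one track CSV and one depth CSV per bird plus a metadata CSV and
    a ground-truth JSON; returns ``{relative_path: sha256}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    deployments, truth = simulate_colony(config)
    manifest = {}

    def _write(name: str, text: str):
        p = directory / name
        p.write_text(text)
        manifest[name] = hashlib.sha256(text.encode()).hexdigest()

    meta_rows = []
    for dep in deployments:
        tr = dep.fixes.copy()
        tr.insert(0, "bird_id", dep.bird_id)
        tr["timestamp_iso8601"] = tr.pop("time").dt.strftime("%Y-%m-%dT%H:%M:%S")
        tr = tr[["bird_id", "timestamp_iso8601", "lon", "lat", "flight_intensity"]]
        _write(f"track_{dep.bird_id}.csv", tr.to_csv(index=False, float_format="%.6f"))
        dp = dep.depths.copy()
        dp.insert(0, "bird_id", dep.bird_id)
        dp["timestamp_iso8601"] = dp.pop("time").dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
        dp = dp[["bird_id", "timestamp_iso8601", "depth_m"]]
        _write(f"depth_{dep.bird_id}.csv", dp.to_csv(index=False, float_format="%.2f"))
        meta_rows.append(
            {
                "bird_id": dep.bird_id, "sex": dep.sex, "year": dep.year, "pair_id": dep.pair_id,
                "wing_mm": round(dep.wing_mm, 2), "headbill_mm": round(dep.head_bill_mm, 2),
                "mass_pre_g": round(dep.mass_pre_g, 1), "mass_post_g": round(dep.mass_post_g, 1),
            }
        )
    _write("metadata.csv", pd.DataFrame(meta_rows).to_csv(index=False))
    _write("ground_truth.json", json.dumps(truth, indent=1, sort_keys=True))
    return manifest
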