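"""End-to-end orchestration: tracks → activities → trips → space use → pairs.

Stages (in order): ``simulate`` (optional), ``classify`` (regularize + HMM),
``trips`` (dives, trips, metrics), ``spaceuse`` (UDs + BA overlap matrix),
``pairs`` (pair table, model selection, permutation tests), ``report``.
Each stage writes its CSV artifact into the output directory and logs row
counts; everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geo import ColonyProjection
from .hmm import apply_colony_override, decode, default_spec, fit_hmm, regularize, attach_dives
from .pairs import build_pair_table, collinearity_filter, fit_candidates, matching_permutation_test, selection_table
from .spaceuse import bhattacharyya_overlap, href_bandwidth, kernel_ud
from .synth import Deployment, SimConfig, simulate_colony
from .trips import (
    audit_trips,
    deployment_summary,
    detect_dives,
    dives_to_frame,
    hourly_mean_depth,
    segment_trips,
    trips_to_frame,
)

log = logging.getLogger("pairforage")

STAGES = ("simulate", "classify", "trips", "spaceuse", "pairs", "report")

#: candidate |Δ| covariates per model-selection group
FORAGING_COVARIATES = [
    "mean_trip_distance_km", "max_colony_distance_km_mean", "total_distance_km",
    "trip_duration_h_mean", "total_trip_duration_h", "azimuth_deg_mean",
    "trips_per_day", "max_colony_distance_km_sd", "trip_duration_h_sd", "azimuth_deg_sd",
]
DIVING_COVARIATES = [
    "dives_per_day", "mean_dive_depth_m", "mean_dive_duration_min",
    "total_dive_duration_h", "mean_differential_depth_m",
    "max_dive_depth_m_sd", "mean_dive_duration_min_sd", "mean_differential_depth_m_sd",
]
MORPH_COVARIATES = ["wing_mm", "headbill_mm", "body_mass_g"]

#: columns z-scored after differencing, the conventional convergence aid
STANDARDIZE = ["max_colony_distance_km_mean", "total_distance_km", "mean_trip_distance_km", "wing_mm"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with study defaults.

    Trip/grid constants default to the reference configuration: 1-km colony
    radius, 20-min minimum trip, 5-min step, 200-m grid, 2720-m bandwidth,
    |r| > 0.8 collinearity cut, log(1+x) BA transform.
    """

    input_dir: str = ""
    output_dir: str = "pairforage_out"
    simulate: bool = True
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    colony_lonlat: tuple = (-82.019, 62.948)
    step_interval_s: float = 300.0
    max_gap_s: float = 1800.0
    hmm_max_iter: int = 60
    hmm_tol: float = 1e-6
    dive_min_depth_m: float = 1.0
    dive_min_duration_s: float = 3.0
    tz_offset_h: float = -5.0
    trip_min_dist_km: float = 1.0
    trip_min_duration_min: float = 20.0
    ud_cell_size_m: float = 200.0
    ud_bandwidth_m: float | None = 2720.0          # None → mean per-bird href
    ba_level: float = 0.5
    collinearity_threshold: float = 0.8
    n_perm: int = 999
    weight_mode: str = "balanced"
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        self.colony_lonlat = tuple(self.colony_lonlat)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["colony_lonlat"] = list(d["colony_lonlat"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, colony_lonlat=self.colony_lonlat, **self.sim)


def load_deployments(input_dir) -> list[Deployment]:
    """Read the fixture-format CSVs (track_*.csv, depth_*.csv, metadata.csv)."""
    input_dir = Path(input_dir)
    meta = pd.read_csv(input_dir / "metadata.csv", dtype={"year": str})
    deployments = []
    for _, r in meta.iterrows():
        tr = pd.read_csv(input_dir / f"track_{r['bird_id']}.csv", parse_dates=["timestamp_iso8601"])
        tr = tr.rename(columns={"timestamp_iso8601": "time"})
        dp = pd.read_csv(input_dir / f"depth_{r['bird_id']}.csv", parse_dates=["timestamp_iso8601"])
        dp = dp.rename(columns={"timestamp_iso8601": "time"})
        deployments.append(
            Deployment(
                bird_id=r["bird_id"], sex=r["sex"], year=str(r["year"]), pair_id=r["pair_id"],
                fixes=tr[[c for c in ("time", "lon", "lat", "flight_intensity") if c in tr.columns]],
                depths=dp[["time", "depth_m"]],
                wing_mm=float(r["wing_mm"]), head_bill_mm=float(r["headbill_mm"]),
                mass_pre_g=float(r["mass_pre_g"]), mass_post_g=float(r["mass_post_g"]),
            )
        )
    return deployments


def run_pipeline(config: PipelineConfig, upto: str | None = None) -> dict:
    """Execute the stage chain; returns the results bundle (also written to
    ``<output_dir>/results.json``).  ``upto`` runs the prefix ending at that
    stage."""
    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; stages are {STAGES}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (out / "config.yaml").write_text(config.to_yaml())

    # ---- simulate / load -------------------------------------------------
    if config.simulate:
        deployments, truth = simulate_colony(config.sim_config())
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    else:
        if not config.input_dir:
            raise ValueError("input_dir required when simulate is false")
        deployments = load_deployments(config.input_dir)
    log.info("stage simulate/load: %d deployments", len(deployments))
    if upto == "simulate":
        return bundle

    # ---- classify --------------------------------------------------------
    series_by_bird = {}
    dives_by_bird = {}
    for dep in deployments:
        s = regularize(dep.fixes, config.colony_lonlat, bird_id=dep.bird_id,
                       interval_s=config.step_interval_s, max_gap_s=config.max_gap_s)
        dv = detect_dives(dep.depths, min_depth=config.dive_min_depth_m,
                          min_duration_s=config.dive_min_duration_s, tz_offset_h=config.tz_offset_h)
        attach_dives(s, dv)
        series_by_bird[dep.bird_id] = s
        dives_by_bird[dep.bird_id] = dv
    spec, report = fit_hmm(list(series_by_bird.values()), default_spec(),
                           max_iter=config.hmm_max_iter, tol=config.hmm_tol, seed=config.seed)
    paths = {}
    rows = []
    for bid, s in series_by_bird.items():
        p = apply_colony_override(decode(s, spec), s, spec, radius_km=config.trip_min_dist_km)
        paths[bid] = p
        rows.append(s.to_frame(states=p.states))
    steps_df = pd.concat(rows, ignore_index=True)
    steps_df.to_csv(out / "steps.csv", index=False)
    bundle["hmm"] = {"loglik": report.loglik, "n_iter": report.n_iter, "converged": report.converged}
    log.info("stage classify: %d steps, HMM ll=%.1f", len(steps_df), report.loglik)
    if upto == "classify":
        return bundle

    # ---- trips -----------------------------------------------------------
    trips_by_bird = {}
    for dep in deployments:
        t = segment_trips(series_by_bird[dep.bird_id], dives_by_bird[dep.bird_id],
                          min_dist_km=config.trip_min_dist_km,
                          min_duration_min=config.trip_min_duration_min)
        audit_trips(t, config.trip_min_dist_km, config.trip_min_duration_min)
        trips_by_bird[dep.bird_id] = t

    hourly_by_year = {}
    for year in sorted({d.year for d in deployments}):
        year_dives = [dv for d in deployments if d.year == year for dv in dives_by_bird[d.bird_id]]
        if year_dives:
            hourly_by_year[year] = hourly_mean_depth(year_dives)

    metrics_rows = []
    excluded = []
    for dep in deployments:
        trips = trips_by_bird[dep.bird_id]
        if not trips:
            excluded.append(dep.bird_id)
            log.warning("bird %s: no kept trips; excluded from pairing analysis", dep.bird_id)
            continue
        bm = deployment_summary(trips, dives_by_bird[dep.bird_id], paths[dep.bird_id],
                                series_by_bird[dep.bird_id], hourly_by_year[dep.year])
        row = bm.as_series()
        row["bird_id"] = dep.bird_id
        row["sex"] = dep.sex
        row["year"] = dep.year
        row["pair_id"] = dep.pair_id
        row["wing_mm"] = dep.wing_mm
        row["headbill_mm"] = dep.head_bill_mm
        row["body_mass_g"] = 0.5 * (dep.mass_pre_g + dep.mass_post_g)
        row["mass_pre_g"] = dep.mass_pre_g
        row["mass_post_g"] = dep.mass_post_g
        metrics_rows.append(row)
    metrics = pd.DataFrame(metrics_rows).reset_index(drop=True)
    all_trips = [t for ts in trips_by_bird.values() for t in ts]
    trips_to_frame(all_trips).to_csv(out / "trips.csv", index=False)
    pd.concat(
        [dives_to_frame(dives_by_bird[d.bird_id]).assign(bird_id=d.bird_id) for d in deployments],
        ignore_index=True,
    ).to_csv(out / "dives.csv", index=False)
    metrics.to_csv(out / "bird_metrics.csv", index=False)
    bundle["trips"] = {"n_trips": len(all_trips), "n_birds_kept": len(metrics), "excluded": excluded}
    log.info("stage trips: %d trips across %d birds", len(all_trips), len(metrics))
    if upto == "trips":
        return bundle

    # ---- spaceuse --------------------------------------------------------
    proj = ColonyProjection(*config.colony_lonlat)
    uds = {}
    hrefs = {}
    for dep in deployments:
        s = series_by_bird[dep.bird_id]
        idx = np.zeros(len(s), dtype=bool)
        for t in trips_by_bird[dep.bird_id]:
            idx[t.step_slice[0] : t.step_slice[1]] = True
        if idx.sum() < 5:
            continue
        x, y = proj.to_xy_m(s.lon[idx], s.lat[idx])
        pts = np.column_stack([x, y])
        try:
            hrefs[dep.bird_id] = href_bandwidth(pts)
        except ValueError:
            pass
        uds[dep.bird_id] = pts
    h = config.ud_bandwidth_m if config.ud_bandwidth_m else float(np.mean(list(hrefs.values())))
    uds = {bid: kernel_ud(pts, h=h, cell_size=config.ud_cell_size_m) for bid, pts in uds.items()}

    ba_rows = []
    meta = {d.bird_id: d for d in deployments}
    for year in sorted({d.year for d in deployments}):
        fem = [b for b in uds if meta[b].year == year and meta[b].sex == "F"]
        mal = [b for b in uds if meta[b].year == year and meta[b].sex == "M"]
        for f in fem:
            for m in mal:
                ba_rows.append(
                    {"female_id": f, "male_id": m, "year": year,
                     "ba": bhattacharyya_overlap(uds[f], uds[m], level=config.ba_level)}
                )
    ba_df = pd.DataFrame(ba_rows)
    ba_df.to_csv(out / "ba_overlap.csv", index=False)
    bundle["spaceuse"] = {
        "bandwidth_m": h,
        "href_mean_m": float(np.mean(list(hrefs.values()))) if hrefs else float("nan"),
        "n_uds": len(uds),
    }
    log.info("stage spaceuse: %d UDs, h=%.0f m", len(uds), h)
    if upto == "spaceuse":
        return bundle

    # ---- pairs -----------------------------------------------------------
    observed = {}
    for pid, grp in metrics.groupby("pair_id"):
        f = grp[grp["sex"] == "F"]["bird_id"]
        m = grp[grp["sex"] == "M"]["bird_id"]
        if len(f) == 1 and len(m) == 1:
            observed[f.iloc[0]] = m.iloc[0]

    groups = {}
    for gname, cands in (("foraging", FORAGING_COVARIATES), ("diving", DIVING_COVARIATES),
                         ("morphology", MORPH_COVARIATES)):
        cands = [c for c in cands if c in metrics.columns and metrics[c].notna().all()]
        retained, dropped = collinearity_filter(metrics[cands], threshold=config.collinearity_threshold)
        groups[gname] = {"candidates": retained, "collinear_dropped": dropped}

    traits = sorted({c for g in groups.values() for c in g["candidates"]})
    ba_matrix = ba_df.pivot(index="female_id", columns="male_id", values="ba") if len(ba_df) else None
    table = build_pair_table(
        metrics, observed, traits,
        standardize_set=[c for c in STANDARDIZE if c in traits],
        ba_matrix=ba_matrix, weight_mode=config.weight_mode,
    )
    table.to_csv(out / "pair_table.csv", index=False, float_format="%.6f")

    results = {"groups": {}, "n_rows": len(table), "n_real": int(table["is_real"].sum())}
    for gname, g in groups.items():
        fits = fit_candidates(table, [c for c in g["candidates"] if c in table.columns])
        sel = selection_table(fits)
        sel.to_csv(out / f"model_selection_{gname}.csv", index=False, float_format="%.4f")
        best = fits[0]
        results["groups"][gname] = {
            "selection": sel.to_dict(orient="records"),
            "collinear_dropped": [list(r) for r in g["collinear_dropped"]],
            "best_model": best.label,
            "best_coef": dict(zip(best.columns, best.coef.tolist())),
            "best_se": dict(zip(best.columns, best.se.tolist())),
            "best_p": dict(zip(best.columns, best.pvalues().tolist())),
        }
    if "log1p_BA" in table.columns:
        fits = fit_candidates(table, ["log1p_BA"])
        sel = selection_table(fits)
        sel.to_csv(out / "model_selection_overlap.csv", index=False, float_format="%.4f")
        results["groups"]["overlap"] = {
            "selection": sel.to_dict(orient="records"),
            "best_model": fits[0].label,
            "best_coef": dict(zip(fits[0].columns, fits[0].coef.tolist())),
        }

    perms = {}
    for trait in ("mean_trip_distance_km", "dives_per_day", "wing_mm"):
        if trait in table.columns:
            p, t_obs, _ = matching_permutation_test(table, trait, n_perm=config.n_perm, seed=config.seed)
            perms[trait] = {"p": p, "statistic": t_obs, "n_perm": config.n_perm}
    results["permutation_tests"] = perms
    bundle["pairs"] = results
    log.info("stage pairs: %d rows (%d real)", len(table), int(table["is_real"].sum()))

    (out / "results.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle
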