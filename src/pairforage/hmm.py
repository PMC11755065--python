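"""Track regularization and 4-state activity classification.

Raw GPS fixes (~3-min cadence) are resampled to a regular 5-min grid, turned
into a feature series (step length, distance from the colony, dive indicator,
flight intensity), and classified into four activities — at the colony,
diving, flying, swimming — with a hidden Markov model.

Emission families: step length ~ Gamma, flight intensity ~ Normal, dive
indicator ~ Bernoulli, all independent given the state.  Distance from the
colony is not modelled as an emission; instead steps within 1 km of the
colony with no dive are forced to the colony state after decoding (the
splashdown filter).  All recursions run in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp, polygamma
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist

from .geo import gc_interpolate, haversine_km

STATES = ("colony", "diving", "flying", "swimming")
_LOG_FLOOR = math.log(1e-300)
_STEP_FLOOR_KM = 1e-3   # Gamma emissions need strictly positive step lengths


@dataclass
class StepSeries:
    """Regular 5-min feature series for one deployment."""

    bird_id: str
    times: np.ndarray            # datetime64[ms], strict 300-s grid
    lon: np.ndarray
    lat: np.ndarray
    step_km: np.ndarray          # great-circle length of the step ending here
    colony_dist_km: np.ndarray
    dive: np.ndarray             # bool: any dive overlapping this step
    flight_intensity: np.ndarray
    interpolated: np.ndarray     # bool: position imputed across a long gap
    interval_s: float = 300.0
    colony_lonlat: tuple | None = None

    def __post_init__(self):
        if len(self.times) > 1:
            dts = np.diff(self.times).astype("timedelta64[ms]").astype(float) / 1000.0
            if not np.allclose(dts, self.interval_s):
                raise ValueError("grid spacing must equal interval_s exactly")
        if (np.asarray(self.step_km) < 0).any() or (np.asarray(self.colony_dist_km) < 0).any():
            raise ValueError("step lengths and colony distances must be >= 0")

    def __len__(self):
        return len(self.times)

    def to_frame(self, states=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bird_id": self.bird_id,
                "time": self.times,
                "lon": self.lon,
                "lat": self.lat,
                "step_km": self.step_km,
                "colonydist_km": self.colony_dist_km,
                "dive": self.dive.astype(int),
                "interp": self.interpolated.astype(int),
            }
        )
        if states is not None:
            df["state"] = states
        return df


@dataclass
class HMMSpec:
    """Four-state HMM parameters with per-state emission families."""

    pi: np.ndarray
    A: np.ndarray
    gamma_shape: np.ndarray
    gamma_rate: np.ndarray
    norm_mu: np.ndarray
    norm_sd: np.ndarray
    bern_p: np.ndarray
    labels: tuple = STATES

    def __post_init__(self):
        for name in ("pi", "A", "gamma_shape", "gamma_rate", "norm_mu", "norm_sd", "bern_p"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        S = len(self.labels)
        if self.A.shape != (S, S):
            raise ValueError("A must be S x S")
        if abs(self.pi.sum() - 1.0) > 1e-10 or np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("pi and rows of A must sum to 1")
        if (self.gamma_shape <= 0).any() or (self.gamma_rate <= 0).any() or (self.norm_sd <= 0).any():
            raise ValueError("Gamma parameters and normal SDs must be > 0")
        if ((self.bern_p < 0) | (self.bern_p > 1)).any():
            raise ValueError("Bernoulli p must be in [0, 1]")

    @property
    def n_states(self):
        return len(self.labels)


def default_spec() -> HMMSpec:
    """Starting values: sticky transitions, emissions separated by activity.

    Step-length means: ~50 m at the colony, ~200 m diving, ~5 km flying
    (60 km/h over 5 min), ~400 m swimming.  Flight intensity (wing-beat
    stand-in) high only in flight; dive indicator concentrated on the diving
    state (0.95 vs <= 0.05).
    """
    means_km = np.array([0.05, 0.25, 5.0, 0.45])
    shape = np.array([1.2, 1.5, 8.0, 1.5])
    return HMMSpec(
        pi=np.array([0.85, 0.05, 0.05, 0.05]),
        A=np.array(
            [
                [0.95, 0.01, 0.03, 0.01],
                [0.01, 0.80, 0.04, 0.15],
                [0.04, 0.03, 0.85, 0.08],
                [0.02, 0.15, 0.08, 0.75],
            ]
        ),
        gamma_shape=shape,
        gamma_rate=shape / means_km,
        norm_mu=np.array([0.6, 3.0, 8.0, 1.5]),
        norm_sd=np.array([0.4, 0.8, 1.0, 0.5]),
        bern_p=np.array([0.02, 0.95, 0.02, 0.05]),
    )


def sample_from_spec(spec: HMMSpec, T: int, seed, bird_id: str = "sim") -> tuple:
    """Sample a state path and a matching StepSeries from an HMMSpec.

    Colony distance is filled with a constant 5 km (outside the splashdown
    radius) so decoding is driven purely by the emissions; intended for
    simulation-based validation of fitting and decoding.
    """
    rng = np.random.default_rng(seed)
    S = spec.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(S, p=spec.pi)
    for t in range(1, T):
        states[t] = rng.choice(S, p=spec.A[states[t - 1]])
    step = rng.gamma(spec.gamma_shape[states], 1.0 / spec.gamma_rate[states])
    fi = rng.normal(spec.norm_mu[states], spec.norm_sd[states])
    dive = rng.random(T) < spec.bern_p[states]
    times = np.datetime64("2022-07-25T00:00:00", "ms") + (np.arange(T) * 300000).astype("timedelta64[ms]")
    series = StepSeries(
        bird_id=bird_id, times=times, lon=np.zeros(T), lat=np.zeros(T),
        step_km=step, colony_dist_km=np.full(T, 5.0), dive=dive,
        flight_intensity=fi, interpolated=np.zeros(T, dtype=bool),
    )
    return states, series


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

class EmptySeries(Exception):
    """Raised when a track has too few fixes to regularize."""


def regularize(
    fixes: pd.DataFrame,
    colony_lonlat,
    bird_id: str = "",
    interval_s: float = 300.0,
    max_gap_s: float = 1800.0,
) -> StepSeries:
    """Resample a track to a regular grid by great-circle interpolation.

    Positions at grid times inside a fix gap no longer than ``max_gap_s`` are
    slerped between the bracketing fixes; positions inside longer gaps are
    still filled (so the grid stays complete) but flagged ``interpolated`` so
    downstream metrics can exclude them.  Grid anchored at the first fix.
    """
    if len(fixes) < 2:
        raise EmptySeries(f"need >= 2 fixes, got {len(fixes)}")
    t = fixes["time"].to_numpy().astype("datetime64[ms]")
    if not (np.diff(t).astype(float) > 0).all():
        raise ValueError("fix timestamps must be strictly increasing")
    tsec = (t - t[0]).astype(float) / 1000.0
    total = tsec[-1]
    n = int(total // interval_s) + 1
    grid = np.arange(n) * interval_s
    lon = np.empty(n)
    lat = np.empty(n)
    interp_flag = np.zeros(n, dtype=bool)
    intens = np.empty(n)
    has_int = "flight_intensity" in fixes.columns
    fi = fixes["flight_intensity"].to_numpy() if has_int else np.zeros(len(fixes))
    flon = fixes["lon"].to_numpy()
    flat = fixes["lat"].to_numpy()

    idx = np.searchsorted(tsec, grid, side="right") - 1
    idx = np.clip(idx, 0, len(tsec) - 2)
    for k in range(n):
        i = idx[k]
        gap = tsec[i + 1] - tsec[i]
        if grid[k] == tsec[i]:
            lon[k], lat[k] = flon[i], flat[i]
        else:
            frac = (grid[k] - tsec[i]) / gap
            lo, la = gc_interpolate(flon[i], flat[i], flon[i + 1], flat[i + 1], np.array([frac]))
            lon[k], lat[k] = lo[0], la[0]
            if gap > max_gap_s:
                interp_flag[k] = True
        intens[k] = fi[i] if (grid[k] - tsec[i]) <= (tsec[i + 1] - grid[k]) else fi[i + 1]

    step = np.zeros(n)
    if n > 1:
        step[1:] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    cdist = haversine_km(colony_lonlat[0], colony_lonlat[1], lon, lat)
    times = t[0] + (grid * 1000).astype("timedelta64[ms]")
    return StepSeries(
        bird_id=bird_id, times=times, lon=lon, lat=lat, step_km=step,
        colony_dist_km=np.asarray(cdist), dive=np.zeros(n, dtype=bool),
        flight_intensity=intens, interpolated=interp_flag, interval_s=interval_s,
        colony_lonlat=tuple(colony_lonlat),
    )


def attach_dives(series: StepSeries, dives) -> StepSeries:
    """Set the per-step dive indicator: true if any dive overlaps the step
    window [t, t + interval)."""
    flag = np.zeros(len(series), dtype=bool)
    t0 = series.times[0]
    for d in dives:
        s = (np.datetime64(d.start, "ms") - t0).astype(float) / 1000.0
        e = (np.datetime64(d.end, "ms") - t0).astype(float) / 1000.0
        k0 = max(0, int(s // series.interval_s))
        k1 = min(len(series) - 1, int(e // series.interval_s))
        if k1 >= 0 and k0 < len(series):
            flag[k0 : k1 + 1] = True
    series.dive = flag
    return series


# ---------------------------------------------------------------------------
# likelihood machinery (log space throughout)
# ---------------------------------------------------------------------------

def log_emissions(series: StepSeries, spec: HMMSpec) -> np.ndarray:
    """(T, S) matrix of per-step log emission densities, floored at 1e-300."""
    x = np.maximum(series.step_km, _STEP_FLOOR_KM)[:, None]
    fi = series.flight_intensity[:, None]
    dv = series.dive.astype(float)[:, None]
    ll = gamma_dist.logpdf(x, spec.gamma_shape[None, :], scale=1.0 / spec.gamma_rate[None, :])
    ll += norm_dist.logpdf(fi, spec.norm_mu[None, :], spec.norm_sd[None, :])
    p = np.clip(spec.bern_p, 1e-12, 1 - 1e-12)[None, :]
    ll += dv * np.log(p) + (1.0 - dv) * np.log1p(-p)
    bad = ~np.isfinite(ll) | (ll < _LOG_FLOOR)
    if bad.all(axis=1).any():
        warnings.warn("zero-likelihood observation under all states; flooring emissions")
    ll[bad] = _LOG_FLOOR
    return ll


def _forward_batch(logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray):
    """Batched forward pass.  logB: (B, T, S).  Returns (logalpha, loglik(B,))."""
    Bn, T, S = logB.shape
    logalpha = np.empty((Bn, T, S))
    logalpha[:, 0] = log_pi[None, :] + logB[:, 0]
    for t in range(1, T):
        logalpha[:, t] = logsumexp(logalpha[:, t - 1, :, None] + log_A[None], axis=1) + logB[:, t]
    return logalpha, logsumexp(logalpha[:, -1], axis=1)


def _backward_batch(logB: np.ndarray, log_A: np.ndarray):
    Bn, T, S = logB.shape
    logbeta = np.zeros((Bn, T, S))
    for t in range(T - 2, -1, -1):
        logbeta[:, t] = logsumexp(log_A[None] + logB[:, t + 1, None, :] + logbeta[:, t + 1, None, :], axis=2)
    return logbeta


def forward_loglik(series: StepSeries, spec: HMMSpec) -> float:
    """Log-likelihood of one series under the spec (forward algorithm)."""
    logB = log_emissions(series, spec)[None]
    with np.errstate(divide="ignore"):
        _, ll = _forward_batch(logB, np.log(spec.pi), np.log(spec.A))
    return float(ll[0])


@dataclass
class FitReport:
    converged: bool
    n_iter: int
    loglik_path: list = field(default_factory=list)
    n_restarts: int = 0

    @property
    def loglik(self):
        return self.loglik_path[-1] if self.loglik_path else -np.inf


class DegenerateFit(Exception):
    """EM collapsed: some state holds essentially no posterior mass."""


def _weighted_gamma_mle(x, w):
    """Weighted Gamma MLE via Newton on the shape; returns (shape, rate)."""
    wsum = w.sum()
    m = float(np.dot(w, x) / wsum)
    lbar = float(np.dot(w, np.log(x)) / wsum)
    s = math.log(m) - lbar
    s = max(s, 1e-8)
    k = (3.0 - s + math.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(25):
        g = math.log(k) - digamma(k) - s
        h = 1.0 / k - polygamma(1, k)
        step = g / h
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    k = min(max(k, 1e-3), 1e4)
    return k, k / m


def _em_pass(series_list, spec: HMMSpec):
    """One E+M sweep over all series; returns (new_spec, total loglik)."""
    S = spec.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(spec.pi, 1e-300))
        log_A = np.log(np.maximum(spec.A, 1e-300))

    total_ll = 0.0
    pi_acc = np.zeros(S)
    xi_acc = np.zeros((S, S))
    post_chunks, step_chunks, fi_chunks, dv_chunks = [], [], [], []

    by_len: dict[int, list[StepSeries]] = {}
    for s in series_list:
        by_len.setdefault(len(s), []).append(s)

    for T, group in by_len.items():
        logB = np.stack([log_emissions(s, spec) for s in group])   # (B,T,S)
        logalpha, ll = _forward_batch(logB, log_pi, log_A)
        logbeta = _backward_batch(logB, log_A)
        total_ll += float(ll.sum())
        loggamma = logalpha + logbeta - ll[:, None, None]
        post = np.exp(loggamma)
        pi_acc += post[:, 0].sum(axis=0)
        if T > 1:
            # xi: (B, T-1, S, S)
            num = (
                logalpha[:, :-1, :, None]
                + log_A[None, None]
                + logB[:, 1:, None, :]
                + logbeta[:, 1:, None, :]
                - ll[:, None, None, None]
            )
            xi_acc += np.exp(logsumexp(num, axis=(0, 1)))
        post_chunks.append(post.reshape(-1, S))
        step_chunks.append(np.concatenate([np.maximum(s.step_km, _STEP_FLOOR_KM) for s in group]))
        fi_chunks.append(np.concatenate([s.flight_intensity for s in group]))
        dv_chunks.append(np.concatenate([s.dive.astype(float) for s in group]))

    post = np.concatenate(post_chunks)
    steps = np.concatenate(step_chunks)
    fis = np.concatenate(fi_chunks)
    dvs = np.concatenate(dv_chunks)

    if not np.isfinite(total_ll):
        raise DegenerateFit(f"non-finite log-likelihood: {total_ll}")
    mass = post.sum(axis=0)
    starved = mass < 1e-6
    if starved.any():
        # benign degenerate limit (e.g. one-activity data): freeze the
        # starved states' parameters instead of dividing by ~zero mass
        warnings.warn(f"states {np.nonzero(starved)[0].tolist()} hold no posterior mass; parameters frozen")

    new_pi = pi_acc / pi_acc.sum()
    rowsum = xi_acc.sum(axis=1, keepdims=True)
    new_A = np.where(rowsum > 1e-12, xi_acc / np.maximum(rowsum, 1e-300), spec.A)
    new_A /= new_A.sum(axis=1, keepdims=True)

    shape = spec.gamma_shape.copy()
    rate = spec.gamma_rate.copy()
    mu = spec.norm_mu.copy()
    sd = spec.norm_sd.copy()
    p = spec.bern_p.copy()
    for j in range(S):
        if starved[j]:
            continue
        w = post[:, j]
        shape[j], rate[j] = _weighted_gamma_mle(steps, w)
        mu[j] = np.dot(w, fis) / mass[j]
        var = np.dot(w, (fis - mu[j]) ** 2) / mass[j]
        sd[j] = math.sqrt(max(var, 1e-6))
        p[j] = min(max(np.dot(w, dvs) / mass[j], 1e-4), 1 - 1e-4)
    new_spec = HMMSpec(pi=new_pi, A=new_A, gamma_shape=shape, gamma_rate=rate,
                       norm_mu=mu, norm_sd=sd, bern_p=p, labels=spec.labels)
    return new_spec, total_ll


def _jitter_spec(spec: HMMSpec, rng) -> HMMSpec:
    A = spec.A * np.exp(rng.normal(0, 0.2, spec.A.shape))
    A /= A.sum(axis=1, keepdims=True)
    pi = spec.pi * np.exp(rng.normal(0, 0.2, spec.pi.shape))
    return HMMSpec(
        pi=pi / pi.sum(), A=A,
        gamma_shape=spec.gamma_shape * np.exp(rng.normal(0, 0.1, 4)),
        gamma_rate=spec.gamma_rate * np.exp(rng.normal(0, 0.1, 4)),
        norm_mu=spec.norm_mu + rng.normal(0, 0.2, 4),
        norm_sd=spec.norm_sd * np.exp(rng.normal(0, 0.1, 4)),
        bern_p=np.clip(spec.bern_p + rng.normal(0, 0.02, 4), 1e-4, 1 - 1e-4),
        labels=spec.labels,
    )


def fit_hmm(series_list, spec0: HMMSpec | None = None, max_iter: int = 100,
            tol: float = 1e-6, max_restarts: int = 5, seed: int = 0):
    """Baum-Welch EM over a collection of step series.

    The log-likelihood is non-decreasing across iterations; the fit stops at
    relative improvement < ``tol`` or ``max_iter``.  A starved state (total
    posterior mass < 1e-6) keeps its current parameters with a warning — the
    benign limit when the data exercise fewer than four activities; a
    non-finite likelihood triggers a jittered restart, at most
    ``max_restarts`` times, then fails loudly.  Returns (spec, FitReport).
    """
    if spec0 is None:
        spec0 = default_spec()
    rng = np.random.default_rng(seed)
    spec_init = spec0
    last_err = None
    for attempt in range(max_restarts + 1):
        spec = spec_init
        report = FitReport(converged=False, n_iter=0, n_restarts=attempt)
        try:
            prev_ll = -np.inf
            for it in range(max_iter):
                spec_new, ll = _em_pass(series_list, spec)
                report.loglik_path.append(ll)
                report.n_iter = it + 1
                if np.isfinite(prev_ll) and ll + 1e-9 * max(1.0, abs(ll)) < prev_ll:
                    warnings.warn(f"EM log-likelihood decreased at iter {it}: {prev_ll} -> {ll}")
                if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
                    report.converged = True
                    spec = spec_new
                    break
                spec = spec_new
                prev_ll = ll
            return spec, report
        except DegenerateFit as err:
            last_err = err
            spec_init = _jitter_spec(spec0, rng)
    raise DegenerateFit(f"EM degenerate after {max_restarts} restarts: {last_err}")


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

@dataclass
class StatePath:
    """Decoded activity sequence with per-step posteriors."""

    states: np.ndarray          # str labels per step
    state_idx: np.ndarray
    posteriors: np.ndarray      # (T, S), rows sum to 1
    loglik: float               # forward log-likelihood of the observations
    path_logprob: float         # joint log-prob of the Viterbi path


def decode(series: StepSeries, spec: HMMSpec) -> StatePath:
    """Global MAP (Viterbi) path plus forward-backward posteriors.

    Ties in the Viterbi maximization break toward the lower state index.
    """
    logB = log_emissions(series, spec)
    T, S = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(spec.pi, 1e-300))
        log_A = np.log(np.maximum(spec.A, 1e-300))

    # Viterbi
    delta = np.empty((T, S))
    psi = np.zeros((T, S), dtype=int)
    delta[0] = log_pi + logB[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_A
        psi[t] = np.argmax(cand, axis=0)            # argmax → first (lowest) index on ties
        delta[t] = cand[psi[t], np.arange(S)] + logB[t]
    idx = np.empty(T, dtype=int)
    idx[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        idx[t] = psi[t + 1, idx[t + 1]]

    logalpha, ll = _forward_batch(logB[None], log_pi, log_A)
    logbeta = _backward_batch(logB[None], log_A)
    post = np.exp(logalpha[0] + logbeta[0] - ll[0])
    post /= post.sum(axis=1, keepdims=True)
    labels = np.asarray(spec.labels, dtype=object)[idx].astype(str)
    return StatePath(states=labels, state_idx=idx, posteriors=post,
                     loglik=float(ll[0]), path_logprob=float(delta[-1, idx[-1]]))


def apply_colony_override(path: StatePath, series: StepSeries, spec: HMMSpec,
                          radius_km: float = 1.0) -> StatePath:
    """Force steps within ``radius_km`` of the colony and with no dive to the
    colony state (the splashdown filter applied after decoding)."""
    mask = (series.colony_dist_km < radius_km) & (~series.dive)
    j = list(spec.labels).index("colony")
    idx = path.state_idx.copy()
    idx[mask] = j
    labels = np.asarray(spec.labels, dtype=object)[idx].astype(str)
    return StatePath(states=labels, state_idx=idx, posteriors=path.posteriors,
                     loglik=path.loglik, path_logprob=path.path_logprob)
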