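"""Real-vs-randomized breeding-pair inference.

The contrast at the heart of the analysis: cross every tracked female with
every tracked male of the same season (19 × 19 = 361 and 21 × 21 = 441 rows
in the reference design, 802 in total), take per-trait absolute differences
|female − male|, flag the observed breeding pairs (is_real = 1, n = 40), and
ask whether real pairs are more or less different than the randomized
combinations.  Inference is a weighted binomial logistic regression (IRLS)
with AICc model selection across single-covariate candidates, plus an exact
matching-permutation test whose null redraws random perfect matchings of
females to males within each year — respecting that every bird appears in
many rows but in exactly one real pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def build_pair_table(
    metrics_by_bird: pd.DataFrame,
    observed_pairs: dict,
    traits,
    standardize_set=(),
    ba_matrix: pd.DataFrame | None = None,
    weight_mode: str = "balanced",
) -> pd.DataFrame:
    """Build the full female × male cross product per year.

    ``metrics_by_bird``: one row per bird with columns bird_id, sex, year and
    one column per trait.  ``observed_pairs``: {female_id: male_id} of real
    pairs.  Trait columns become |Δ| = |female − male|; those named in
    ``standardize_set`` are z-scored across all rows after differencing.  An
    optional ``ba_matrix`` (index female_id, columns male_id) adds a
    log(1+BA) column.  Weights: real pairs carry n_randomized/n_real within
    their year, randomized pairs 1 (total class weights balanced); with
    ``weight_mode="none"`` all weights are 1.
    """
    df = metrics_by_bird
    rows = []
    for year, sub in df.groupby("year", sort=True):
        females = sub[sub["sex"] == "F"]
        males = sub[sub["sex"] == "M"]
        for _, f in females.iterrows():
            for _, m in males.iterrows():
                row = {
                    "female_id": f["bird_id"],
                    "male_id": m["bird_id"],
                    "year": year,
                    "is_real": int(observed_pairs.get(f["bird_id"]) == m["bird_id"]),
                }
                ok = True
                for t in traits:
                    fv, mv = f[t], m[t]
                    if pd.isna(fv) or pd.isna(mv):
                        warnings.warn(f"dropping pair {f['bird_id']}x{m['bird_id']}: missing {t}")
                        ok = False
                        break
                    row[t] = abs(fv - mv)
                if not ok:
                    continue
                if ba_matrix is not None:
                    ba = float(ba_matrix.loc[f["bird_id"], m["bird_id"]])
                    row["log1p_BA"] = math.log1p(ba)
                rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("empty pair table")
    # weights balance total class mass within year
    w = np.ones(len(table))
    if weight_mode == "balanced":
        for year, sub in table.groupby("year"):
            n_real = int(sub["is_real"].sum())
            n_rand = len(sub) - n_real
            if n_real > 0:
                w[sub.index[sub["is_real"] == 1]] = n_rand / n_real
    table["weight"] = w
    for t in standardize_set:
        col = table[t].to_numpy(dtype=float)
        sd = col.std(ddof=1)
        if sd == 0:
            warnings.warn(f"cannot standardize constant column {t}")
            continue
        table[t] = (col - col.mean()) / sd
    return table


def collinearity_filter(trait_matrix: pd.DataFrame, threshold: float = 0.8):
    """Drop all but one variable from each strongly correlated group.

    Pearson |r| > ``threshold`` links variables; within a linked set the
    "mean" variant of a metric is preferred over "max"/"min"/"total"/"sd"
    variants (lexical rule on column names), then the earlier column wins.
    Returns (retained column list, list of (kept, dropped, r) records).
    """
    if trait_matrix.shape[1] < 2:
        raise ValueError("need >= 2 traits")
    cols = [c for c in trait_matrix.columns]
    const = [c for c in cols if trait_matrix[c].std(ddof=0) == 0 or trait_matrix[c].isna().any()]
    for c in const:
        warnings.warn(f"excluding column {c}: constant or missing values")
    cols = [c for c in cols if c not in const]
    corr = trait_matrix[cols].corr()

    def rank(name: str):
        n = name.lower()
        # prefer mean variants; penalize max/min/total/sd variants
        bad = any(tag in n for tag in ("max", "min", "total", "_sd", "sd_"))
        good = "mean" in n or "average" in n
        return (0 if good else 1, 1 if bad else 0)

    dropped = {}
    records = []
    order = sorted(cols, key=lambda c: (rank(c), cols.index(c)))
    for c in order:
        if c in dropped:
            continue
        for other in cols:
            if other == c or other in dropped:
                continue
            r = corr.loc[c, other]
            if abs(r) > threshold:
                dropped[other] = (c, float(r))
                records.append((c, other, float(r)))
    retained = [c for c in cols if c not in dropped]
    return retained, records


# ---------------------------------------------------------------------------
# weighted logistic regression (IRLS)
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    pass


@dataclass
class FitResult:
    """One fitted candidate model."""

    label: str
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    k: int
    n: int
    columns: list = field(default_factory=list)
    aicc: float = float("nan")
    delta_aicc: float = float("nan")
    aicc_weight: float = float("nan")

    @property
    def deviance(self):
        return -2.0 * self.loglik

    @property
    def aic(self):
        return -2.0 * self.loglik + 2.0 * self.k

    def zvalues(self):
        return self.coef / self.se

    def pvalues(self):
        return 2.0 * stats.norm.sf(np.abs(self.zvalues()))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: −2ll + 2k + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def weighted_logistic_loglik(beta, X, y, w):
    """Weighted Bernoulli log-likelihood at beta (stable log1p form)."""
    eta = X @ np.asarray(beta, dtype=float)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    label: str = "model",
    columns=None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Maximize the weighted Bernoulli log-likelihood by IRLS.

    ``X`` must include its intercept column if one is wanted.  Convergence:
    max |Δβ| < ``tol``.  Diverging coefficients (complete separation) raise
    ``SeparationError``; a constant response raises ``ValueError``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate response: y is constant")
    if n <= k:
        raise ValueError("need n > k")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be > 0")

    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        s = np.clip(mu * (1.0 - mu), 1e-12, None)
        W = w * s
        z = eta + (y - mu) / s
        XtW = X.T * W
        H = XtW @ X
        try:
            beta_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise SeparationError(f"singular information matrix: {err}") from None
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(X @ beta)) > 40.0:
            raise SeparationError("perfect separation: linear predictor diverging")
        if step < tol:
            break
    else:
        warnings.warn(f"IRLS did not reach tol={tol} in {max_iter} iterations")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = w * np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * W) @ X)
    se = np.sqrt(np.diag(cov))
    ll = weighted_logistic_loglik(beta, X, y, w)
    return FitResult(label=label, coef=beta, se=se, loglik=ll, k=k, n=n,
                     columns=list(columns) if columns is not None else [f"b{j}" for j in range(k)])


def fit_candidates(table: pd.DataFrame, covariates, response: str = "is_real",
                   weight_col: str = "weight") -> list[FitResult]:
    """Fit the null model plus one single-covariate model per entry of
    ``covariates`` on identical rows, and rank them by AICc.  Candidates that
    perfectly separate the response (inestimable by maximum likelihood) are
    skipped with a warning."""
    y = table[response].to_numpy(dtype=float)
    w = table[weight_col].to_numpy(dtype=float)
    n = len(table)
    ones = np.ones((n, 1))
    fits = [fit_weighted_logistic(ones, y, w, label="~ 1", columns=["intercept"])]
    for cov in covariates:
        X = np.column_stack([np.ones(n), table[cov].to_numpy(dtype=float)])
        try:
            fits.append(fit_weighted_logistic(X, y, w, label=f"~ {cov}", columns=["intercept", cov]))
        except SeparationError as err:
            warnings.warn(f"candidate ~ {cov} dropped: {err}")
    return aicc_rank(fits)


def aicc_rank(fits: list[FitResult]) -> list[FitResult]:
    """ΔAICc and Akaike weights for a candidate set fit on identical rows."""
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"candidates fit on differing n: {sorted(ns)}")
    for f in fits:
        f.aicc = aicc(f.loglik, f.k, f.n)
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best
    raw = np.array([math.exp(-f.delta_aicc / 2.0) for f in fits])
    raw /= raw.sum()
    for f, wgt in zip(fits, raw):
        f.aicc_weight = float(wgt)
    return sorted(fits, key=lambda f: f.aicc)


def selection_table(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [f.label for f in fits],
            "AICc": [f.aicc for f in fits],
            "dAICc": [f.delta_aicc for f in fits],
            "AICc_weight": [f.aicc_weight for f in fits],
            "deviance": [f.deviance for f in fits],
        }
    )


# ---------------------------------------------------------------------------
# matching permutation test
# ---------------------------------------------------------------------------

def matching_permutation_test(
    table: pd.DataFrame,
    trait: str,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool | None = None,
):
    """Permutation test for pairing structure in one trait.

    Statistic: mean |Δtrait| over real pairs minus the mean over all
    potential pairs.  The null redraws a uniform random perfect matching of
    females to males within each year, so every bird keeps exactly one
    pseudo-mate per draw — the exchangeability that the repeated appearance
    of each bird across rows actually leaves available.  Two-sided
    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).  With ``exhaustive``
    (auto-enabled when the total number of matchings is small) the full
    matching set is enumerated instead.  Returns (p, T_obs, null draws).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    grand = float(table[trait].mean())

    year_mats = []
    for year, sub in table.groupby("year"):
        females = sorted(sub["female_id"].unique())
        males = sorted(sub["male_id"].unique())
        mat = sub.pivot_table(index="female_id", columns="male_id", values=trait).loc[females, males].to_numpy()
        real = sub[sub["is_real"] == 1]
        if len(real) < 2:
            raise ValueError(f"need >= 2 real pairs in year {year}")
        fidx = {f: i for i, f in enumerate(females)}
        midx = {m: j for j, m in enumerate(males)}
        match = np.full(len(females), -1, dtype=int)
        for _, r in real.iterrows():
            match[fidx[r["female_id"]]] = midx[r["male_id"]]
        if (match < 0).any():
            raise ValueError(f"year {year}: some females lack an observed mate")
        year_mats.append((mat, match))

    def stat_for(matches):
        vals = [mat[np.arange(len(m)), m].mean() for (mat, _), m in zip(year_mats, matches)]
        sizes = [len(m) for m in matches]
        return float(np.average(vals, weights=sizes)) - grand

    t_obs = stat_for([m for _, m in year_mats])

    n_f = [mat.shape[0] for mat, _ in year_mats]
    total_matchings = np.prod([math.factorial(n) for n in n_f])
    if exhaustive is None:
        exhaustive = total_matchings <= 5000
    null = []
    if exhaustive:
        perms_per_year = [list(itertools.permutations(range(n))) for n in n_f]
        for combo in itertools.product(*perms_per_year):
            null.append(stat_for([np.array(p) for p in combo]))
        null = np.asarray(null)
        p = float(np.mean(np.abs(null) >= abs(t_obs) - 1e-12))
    else:
        for _ in range(n_perm):
            null.append(stat_for([rng.permutation(n) for n in n_f]))
        null = np.asarray(null)
        p = (1.0 + int(np.sum(np.abs(null) >= abs(t_obs) - 1e-12))) / (1.0 + n_perm)
    return p, t_obs, null


# ---------------------------------------------------------------------------
# t-tests (sex comparisons; mass before/after deployment)
# ---------------------------------------------------------------------------

def ttest_unpaired(sample_f, sample_m):
    """Student's two-sample t-test with pooled variance; returns (t, df, p)."""
    a = np.asarray(sample_f, dtype=float)
    b = np.asarray(sample_m, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def ttest_paired(before, after):
    """Paired t-test; returns (t, df, p)."""
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2")
    if (a - b).std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)
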