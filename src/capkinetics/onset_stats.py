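"""Population means, baseline-referenced Dunnett tests, onset/peak summaries.

The statistical question mirrors standard on-kinetics analysis: each
post-step second's population mean is compared with the mean of a fixed
baseline window (many-to-one comparisons sharing one control).  Per
capillary the comparison is paired — its value at the post second minus its
own baseline-window mean — tested against zero with a t statistic and
adjusted for the family of post seconds with a Dunnett-style procedure.

Under an iid null the paired differences at two post seconds are
equicorrelated through the shared baseline term: with an m-second baseline,
rho = 1/(m+1).  The adjusted p-value for an observed |t| is the probability
that the maximum of k equicorrelated |t|-variates exceeds it, computed by
quadrature over the multivariate-t mixing representation when the design is
balanced, or by seeded Monte Carlo of the same model when missingness makes
it unbalanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "aggregate_means",
    "dunnett_vs_baseline",
    "find_onset_and_peak",
    "percent_change",
    "OnsetSummary",
    "max_abs_t_sf",
]

MEASURE_COLUMNS = ("velocity", "lineal_density", "hematocrit", "supply_rate", "so2")


# ---------------------------------------------------------------------------
# Second-by-second means
# ---------------------------------------------------------------------------

def aggregate_means(population: pd.DataFrame,
                    measures=MEASURE_COLUMNS) -> pd.DataFrame:
    """Available-case per-second mean/SD/SEM/n for each measure.

    ``population`` is a long table with columns ``capillary_id``, ``t`` and
    the measure columns; missing values are excluded per second with the
    contributing count recorded.  Returns a tidy frame with columns
    ``measure, t, mean, sd, sem, n``.
    """
    recs = []
    for m in measures:
        if m not in population.columns:
            continue
        g = population.groupby("t")[m]
        df = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1),
                           "n": g.count()})
        df["sem"] = df["sd"] / np.sqrt(df["n"].clip(lower=1))
        df.loc[df["n"] == 0, ["mean", "sd", "sem"]] = np.nan
        df["measure"] = m
        recs.append(df.reset_index())
    out = pd.concat(recs, ignore_index=True)
    return out[["measure", "t", "mean", "sd", "sem", "n"]]


# ---------------------------------------------------------------------------
# Dunnett-style family adjustment
# ---------------------------------------------------------------------------

def max_abs_t_sf(tvals, k: int, nu: float, rho: float, *,
                 n_nodes: int = 48) -> np.ndarray:
    """P(max_j |T_j| >= t) for k equicorrelated t-variates (df nu, corr rho).

    Uses the mixing representation T_j = (sqrt(1-rho) Z_j + sqrt(rho) Z0)/W
    with W = sqrt(chi2_nu/nu): conditional on (Z0, W) the components are
    independent, so the joint CDF is an expectation of a product, evaluated
    with Gauss-Hermite nodes in Z0 and Gauss-Legendre nodes in the
    chi-square quantile.
    """
    tvals = np.atleast_1d(np.asarray(tvals, dtype=float))
    xh, wh = np.polynomial.hermite_e.hermegauss(n_nodes)  # weight e^{-x^2/2}
    wh = wh / math.sqrt(2.0 * math.pi)
    xl, wl = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (xl + 1.0)
    wu = 0.5 * wl
    w = np.sqrt(stats.chi2.ppf(u, nu) / nu)

    sr = math.sqrt(rho)
    s1 = math.sqrt(1.0 - rho)
    t_ = tvals[:, None, None]
    z0 = xh[None, :, None]
    w_ = w[None, None, :]
    upper = (t_ * w_ - sr * z0) / s1
    lower = (-t_ * w_ - sr * z0) / s1
    inner = np.clip(special.ndtr(upper) - special.ndtr(lower), 0.0, 1.0)
    cdf = np.einsum("ijk,j,k->i", inner ** k, wh, wu)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    sf[~np.isfinite(tvals)] = np.nan
    return sf


def _max_abs_t_sf_mc(tvals, k: int, nu: float, rho: float, *,
                     n_draws: int = 100_000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo version of :func:`max_abs_t_sf` (fixed seed)."""
    rng = np.random.default_rng(seed)
    sr, s1 = math.sqrt(rho), math.sqrt(1.0 - rho)
    z0 = rng.standard_normal(n_draws)
    w = np.sqrt(rng.chisquare(nu, n_draws) / nu)
    # max over k iid normals given z0: use batched max to bound memory
    mx = np.zeros(n_draws)
    batch = max(1, int(5e7 // n_draws))
    for j0 in range(0, k, batch):
        z = rng.standard_normal((min(batch, k - j0), n_draws))
        np.maximum(mx, np.abs(s1 * z + sr * z0).max(axis=0), out=mx)
    mx /= w
    tvals = np.atleast_1d(np.asarray(tvals, dtype=float))
    sf = np.array([np.nan if not np.isfinite(t) else float(np.mean(mx >= t))
                   for t in tvals])
    return sf


def dunnett_vs_baseline(values: np.ndarray | pd.DataFrame, t=None, *,
                        baseline_window=(51, 60), post_window=None,
                        alpha: float = 0.05, n_mc: int = 100_000,
                        mc_seed: int = 0) -> pd.DataFrame:
    """Per-second Dunnett-adjusted p-values against a baseline window.

    Parameters
    ----------
    values : 2-D array or DataFrame
        Capillaries x seconds, NaN marking missing observations.  A
        DataFrame's columns are taken as the time grid.
    t : array-like, optional
        Time grid (s) for an array input.
    baseline_window, post_window : (lo, hi)
        Closed windows; the baseline score is each capillary's mean over
        the baseline window, the post window defaults to everything after
        the baseline.

    Returns a frame with ``t, diff, stat, p_adj, n`` per post second;
    seconds with fewer than two complete pairs carry missing p-values.
    """
    if isinstance(values, pd.DataFrame):
        t = values.columns.to_numpy(dtype=float)
        values = values.to_numpy(dtype=float)
    else:
        values = np.asarray(values, dtype=float)
        if t is None:
            raise ValueError("time grid required for array input")
        t = np.asarray(t, dtype=float)
    if values.ndim != 2 or values.shape[1] != t.size:
        raise ValueError("values must be capillaries x seconds matching t")

    b_lo, b_hi = baseline_window
    base_cols = (t >= b_lo) & (t <= b_hi)
    m = int(base_cols.sum())
    if m == 0:
        raise ValueError("baseline window contains no seconds")
    if post_window is None:
        post_cols = t > b_hi
    else:
        post_cols = (t >= post_window[0]) & (t <= post_window[1])
    t_post = t[post_cols]

    with np.errstate(invalid="ignore"):
        baseline = np.nanmean(values[:, base_cols], axis=1)
    ok_base = np.isfinite(baseline)
    if ok_base.sum() < 2:
        raise ValueError("need >= 2 capillaries with baseline data")

    post = values[:, post_cols]
    diffs = post - baseline[:, None]
    n_j = np.sum(np.isfinite(diffs), axis=0)
    mean_j = np.full(t_post.size, np.nan)
    stat_j = np.full(t_post.size, np.nan)
    for j in range(t_post.size):
        d = diffs[:, j]
        d = d[np.isfinite(d)]
        if d.size < 2:
            continue
        mean_j[j] = d.mean()
        sd = d.std(ddof=1)
        if sd == 0.0:
            stat_j[j] = 0.0 if mean_j[j] == 0.0 else np.inf
        else:
            stat_j[j] = mean_j[j] / (sd / math.sqrt(d.size))

    valid = n_j >= 2
    k = int(valid.sum())
    rho = 1.0 / (m + 1.0)
    p_adj = np.full(t_post.size, np.nan)
    if k:
        balanced = np.all(n_j[valid] == n_j[valid][0]) and \
            not np.any(~np.isfinite(values[ok_base][:, post_cols]))
        nu = float(n_j[valid].min() - 1)
        absstat = np.abs(stat_j[valid])
        if balanced:
            p = max_abs_t_sf(absstat, k, nu, rho)
        else:
            p = _max_abs_t_sf_mc(absstat, k, nu, rho, n_draws=n_mc, seed=mc_seed)
        p = np.where(np.isinf(absstat), 0.0, p)
        p_adj[valid] = p

    return pd.DataFrame({"t": t_post, "diff": mean_j, "stat": stat_j,
                         "p_adj": p_adj, "n": n_j})


# ---------------------------------------------------------------------------
# Onset / peak summaries
# ---------------------------------------------------------------------------

@dataclass
class OnsetSummary:
    """One published-style summary row: baseline, first-significant, peak.

    All response fields are NaN when no post-step second reaches the
    significance threshold (the all-NA case).
    """

    measure: str
    challenge: str
    baseline_mean: float
    baseline_sd: float
    first_sig_mean: float
    first_sig_sd: float
    first_sig_time: float
    first_sig_p: float
    peak_mean: float
    peak_sd: float
    peak_time: float
    peak_p: float
    direction: int  # +1 peak, -1 nadir

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def find_onset_and_peak(means: pd.DataFrame, dunnett: pd.DataFrame, *,
                        step_time: float = 60.0, baseline_window=(51, 60),
                        alpha: float = 0.05, direction: int | None = None,
                        measure: str = "", challenge: str = "") -> OnsetSummary:
    """First significant post-step second and the response peak/nadir.

    ``means`` is one measure's slice of :func:`aggregate_means`;
    ``dunnett`` the matching adjusted p-value frame.  The first significant
    time is the earliest post-step second with adjusted p below alpha; the
    peak (or nadir, by the response direction — the sign of the post-window
    mean minus the baseline mean, ties counting as a peak) is the extremum
    of the post-step means with its own time and adjusted p.  When no
    second is significant every response field is NaN.
    """
    mm = means.set_index("t")
    b_lo, b_hi = baseline_window
    base = mm.loc[(mm.index >= b_lo) & (mm.index <= b_hi)]
    baseline_mean = float(base["mean"].mean())
    baseline_sd = float(base["sd"].mean())

    post = dunnett[dunnett["t"] > step_time]
    post_means = mm.loc[mm.index.intersection(post["t"])]

    if direction is None:
        delta = float(post_means["mean"].mean()) - baseline_mean
        direction = 1 if delta >= 0 else -1

    sig = post[post["p_adj"] < alpha]
    na = math.nan
    if sig.empty:
        return OnsetSummary(measure, challenge, baseline_mean, baseline_sd,
                            na, na, na, na, na, na, na, na, direction)

    t_first = float(sig["t"].iloc[0])
    row_first = mm.loc[t_first]
    p_first = float(sig["p_adj"].iloc[0])

    vals = post_means["mean"]
    t_ext = float(vals.idxmax() if direction > 0 else vals.idxmin())
    row_ext = mm.loc[t_ext]
    p_ext_ser = post.loc[post["t"] == t_ext, "p_adj"]
    p_ext = float(p_ext_ser.iloc[0]) if not p_ext_ser.empty else na

    return OnsetSummary(measure, challenge, baseline_mean, baseline_sd,
                        float(row_first["mean"]), float(row_first["sd"]),
                        t_first, p_first,
                        float(row_ext["mean"]), float(row_ext["sd"]),
                        t_ext, p_ext, direction)


def percent_change(baseline: float, extreme: float) -> float:
    """100 x (extreme - baseline) / baseline; undefined for zero baseline."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    if not (np.isfinite(baseline) and np.isfinite(extreme)):
        return math.nan
    return 100.0 * (extreme - baseline) / baseline
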