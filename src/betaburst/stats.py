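"""Burst-rate and group-level statistics.

Converts burst event times plus a behavioural event table into
condition-wise burst rates, event-locked rate curves in sliding windows,
the post-movement beta rebound (PMBR) statistic, and the group /
association statistics used to compare them.

PMBR is the mean beta-burst rate in windows extending from 0.5 to 1 s
after button presses minus the rate in baseline windows extending from
3 to 1.5 s before button presses. All windows are half-open ``[lo, hi)``
so no burst is double-counted at a boundary; windows that extend past the
recording edges are dropped from both numerator and denominator for that
response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RateCurve",
    "PMBRResult",
    "GroupComparison",
    "condition_rates",
    "event_locked_rate",
    "pmbr",
    "group_compare",
    "rm_anova_gg",
    "associate",
]

CONDITIONS = ("rest", "0back", "1back", "2back")

# PMBR windows (s relative to the button press), half-open [lo, hi)
PMBR_POST = (0.5, 1.0)
PMBR_BASELINE = (-3.0, -1.5)


@dataclass
class RateCurve:
    """Event-locked burst rate in sliding windows.

    ``lags`` are window centres (s) relative to the locking events;
    ``rate`` is bursts/s averaged over locking events; ``window`` is the
    sliding-window length (s)."""

    lags: np.ndarray
    rate: np.ndarray
    window: float
    n_events: int

    def mean_over(self, lo: float, hi: float) -> float:
        """Mean rate over lags in [lo, hi] (inclusive of endpoints)."""
        sel = (self.lags >= lo - 1e-12) & (self.lags <= hi + 1e-12)
        if not sel.any():
            raise ValueError(f"no lags inside [{lo}, {hi}]")
        return float(self.rate[sel].mean())


@dataclass
class PMBRResult:
    pmbr: float
    post_rate: float
    baseline_rate: float
    n_responses: int


@dataclass
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    effect_size: float
    effect_size_name: str
    n_a: int
    n_b: int
    df: float = None


def _interval_counts(bursts, starts, stops):
    """Count bursts falling in the union of half-open [start, stop) intervals."""
    bursts = np.sort(np.asarray(bursts, dtype=float))
    lo = np.searchsorted(bursts, starts, side="left")
    hi = np.searchsorted(bursts, stops, side="left")
    return int(np.sum(hi - lo))


def condition_rates(bursts, events: pd.DataFrame, conditions=CONDITIONS):
    """Mean burst rate (bursts/s) per experimental condition.

    ``events`` is a BIDS-style table with onset, duration, trial_type; a
    condition's rate is the burst count inside the union of its intervals
    divided by their total duration. Bursts outside every interval are
    ignored.

    Raises
    ------
    ValueError
        If a requested condition has zero total duration (undefined rate).
    """
    bursts = np.asarray(bursts, dtype=float)
    out = {}
    for cond in conditions:
        rows = events[events["trial_type"] == cond]
        total = float(rows["duration"].sum())
        if total <= 0:
            raise ValueError(f"condition {cond!r} has zero total duration")
        starts = rows["onset"].to_numpy(dtype=float)
        stops = starts + rows["duration"].to_numpy(dtype=float)
        out[cond] = _interval_counts(bursts, starts, stops) / total
    return out


def event_locked_rate(bursts, lock_times, window: float = 0.5,
                      lag_range=(-3.0, 3.0), step: float = 0.05) -> RateCurve:
    """Burst rate time-locked to events, in sliding windows.

    At each lag l the rate is the count of bursts in
    ``[t + l - w/2, t + l + w/2)`` averaged over locking times t, divided
    by the window length w (bursts per second in 500-ms sliding windows by
    default, stepped every 50 ms).
    """
    lock_times = np.asarray(lock_times, dtype=float)
    if lock_times.size == 0:
        raise ValueError("lock_times must contain at least one event")
    if not (window > 0 and step > 0):
        raise ValueError("window and step must be > 0")
    bursts = np.sort(np.asarray(bursts, dtype=float))
    n_lags = int(np.floor((lag_range[1] - lag_range[0]) / step + 1e-9)) + 1
    lags = lag_range[0] + step * np.arange(n_lags)
    rate = np.empty(n_lags)
    for i, lag in enumerate(lags):
        starts = lock_times + lag - window / 2
        c = _interval_counts(bursts, starts, starts + window)
        rate[i] = c / (lock_times.size * window)
    return RateCurve(lags=lags, rate=rate, window=window, n_events=lock_times.size)


def pmbr(bursts, response_times, post=PMBR_POST, baseline=PMBR_BASELINE,
         t_start=-np.inf, t_stop=np.inf, method="pooled") -> PMBRResult:
    """Post-movement beta rebound: post-response minus baseline burst rate.

    With ``method='pooled'`` (default) each window's rate is the total
    burst count in that window across responses divided by
    ``n_responses x window length``; ``method='mean'`` averages
    per-response rates instead (identical for equal-length windows, kept
    for completeness). Responses whose windows extend past
    ``[t_start, t_stop]`` are dropped entirely.
    """
    responses = np.asarray(response_times, dtype=float)
    if responses.size == 0:
        raise ValueError("response_times must contain at least one response")
    if not (post[1] > post[0] and baseline[1] > baseline[0]):
        raise ValueError("windows must be non-degenerate")
    lo_edge = min(post[0], baseline[0])
    hi_edge = max(post[1], baseline[1])
    keep = (responses + lo_edge >= t_start) & (responses + hi_edge <= t_stop)
    responses = responses[keep]
    if responses.size == 0:
        raise ValueError("no responses with complete windows inside the recording")
    bursts = np.sort(np.asarray(bursts, dtype=float))

    def _window_rate(win):
        w = win[1] - win[0]
        starts = responses + win[0]
        c = _interval_counts(bursts, starts, starts + w)
        if method == "pooled":
            return c / (responses.size * w)
        elif method == "mean":
            lo = np.searchsorted(bursts, starts, side="left")
            hi = np.searchsorted(bursts, starts + w, side="left")
            return float(np.mean((hi - lo) / w))
        raise ValueError(f"unknown method {method!r}")

    post_rate = _window_rate(post)
    base_rate = _window_rate(baseline)
    return PMBRResult(
        pmbr=post_rate - base_rate,
        post_rate=post_rate,
        baseline_rate=base_rate,
        n_responses=int(responses.size),
    )


def _mann_whitney_z(u, a, b):
    """Normal-approximation Z for Mann-Whitney U with tie correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0
    return (u - mu) / np.sqrt(sigma2)


def group_compare(values_a, values_b, method: str = "mann_whitney") -> GroupComparison:
    """Two-group comparison with the conventional effect size.

    mann_whitney: U statistic, exact p for pooled n <= 20 without ties
    else normal approximation with tie correction, and effect size
    r = |Z| / sqrt(N). t_test: Welch t with Cohen's d (pooled-SD
    convention).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    n = a.size + b.size
    if method == "mann_whitney":
        has_ties = np.unique(np.concatenate([a, b])).size < n
        mw_method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        z = _mann_whitney_z(res.statistic, a, b)
        return GroupComparison(
            method="mann_whitney", statistic=float(res.statistic),
            p_value=float(res.pvalue), effect_size=abs(z) / np.sqrt(n),
            effect_size_name="rank_r", n_a=a.size, n_b=b.size,
        )
    elif method == "t_test":
        sd_a, sd_b = a.std(ddof=1), b.std(ddof=1)
        if sd_a == 0 and sd_b == 0:
            raise ValueError("degenerate variance: all values identical")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        pooled_sd = np.sqrt(
            ((a.size - 1) * sd_a**2 + (b.size - 1) * sd_b**2) / (n - 2)
        )
        d = (a.mean() - b.mean()) / pooled_sd if pooled_sd > 0 else 0.0
        # Welch-Satterthwaite df
        va, vb = sd_a**2 / a.size, sd_b**2 / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        return GroupComparison(
            method="t_test", statistic=float(t), p_value=float(p),
            effect_size=float(d), effect_size_name="cohen_d",
            n_a=a.size, n_b=b.size, df=float(df),
        )
    raise ValueError(f"unknown method {method!r}")


def rm_anova_gg(matrix):
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is participants x conditions with no missing cells. Returns
    a dict with the F statistic, unadjusted and GG-adjusted dfs and p,
    partial eta squared, and the GG epsilon estimated from the sample
    covariance of the conditions. The correction is applied
    unconditionally (no Mauchly gating); with two conditions epsilon is
    exactly 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D (participants x conditions)")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite cells are not allowed")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 participants and >= 2 conditions")
    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else np.inf

    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    S = np.cov(X, rowvar=False, ddof=1)
    J = np.eye(k) - np.ones((k, k)) / k
    Sc = J @ S @ J
    lam = np.linalg.eigvalsh(Sc)
    eps = np.sum(lam) ** 2 / (df1 * np.sum(lam**2))
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    p_unc = float(sps.f.sf(F, df1, df2))
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    return {
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "df1_gg": eps * df1,
        "df2_gg": eps * df2,
        "p_uncorrected": p_unc,
        "p_gg": p_gg,
        "epsilon": eps,
        "partial_eta_sq": float(ss_cond / (ss_cond + ss_err)),
        "ss_condition": float(ss_cond),
        "ss_error": float(ss_err),
    }


def associate(x, y, covariates=None):
    """Spearman rank correlation, optionally adjusted for covariates.

    Without covariates this is the ties-corrected Spearman rho with its
    p-value. With covariates, both x and y are first residualised on the
    covariates (plus an intercept) by least squares and the residuals are
    then rank-correlated — a documented convention, distinct from ranking
    before residualising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != x.size:
            raise ValueError("covariates must have the same number of rows as x")
        Z = np.column_stack([np.ones(x.size), C])
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("residualised input is constant")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
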