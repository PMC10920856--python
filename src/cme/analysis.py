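"""Downstream statistics of CME time series.

Covers the analyses layered on top of the per-frame descriptor: automatic
correlation-method choice, linear fits of CMEr versus CMEa, K-means
clustering of the CME scatter with occupancy (dwell-time) ratios, group
comparison via a normality/equal-variance decision tree, and detection of
the proliferation-to-invasion transition as a slope changepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import ConstantSeriesError
from .entropy import CMETimeSeries

ALPHA = 0.05  # two-tailed, 95% confidence throughout


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return "n.s."


def _is_normal(sample: np.ndarray, alpha: float = ALPHA) -> bool:
    """Lilliefors test; constant samples are treated as non-normal."""
    if np.ptp(sample) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(sample, dist="norm")
    return bool(p > alpha)


# ---------------------------------------------------------------------------
# Correlation and linear fits
# ---------------------------------------------------------------------------

def correlate(x, y) -> tuple[str, float]:
    """Correlation with automatic method choice.

    Pearson if both series pass the Lilliefors normality test, otherwise
    Spearman.  Returns ``(method, coefficient)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need two equal-length series of at least 5 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("constant series: correlation undefined")
    if _is_normal(x) and _is_normal(y):
        return "pearson", float(stats.pearsonr(x, y).statistic)
    return "spearman", float(stats.spearmanr(x, y).statistic)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares ``y = slope * x + intercept`` with R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ConstantSeriesError("constant series: var(x) = 0")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), r2


# ---------------------------------------------------------------------------
# Clustering and dwell-time ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSummary:
    """K-means clusters of the (CMEa, CMEr) scatter.

    Clusters are relabeled ``0..k-1`` by ascending mean CMEa, so identity
    is seed-independent for well-separated data (cluster I = index 0).
    """

    k: int
    labels: np.ndarray
    means: np.ndarray       # (k, 2) columns (cmea, cmer)
    sds: np.ndarray         # (k, 2)
    percentages: np.ndarray
    seed: int


def cluster_scatter(
    ts: CMETimeSeries | np.ndarray, k: int = 3, seed: int = 0
) -> ClusterSummary:
    """K-means on the raw (CMEa, CMEr) pairs (no standardization).

    10 restarts with a fixed seed; frames with failed CME are excluded.
    """
    if isinstance(ts, CMETimeSeries):
        pts = np.column_stack([ts.cmea[ts.valid], ts.cmer[ts.valid]])
    else:
        pts = np.asarray(ts, dtype=float)
    n = pts.shape[0]
    if np.unique(pts, axis=0).shape[0] < k:
        raise ValueError(f"k={k} exceeds the number of distinct points")
    if n < 3 * k:
        raise ValueError(f"need at least 3*k={3 * k} frames, got {n}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pts)
    order = np.argsort(km.cluster_centers_[:, 0])  # ascending mean CMEa
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[km.labels_]
    means = np.vstack([pts[labels == i].mean(axis=0) for i in range(k)])
    sds = np.vstack([pts[labels == i].std(axis=0) for i in range(k)])
    percentages = np.array([(labels == i).mean() * 100.0 for i in range(k)])
    return ClusterSummary(k=k, labels=labels, means=means, sds=sds,
                          percentages=percentages, seed=seed)


def _round_sig(x: float, sig: int = 2) -> float:
    return float(f"{x:.{sig}g}")


def occupancy_ratios(percentages) -> dict[str, float]:
    """Dwell-time ratios between three clusters, 2 significant figures.

    At a fixed sampling interval the per-cluster percentage of frames is
    equivalent to the dwell time in that state; the ratios I/III, II/III
    and I/(II+III) summarize how long the object stays in each state.
    """
    p = np.asarray(percentages, dtype=float)
    if p.size != 3:
        raise ValueError("occupancy ratios are defined for exactly 3 clusters")
    if p[2] == 0 or (p[1] + p[2]) == 0:
        raise ZeroDivisionError("zero denominator in occupancy ratio")
    return {
        "I/III": _round_sig(p[0] / p[2]),
        "II/III": _round_sig(p[1] / p[2]),
        "I/(II+III)": _round_sig(p[0] / (p[1] + p[2])),
    }


def theoretical_length_ratio(
    chamber_count: float, chamber_len_um: float,
    channel_count: float, channel_len_um: float,
) -> float:
    """Total chamber length over total channel length, 2 decimals.

    For an object traversing a periodic chamber/channel array at constant
    speed, this is the expected ratio of time spent in chambers to time
    spent in channels.
    """
    if min(chamber_count, chamber_len_um, channel_count, channel_len_um) <= 0:
        raise ValueError("all inputs must be positive")
    return round(
        (chamber_count * chamber_len_um) / (channel_count * channel_len_um), 2
    )


# ---------------------------------------------------------------------------
# Group comparison decision tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality/equal-variance decision tree."""

    test: str
    p_value: float
    stars: str
    acos_applied: bool
    decisions: dict = field(default_factory=dict)


def compare_groups(groups) -> GroupComparison:
    """Compare >= 2 groups with automatic parametric/nonparametric choice.

    Decision tree: Lilliefors normality on every group plus Bartlett equal
    variance.  If both hold, a t-test (2 groups) or one-way ANOVA (>2).  If
    not, and every value lies in [-1, 1] (as CME components do), an arccos
    transform — bijective on that domain — is applied and the criteria
    retested.  If they still fail, Wilcoxon rank sum (2 groups) or
    Kruskal-Wallis (>2).  Two-tailed at 95% confidence; stars at
    0.05/0.01/0.001.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 4 for g in gs):
        raise ValueError("each group needs >= 4 values (normality test unreliable)")

    decisions: dict[str, bool] = {}
    use_parametric, data = _parametric_ok(gs, decisions, suffix="raw")
    acos_applied = False
    if not use_parametric and all(np.all(np.abs(g) <= 1.0) for g in gs):
        transformed = [np.arccos(g) for g in gs]
        acos_applied = True
        ok, _ = _parametric_ok(transformed, decisions, suffix="acos")
        if ok:
            use_parametric, data = True, transformed

    two = len(gs) == 2
    if use_parametric:
        if two:
            test = "t-test"
            res = stats.ttest_ind(data[0], data[1], equal_var=True)
        else:
            test = "ANOVA"
            res = stats.f_oneway(*data)
        p = float(res.pvalue)
    else:
        try:
            if two:
                test = "Wilcoxon rank sum"
                p = float(stats.ranksums(gs[0], gs[1]).pvalue)
            else:
                test = "Kruskal-Wallis"
                p = float(stats.kruskal(*gs).pvalue)
        except ValueError:  # all values identical across groups
            test = "Kruskal-Wallis" if not two else "Wilcoxon rank sum"
            p = 1.0
    if np.isnan(p):  # identical inputs make parametric statistics 0/0
        p = 1.0
    return GroupComparison(
        test=test, p_value=p, stars=_stars(p),
        acos_applied=acos_applied, decisions=decisions,
    )


def _parametric_ok(gs, decisions: dict, suffix: str):
    normal = all(_is_normal(g) for g in gs)
    decisions[f"normal_{suffix}"] = normal
    if any(np.ptp(g) == 0 for g in gs):
        equal_var = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            equal_var = bool(stats.bartlett(*gs).pvalue > ALPHA)
    decisions[f"equal_var_{suffix}"] = equal_var
    return normal and equal_var, gs


# ---------------------------------------------------------------------------
# Transition detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionReport:
    """Two-segment piecewise-linear changepoint of a CME profile.

    ``transition`` is True only when the post-breakpoint slope exceeds the
    pre-breakpoint slope by more than the declared threshold — the
    signature of a spheroid switching from proliferation (flat profile) to
    invasion (rising profile).  The method tag marks this as one concrete
    realization of a slope/inflection criterion.
    """

    breakpoint_time: float
    pre_slope: float
    post_slope: float
    sse: float
    transition: bool
    threshold: float
    method: str = "piecewise-linear changepoint (non-canonical)"


def detect_transition(
    ts: CMETimeSeries | tuple[np.ndarray, np.ndarray],
    min_segment: int = 3,
    slope_se_factor: float = 3.5,
) -> TransitionReport:
    """Fit a continuous two-segment line and test for a slope increase.

    Every observed time with at least ``min_segment`` points on each side
    is a candidate breakpoint; the total-SSE minimizer wins.  A transition
    is declared when the slope increase ``post_slope - pre_slope`` exceeds
    ``slope_se_factor`` times its own standard error from the piecewise
    fit.  The default factor of 3.5 compensates for the selection of the
    best breakpoint among all candidates: on pure-noise profiles the
    maximized slope-change t-statistic reaches ~3 in the upper percentile,
    so 3.5 keeps spurious transitions below the percent level while
    genuine changepoints score far higher.
    """
    if isinstance(ts, CMETimeSeries):
        x = ts.times[ts.valid]
        y = ts.cme_avg[ts.valid]
    else:
        x = np.asarray(ts[0], dtype=float)
        y = np.asarray(ts[1], dtype=float)
    n = x.size
    if n < 2 * min_segment + 2 or n < 8:
        raise ValueError(f"too few frames for transition detection: {n}")

    best = None
    for i in range(min_segment - 1, n - min_segment):
        t_c = x[i]
        design = np.column_stack([np.ones(n), x, np.maximum(x - t_c, 0.0)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(np.sum((design @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, t_c, coef, design)
    sse, t_c, coef, design = best
    pre_slope = float(coef[1])
    post_slope = float(coef[1] + coef[2])

    # standard error of the slope change (hinge coefficient) at the
    # selected breakpoint
    dof = max(n - 3, 1)
    cov = (sse / dof) * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(max(cov[2, 2], 0.0)))
    threshold = slope_se_factor * se
    return TransitionReport(
        breakpoint_time=float(t_c),
        pre_slope=pre_slope,
        post_slope=post_slope,
        sse=sse,
        transition=bool(post_slope - pre_slope > threshold),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Peak finding on CME profiles
# ---------------------------------------------------------------------------

def find_cme_peaks(
    values,
    smooth_window: int = 3,
    prominence: float | None = None,
    distance: int = 3,
) -> np.ndarray:
    """Indices of prominent local maxima of a CME profile.

    The profile is lightly smoothed (centered moving average) and peaks
    are located with a prominence floor.  By default the floor adapts to
    the profile's own noise level, estimated robustly from first
    differences (median absolute deviation scaled to sigma; differencing
    doubles the variance, smoothing averages ``smooth_window`` samples).
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 2 * distance + 1:
        return np.array([], dtype=int)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        ys = np.convolve(y, kernel, mode="same")
        ys[0], ys[-1] = y[0], y[-1]
    else:
        ys = y
    if prominence is None:
        d = np.diff(y)
        sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
        sigma_s = sigma / np.sqrt(max(smooth_window, 1))
        prominence = max(0.03, 4.0 * sigma_s)
    peaks, _ = signal.find_peaks(ys, prominence=prominence, distance=distance)
    return peaks
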