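"""Pre-estimation screening: residency, range shifts, excursion removal.

Home-range estimators assume range residency, so trajectories are screened
first.  An empirical variogram (semivariance of displacement against time
lag) that plateaus indicates a resident; one that keeps climbing indicates
drift or dispersal.  Excursions — brief long-distance loops away from the
territory — are removed before hull construction with a one-sided Hampel
filter on Tukey-transformed distances to the track centroid:

    upper bound = median(transformed distance) + 3 * MAD,

with the MAD left unscaled (no 1.4826 normal-consistency factor) and only the
upper bound applied, since small distances are legitimate den attendance.
The Tukey power lambda is chosen on a grid by maximising Shapiro-Wilk W of
the transformed sample, the convention of the transformTukey approach.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateError, ValidationError
from .trajectory import Trajectory

#: Hampel multiplier: 3 median absolute deviations.
HAMPEL_K = 3.0
#: Lambda grid for the Tukey ladder of powers.
TUKEY_GRID = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.025), 3)


@dataclass
class Variogram:
    """Empirical semivariogram: mean half squared displacement per lag bin."""

    lags_h: np.ndarray        # bin centres, hours
    semivariance: np.ndarray  # m^2
    n_pairs: np.ndarray


@dataclass
class ResidencyVerdict:
    resident: bool
    plateau_mean: float
    tail_mean: float
    ratio: float


@dataclass
class ExcursionSegment:
    start: int              # index into the input fix series
    stop: int               # inclusive
    n_fixes: int
    max_distance_m: float


@dataclass
class ExcursionFilterResult:
    lam: float
    upper_bound: float
    kept: Trajectory
    excursions: list = field(default_factory=list)
    flagged: np.ndarray | None = None  # boolean mask over input fixes
    distances: np.ndarray | None = None


@dataclass
class RangeShift:
    index: int
    between_distance_m: float
    rms_before_m: float
    rms_after_m: float


def empirical_variogram(traj: Trajectory, bin_width_h: float = 24.0,
                        max_lag_h: float = 960.0) -> Variogram:
    """Semivariance of displacement over all fix pairs, binned by time lag.

    For each pair (i, j) with lag <= ``max_lag_h`` the half squared planar
    displacement is accumulated into the lag bin; per-bin means are returned.
    Empty bins are omitted rather than zero-filled.
    """
    if traj.n < 10:
        raise ValidationError("variogram needs at least 10 fixes")
    if bin_width_h <= 0:
        raise ValidationError("bin_width must be positive")
    xy = traj.xy
    th = traj.t_seconds / 3600.0
    i, j = np.triu_indices(traj.n, k=1)
    lag = th[j] - th[i]
    keep = lag <= max_lag_h
    i, j, lag = i[keep], j[keep], lag[keep]
    sv = 0.5 * ((xy[j, 0] - xy[i, 0]) ** 2 + (xy[j, 1] - xy[i, 1]) ** 2)
    k = np.floor(lag / bin_width_h).astype(int)
    nbin = int(k.max()) + 1 if k.size else 0
    counts = np.bincount(k, minlength=nbin)
    sums = np.bincount(k, weights=sv, minlength=nbin)
    nonempty = counts > 0
    centres = (np.arange(nbin) + 0.5) * bin_width_h
    return Variogram(centres[nonempty], sums[nonempty] / counts[nonempty],
                     counts[nonempty])


def assess_residency(vg: Variogram, plateau_window_h=(120.0, 240.0),
                     tail_window_h=(600.0, 960.0), tol: float = 0.5) -> ResidencyVerdict:
    """Judge range residency from variogram plateau behaviour.

    Resident iff the mean tail-window semivariance is at most ``(1 + tol)``
    times the mean plateau-window semivariance, i.e. the curve has stopped
    climbing.  Window defaults correspond to 5-10 day and 25-40 day lags.
    """
    def window_mean(lo, hi):
        sel = (vg.lags_h >= lo) & (vg.lags_h <= hi)
        if not sel.any():
            raise DegenerateError(f"no variogram bins in window [{lo}, {hi}] h")
        return float(np.average(vg.semivariance[sel], weights=vg.n_pairs[sel]))

    plateau = window_mean(*plateau_window_h)
    tail = window_mean(*tail_window_h)
    if plateau == 0.0:
        ratio = 1.0 if tail == 0.0 else np.inf
    else:
        ratio = tail / plateau
    return ResidencyVerdict(ratio <= 1.0 + tol, plateau, tail, ratio)


def tukey_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """Tukey ladder of powers: x**lam (lam>0), ln x (lam=0), -x**lam (lam<0).

    Monotone increasing in x for every lambda, so thresholds on the
    transformed scale map back to thresholds on distance.
    """
    v = np.asarray(values, dtype=float)
    if lam > 0:
        return v ** lam
    if lam == 0:
        return np.log(v)
    return -(v ** lam)


def tukey_lambda(values, grid: np.ndarray = TUKEY_GRID) -> float:
    """Select the power-ladder lambda maximising Shapiro-Wilk normality W.

    ``values`` must be positive (zeros are replaced by half the smallest
    positive value by callers).  A constant sample returns lambda = 1 with a
    warning; fewer than 3 values is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("tukey_lambda needs at least 3 values")
    if np.any(v <= 0):
        raise ValidationError("tukey_lambda needs strictly positive values")
    if np.ptp(v) == 0:
        warnings.warn("constant sample; lambda = 1", stacklevel=2)
        return 1.0
    # Shapiro-Wilk caps at n = 5000; a random subsample preserves the W
    # ranking across lambdas.
    if v.size > 5000:
        rng = np.random.default_rng(0)
        v = rng.choice(v, 5000, replace=False)
    best_w, best_lam = -np.inf, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lam in grid:
            w = stats.shapiro(tukey_transform(v, lam)).statistic
            if w > best_w:
                best_w, best_lam = w, float(lam)
    return best_lam


def hampel_upper_bound(transformed, k: float = HAMPEL_K) -> float:
    """median(v) + k * median(|v - median(v)|), with the MAD unscaled."""
    v = np.asarray(transformed, dtype=float)
    if v.size < 3:
        raise ValidationError("hampel_upper_bound needs at least 3 values")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med + k * mad


def remove_excursions(traj: Trajectory, k: float = HAMPEL_K) -> ExcursionFilterResult:
    """Flag and remove excursion fixes from a resident trajectory.

    Distances to the track centroid are Tukey-transformed (lambda selected by
    :func:`tukey_lambda`); fixes whose transformed distance exceeds the
    one-sided Hampel bound are flagged, and maximal runs of consecutive
    flagged fixes become excursion segments.  The kept trajectory is
    re-centroided once (its centroid is a derived property).

    Raises
    ------
    DegenerateError
        More than 50% of fixes flagged — the safety net against non-resident
        input, including the degenerate MAD = 0 case.
    """
    xy = traj.xy
    cx, cy = xy[:, 0].mean(), xy[:, 1].mean()
    d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
    pos = d[d > 0]
    if pos.size == 0:
        # Stationary track: nothing to remove.
        return ExcursionFilterResult(1.0, 0.0, traj, [], np.zeros(traj.n, bool), d)
    d_adj = np.where(d > 0, d, pos.min() / 2.0)
    lam = tukey_lambda(d_adj)
    z = tukey_transform(d_adj, lam)
    bound = hampel_upper_bound(z, k=k)
    flagged = z > bound
    if flagged.mean() > 0.5:
        raise DegenerateError(
            f"{flagged.mean():.0%} of fixes flagged; input looks non-resident"
        )
    segments = []
    idx = np.flatnonzero(flagged)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            segments.append(ExcursionSegment(
                int(run[0]), int(run[-1]), len(run), float(d[run].max())))
    kept = traj.with_fixes(traj.fixes.loc[~flagged])
    return ExcursionFilterResult(lam, float(bound), kept, segments, flagged, d)


def detect_range_shift(traj: Trajectory, min_segment: int = 30) -> RangeShift | None:
    """Least-squares change-point surrogate for a range-shift test.

    Every split with both segments >= ``min_segment`` fixes is scored by the
    total within-segment squared distance to the segment centroids; the best
    split is declared a shift only when the between-centroid distance exceeds
    the larger of the two segment RMS radii.  A single shift at most — the
    simple heuristic this pipeline uses in place of likelihood-based
    range-shift models.
    """
    n = traj.n
    if n < 2 * min_segment:
        raise ValidationError("need at least 2*min_segment fixes")
    xy = traj.xy
    csum = np.vstack([np.zeros(2), np.cumsum(xy, axis=0)])
    csq = np.concatenate([[0.0], np.cumsum((xy ** 2).sum(axis=1))])

    def seg_ss(a, b):  # fixes a..b-1
        m = b - a
        s = csum[b] - csum[a]
        return (csq[b] - csq[a]) - (s @ s) / m

    ks = np.arange(min_segment, n - min_segment + 1)
    costs = np.array([seg_ss(0, k) + seg_ss(k, n) for k in ks])
    k = int(ks[np.argmin(costs)])
    c1 = csum[k] / k
    c2 = (csum[n] - csum[k]) / (n - k)
    between = float(np.hypot(*(c2 - c1)))
    rms1 = float(np.sqrt(seg_ss(0, k) / k))
    rms2 = float(np.sqrt(seg_ss(k, n) / (n - k)))
    if between > max(rms1, rms2):
        return RangeShift(k, between, rms1, rms2)
    return None
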