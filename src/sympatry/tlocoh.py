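"""Time-local convex hulls (T-LoCoH): hullsets, isopleths, time-use metrics.

T-LoCoH builds a utilization distribution from local convex hulls around each
fix, selecting each hull's neighbours by the *time-scaled distance* (TSD)

    TSD(i, j) = sqrt(dx^2 + dy^2 + (s * v_max * dt)^2),

which places the time separation on a third Euclidean axis, scaled by the
animal's maximum observed velocity ``v_max`` and a dimensionless factor
``s``.  With s = 0 time is ignored and hulls are purely space-selected; as s
grows, fixes far apart in time are pushed apart regardless of spatial
proximity.  Neighbours are chosen with the adaptive ("a") method: fixes are
taken in order of TSD while their cumulative TSD stays within a threshold
``a``, which adapts the neighbourhood size to local fix density.

Sorting hulls by the number of enclosed fixes (density) and taking cumulative
unions yields isopleths — the 95% isopleth is the home range, the 50%
isopleth the core area.  Sorting instead by revisitation (NSV, number of
separate visits, where a new visit starts after an inter-visit gap, 12 h by
default) or by duration of use (MNLV, mean locations per visit) yields
behavioural time-use maps of the same territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .errors import DegenerateError, ValidationError
from .trajectory import Trajectory, compute_vmax

#: Default inter-visit gap: 12 h in seconds.
DEFAULT_IVG = 43_200.0
#: Default isopleth levels: core area and home range.
DEFAULT_LEVELS = (0.50, 0.95)

ORDERINGS = ("density", "nsv", "mnlv")


@dataclass(frozen=True)
class TlocohParams:
    """Hullset parameters.

    s : dimensionless TSD time-scaling factor (s >= 0).
    a : cumulative-TSD neighbour threshold, metres (a > 0).
    ivg : inter-visit gap in seconds (default 12 h).
    levels : isopleth fractions in (0, 1].
    """

    s: float
    a: float
    ivg: float = DEFAULT_IVG
    levels: tuple = DEFAULT_LEVELS

    def __post_init__(self):
        if self.s < 0:
            raise ValidationError("s must be >= 0")
        if self.a <= 0:
            raise ValidationError("a must be > 0")
        if self.ivg <= 0:
            raise ValidationError("ivg must be > 0")
        if any(not (0 < lv <= 1) for lv in self.levels):
            raise ValidationError("levels must lie in (0, 1]")


@dataclass
class Hull:
    """One local convex hull: the parent fix, its neighbours, and metrics."""

    parent: int
    neighbors: np.ndarray        # fix indices, parent included
    polygon: object              # shapely Polygon
    area: float
    enclosed: np.ndarray         # indices of all trajectory fixes covered
    n_enclosed: int
    nsv: int = 0
    mnlv: float = 0.0


@dataclass
class Hullset:
    traj: Trajectory
    params: TlocohParams
    v_max: float
    hulls: list
    skipped: list = field(default_factory=list)  # degenerate parent indices

    @property
    def n_fixes(self) -> int:
        return self.traj.n


@dataclass
class Isopleth:
    level: float
    ordering: str
    polygon: object              # shapely (Multi)Polygon
    area: float
    n_fixes: int
    n_hulls: int
    partial: bool = False


def tsd_distance(dxy, dt, s: float, v_max: float):
    """Time-scaled distance for planar offset(s) ``dxy`` (m) and ``dt`` (s)."""
    dxy = np.asarray(dxy, dtype=float)
    planar2 = (dxy ** 2).sum(axis=-1) if dxy.ndim > 1 else float(dxy @ dxy)
    return np.sqrt(planar2 + (s * v_max * np.asarray(dt, dtype=float)) ** 2)


def select_neighbors_adaptive(traj: Trajectory, parent: int, params: TlocohParams,
                              v_max: float | None = None) -> np.ndarray:
    """Adaptive-method neighbour set of one fix (indices, parent included).

    Fixes are sorted by TSD from the parent and taken while the running
    cumulative TSD stays <= a.  At least the 2 nearest neighbours are always
    retained (a hull needs 3 points).
    """
    if traj.n < 3:
        raise ValidationError("adaptive neighbour selection needs >= 3 fixes")
    if v_max is None:
        v_max = compute_vmax(traj)
    xy, ts = traj.xy, traj.t_seconds
    tsd = tsd_distance(xy - xy[parent], ts - ts[parent], params.s, v_max)
    order = np.argsort(tsd, kind="stable")
    csum = np.cumsum(tsd[order])
    count = int(np.searchsorted(csum, params.a, side="right"))
    count = max(count, 3)  # parent + 2 nearest
    return np.sort(order[:count])


def _visit_metrics(times: np.ndarray, ivg: float) -> tuple[int, float]:
    """NSV and MNLV of a sorted time vector: a gap >= ivg starts a new visit."""
    if times.size == 0:
        return 0, 0.0
    nsv = 1 + int(np.count_nonzero(np.diff(times) >= ivg))
    return nsv, times.size / nsv


def time_use_metrics(enclosed_times: np.ndarray, ivg: float = DEFAULT_IVG):
    """(NSV, MNLV) of a hull from the times of its enclosed fixes."""
    return _visit_metrics(np.sort(np.asarray(enclosed_times, dtype=float)), ivg)


def build_hullset(traj: Trajectory, params: TlocohParams,
                  v_max: float | None = None) -> Hullset:
    """Construct one local hull per fix with enclosure and time-use metrics.

    Fixes whose neighbour set is geometrically degenerate (collinear or
    duplicated coordinates, e.g. repeated den fixes) are skipped and reported;
    more than 20% skipped raises :class:`DegenerateError`.  Enclosure
    (``n_enclosed``) counts all trajectory fixes covered by the hull polygon,
    boundary inclusive.
    """
    if traj.n < 3:
        raise ValidationError("hullset needs >= 3 fixes")
    if v_max is None:
        v_max = compute_vmax(traj)
    xy, ts = traj.xy, traj.t_seconds
    n = traj.n
    points = shapely.points(xy[:, 0], xy[:, 1])
    tree = shapely.STRtree(points)

    # Pairwise TSD, vectorised (n^2 memory; fox-season tracks are ~1e3 fixes).
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    dt = ts[:, None] - ts[None, :]
    tsd = np.sqrt(dx * dx + dy * dy + (params.s * v_max * dt) ** 2)

    hulls, skipped = [], []
    for p in range(n):
        order = np.argsort(tsd[p], kind="stable")
        csum = np.cumsum(tsd[p][order])
        count = max(int(np.searchsorted(csum, params.a, side="right")), 3)
        nb = order[:count]
        poly = MultiPoint(xy[nb]).convex_hull
        if poly.geom_type != "Polygon" or poly.area == 0.0:
            skipped.append(p)
            continue
        enclosed = np.sort(tree.query(poly, predicate="covers"))
        nsv, mnlv = _visit_metrics(np.sort(ts[enclosed]), params.ivg)
        hulls.append(Hull(p, np.sort(nb), poly, float(poly.area), enclosed,
                          int(enclosed.size), nsv, mnlv))
    if len(skipped) > 0.2 * n:
        raise DegenerateError(
            f"{len(skipped)}/{n} fixes produced degenerate hulls")
    return Hullset(traj, params, v_max, hulls, skipped)


def _hull_metric(hull: Hull, ordering: str) -> float:
    if ordering == "density":
        return hull.n_enclosed
    if ordering == "nsv":
        return hull.nsv
    if ordering == "mnlv":
        return hull.mnlv
    raise ValidationError(f"unknown ordering {ordering!r}")


def isopleths(hullset: Hullset, ordering: str = "density",
              levels: tuple | None = None) -> list[Isopleth]:
    """Cumulative-union isopleths of a hullset under the given hull ordering.

    Hulls are sorted by the ordering metric (descending), ties broken by
    smaller area first, then earlier parent time — fixed for determinism.
    Hull polygons are united in that order until the fraction of unique
    trajectory fixes enclosed reaches each level, so isopleths at increasing
    levels nest by construction.  A level the full hullset cannot reach is
    returned flagged ``partial``.
    """
    if not hullset.hulls:
        raise ValidationError("empty hullset")
    levels = tuple(sorted(levels if levels is not None else hullset.params.levels))
    ts = hullset.traj.t_seconds
    total = hullset.n_fixes
    order = sorted(
        hullset.hulls,
        key=lambda h: (-_hull_metric(h, ordering), h.area, ts[h.parent]))

    out = []
    covered = np.zeros(total, dtype=bool)
    members: list = []
    it = iter(order)
    for level in levels:
        while covered.sum() < level * total:
            h = next(it, None)
            if h is None:
                break
            members.append(h)
            covered[h.enclosed] = True
        frac = covered.sum() / total
        poly = shapely.unary_union([h.polygon for h in members])
        out.append(Isopleth(level, ordering, poly, float(poly.area),
                            int(covered.sum()), len(members),
                            partial=frac < level))
    return out


def suggest_s(traj: Trajectory, period_of_interest_h: float = 12.0,
              v_max: float | None = None, window: float = 0.5) -> float:
    """Diagnostic balance-point suggestion for the TSD scaling factor s.

    Over fix pairs whose separation lies within ``(1 +/- window)`` of the
    period of interest, returns the s at which the median time term
    ``s * v_max * dt`` equals the median spatial separation — the point where
    time and space contribute equally at the behaviourally relevant
    timescale.  Clamped to [0.001, 1].  A surrogate for the visual s-selection
    tools of the reference workflow; treat it as a starting point.
    """
    if traj.n < 100:
        raise ValidationError("suggest_s needs >= 100 fixes")
    if v_max is None:
        v_max = compute_vmax(traj)
    xy, ts = traj.xy, traj.t_seconds
    period = period_of_interest_h * 3600.0
    i, j = np.triu_indices(traj.n, k=1)
    dt = ts[j] - ts[i]
    sel = (dt >= (1 - window) * period) & (dt <= (1 + window) * period)
    if not sel.any():
        raise ValidationError("no fix pairs near the period of interest")
    d_med = float(np.median(np.hypot(xy[j[sel], 0] - xy[i[sel], 0],
                                     xy[j[sel], 1] - xy[i[sel], 1])))
    t_med = float(np.median(dt[sel]))
    if d_med == 0.0 or v_max == 0.0:
        warnings.warn("degenerate spatial term; s clamped to 0.001", stacklevel=2)
        return 0.001
    return float(np.clip(d_med / (v_max * t_med), 0.001, 1.0))


def suggest_a(traj: Trajectory, s: float, v_max: float | None = None,
              n_neighbors: int = 15) -> float:
    """Diagnostic default for the adaptive threshold ``a``.

    Median over parent fixes of the cumulative TSD to the ``n_neighbors``
    nearest fixes, i.e. the a-value at which a typical hull draws on about
    ``n_neighbors`` points.  A starting value; refine it with
    :func:`enclosed_fraction_curve`.
    """
    if v_max is None:
        v_max = compute_vmax(traj)
    xy, ts = traj.xy, traj.t_seconds
    n = traj.n
    k = min(n_neighbors + 1, n)
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    dt = ts[:, None] - ts[None, :]
    tsd = np.sqrt(dx * dx + dy * dy + (s * v_max * dt) ** 2)
    part = np.partition(tsd, k - 1, axis=1)[:, :k]
    return float(np.median(part.sum(axis=1)))


def enclosed_fraction_curve(traj: Trajectory, s: float, a_values,
                            level: float = 0.95, v_max: float | None = None):
    """Diagnostic curve for choosing ``a``: isopleth coverage fraction vs a.

    Returns (a, fraction of fixes enclosed by the level isopleth) pairs; the
    analyst inspects the curve for the knee, mirroring the graphical
    recommendations of the reference workflow.
    """
    out = []
    for a in a_values:
        hs = build_hullset(traj, TlocohParams(s=s, a=float(a)), v_max=v_max)
        iso = isopleths(hs, "density", (level,))[0]
        out.append((float(a), iso.n_fixes / traj.n))
    return out
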