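"""Synthetic territorial central-place-forager data.

Everything downstream of the collar is testable without field data by
generating tracks with the statistical structure the analysis assumes:

* a discrete-time mean-reverting (Ornstein-Uhlenbeck-like) walk around a den
  reproduces range residency (a plateauing variogram) and den-centred use;
* the fix schedule matches a satellite collar duty cycle of one location per
  1.5-2 h (12-16 fixes/day) over a ~3-month season;
* excursions are injected as smooth out-and-back displacements to a stated
  multiple of the 95% range radius, with a truth mask for recovery tests;
* dyads are generated in three regimes with unambiguous truth — independent
  (no coupling), cohesive (B's shared-area presence scheduled to coincide
  with A's), exclusive (B barred from the shared area while A is present) —
  by manipulating schedules, not step dynamics;
* habitat rasters are seeded nearest-nucleus patch mosaics.

All randomness flows from one seed through ``numpy.random.Generator``
splitting (``rng.spawn``), so a fixed seed reproduces every artefact
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .habitat import HabitatRaster
from .projection import TransverseMercator
from .trajectory import Trajectory

#: Projection anchor for emitting lon/lat: the study system's coastal tundra.
DEFAULT_ANCHOR = (-94.0, 58.0)


@dataclass
class SimConfig:
    """Conditions of a simulated animal-season.

    Defaults emulate the collar schedule (one fix per 1.5-2 h, 12-16/day)
    over a mid-March to mid-June season (92 days), and a territory whose 95%
    range radius is ~2 km: attraction 0.15 per step with 500 m step noise
    gives a stationary positional SD of ~900 m per axis.
    """

    seed: int = 0
    n_days: float = 92.0
    start: str = "2019-03-15T00:00:00Z"
    fix_interval_h: tuple = (1.5, 2.0)
    den: tuple = (0.0, 0.0)
    attraction: float = 0.15        # per-step pull toward the den, in (0, 1]
    step_sd: float = 500.0          # isotropic per-step noise, metres
    # Excursion injection.
    n_excursions: int = 0
    excursion_fixes: int = 6
    excursion_multiplier: float = 10.0
    # Dyad regime.
    regime: str = "independent"     # independent | cohesive | exclusive
    den_separation: float = 3_000.0
    shared_radius: float = 1_500.0
    compliance: float = 0.9
    schedule_jitter_s: float = 120.0
    # Habitat raster.
    habitat_classes: int = 7
    habitat_shape: tuple = (120, 120)
    habitat_cellsize: float = 100.0
    habitat_shares: tuple | None = None
    habitat_seeds_per_class: int = 8
    anchor: tuple = DEFAULT_ANCHOR


def _schedule(cfg: SimConfig, rng) -> np.ndarray:
    """Fix times in seconds from season start, spaced uniform(1.5, 2) h."""
    lo, hi = cfg.fix_interval_h
    n_max = int(cfg.n_days * 24.0 / lo) + 2
    gaps = rng.uniform(lo * 3600.0, hi * 3600.0, size=n_max)
    t = np.cumsum(gaps)
    return t[t <= cfg.n_days * 86_400.0]


def _ou_walk(n: int, den, attraction: float, step_sd: float, rng) -> np.ndarray:
    if not 0 < attraction <= 1:
        raise ConfigurationError("attraction must lie in (0, 1]")
    den = np.asarray(den, dtype=float)
    xy = np.empty((n, 2))
    # Start at the stationary distribution so early fixes are not transient.
    sd0 = step_sd / np.sqrt(1 - (1 - attraction) ** 2) if attraction < 1 else 0.0
    xy[0] = den + rng.normal(0, sd0, 2)
    noise = rng.normal(0, step_sd, (n - 1, 2))
    for i in range(1, n):
        xy[i] = xy[i - 1] + attraction * (den - xy[i - 1]) + noise[i - 1]
    return xy


def _to_trajectory(animal_id, t_rel, xy, cfg: SimConfig,
                   species=None) -> Trajectory:
    proj = TransverseMercator(*cfg.anchor)
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    t0 = pd.Timestamp(cfg.start)
    fixes = pd.DataFrame({
        "t": t0 + pd.to_timedelta(t_rel, unit="s"),
        "lon": lon, "lat": lat, "x": xy[:, 0], "y": xy[:, 1],
    })
    return Trajectory(animal_id, fixes, species=species, projection=proj)


def simulate_forager(cfg: SimConfig, rng=None, animal_id: str = "sim",
                     species: str | None = None) -> Trajectory:
    """One range-resident central-place forager track."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    t_rel = _schedule(cfg, rng)
    xy = _ou_walk(t_rel.size, cfg.den, cfg.attraction, cfg.step_sd, rng)
    return _to_trajectory(animal_id, t_rel, xy, cfg, species)


def range_radius_95(traj: Trajectory) -> float:
    """95th percentile of distance to the track centroid, metres."""
    xy = traj.xy
    c = xy.mean(axis=0)
    return float(np.quantile(np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1]), 0.95))


def inject_excursions(traj: Trajectory, cfg: SimConfig, rng=None):
    """Displace runs of fixes into excursions; returns (Trajectory, truth mask).

    Each excursion displaces ``excursion_fixes`` consecutive fixes along a
    random bearing with a smooth out-and-back profile
    ``multiplier * r95 * sin(pi (i+1)/(k+1)) ** 0.25``; the shallow power
    keeps the animal near the far point for nearly the whole excursion, as a
    fast-travelling forager on a 1.5-2 h fix schedule would appear.
    """
    if cfg.excursion_multiplier <= 1:
        raise ValidationError("excursion distance multiplier must exceed 1")
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    k, n_exc = cfg.excursion_fixes, cfg.n_excursions
    mask = np.zeros(traj.n, dtype=bool)
    if n_exc == 0:
        return traj, mask
    if n_exc * (k + 2) > traj.n:
        raise ValidationError("requested excursions longer than the track")
    r95 = range_radius_95(traj)
    xy = traj.xy.copy()
    # Non-overlapping starts, away from the track ends.
    slots = traj.n // n_exc
    starts = [int(rng.integers(i * slots + 1, (i + 1) * slots - k - 1))
              for i in range(n_exc)]
    profile = np.sin(np.pi * (np.arange(k) + 1) / (k + 1)) ** 0.25
    for s0 in starts:
        theta = rng.uniform(0, 2 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        xy[s0:s0 + k] += np.outer(cfg.excursion_multiplier * r95 * profile, u)
        mask[s0:s0 + k] = True
    fixes = traj.fixes.copy()
    fixes["x"], fixes["y"] = xy[:, 0], xy[:, 1]
    if traj.projection is not None:
        lon, lat = traj.projection.inverse(xy[:, 0], xy[:, 1])
        fixes["lon"], fixes["lat"] = lon, lat
    return traj.with_fixes(fixes), mask


def _push_out_of_disc(xy, center, radius):
    """Reflect points inside the disc radially just outside it."""
    d = xy - center
    r = np.hypot(d[:, 0], d[:, 1])
    inside = r < radius
    if inside.any():
        r_safe = np.where(r[inside] == 0, 1.0, r[inside])
        unit = d[inside] / r_safe[:, None]
        xy = xy.copy()
        xy[inside] = center + unit * (2 * radius - r[inside])[:, None]
    return xy


def simulate_dyad(cfg: SimConfig, rng=None):
    """Two neighbouring tracks plus ground truth for the configured regime.

    Dens sit ``den_separation`` apart with a circular shared zone of radius
    ``shared_radius`` at the midpoint.  B's fix schedule is A's plus a
    +/- ``schedule_jitter_s`` offset (within the simultaneity buffer), so
    every fix forms a simultaneous pair.  Regimes rewire B's shared-zone
    presence only:

    * ``independent`` — A and B are independent walks;
    * ``cohesive`` — whenever A is in the shared zone, B is placed in it too
      with probability ``compliance``;
    * ``exclusive`` — B is pushed out of the shared zone whenever A occupies
      it.

    Returns (traj_a, traj_b, truth) where truth carries the regime, the
    shared-zone geometry and the expected sign of L_ixn.
    """
    if cfg.regime not in ("independent", "cohesive", "exclusive"):
        raise ConfigurationError(f"unknown dyad regime {cfg.regime!r}")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    r_a, r_b, r_reg = rng.spawn(3)
    half = cfg.den_separation / 2.0
    den_a, den_b = np.array([-half, 0.0]), np.array([half, 0.0])
    center = np.array([0.0, 0.0])

    t_a = _schedule(cfg, r_a)
    xy_a = _ou_walk(t_a.size, den_a, cfg.attraction, cfg.step_sd, r_a)
    jitter = r_b.uniform(-cfg.schedule_jitter_s, cfg.schedule_jitter_s, t_a.size)
    t_b = np.sort(t_a + jitter)
    xy_b = _ou_walk(t_b.size, den_b, cfg.attraction, cfg.step_sd, r_b)

    in_a = np.hypot(*(xy_a - center).T) < cfg.shared_radius
    if cfg.regime == "cohesive":
        join = in_a & (r_reg.uniform(size=in_a.size) < cfg.compliance)
        if join.any():
            # Uniform draw inside the shared disc.
            m = int(join.sum())
            rr = cfg.shared_radius * np.sqrt(r_reg.uniform(size=m))
            th = r_reg.uniform(0, 2 * np.pi, m)
            xy_b[join] = center + np.column_stack([rr * np.cos(th),
                                                   rr * np.sin(th)])
    elif cfg.regime == "exclusive":
        xy_b[in_a] = _push_out_of_disc(xy_b[in_a], center, cfg.shared_radius)

    traj_a = _to_trajectory("A", t_a, xy_a, cfg)
    traj_b = _to_trajectory("B", t_b, xy_b, cfg)
    truth = {
        "regime": cfg.regime,
        "shared_center": tuple(center),
        "shared_radius": cfg.shared_radius,
        "expected_l_ixn_sign": {"independent": 0, "cohesive": 1,
                                "exclusive": -1}[cfg.regime],
    }
    return traj_a, traj_b, truth


def generate_habitat_raster(cfg: SimConfig, rng=None) -> HabitatRaster:
    """Seeded nearest-nucleus patch mosaic raster.

    Class nuclei are scattered in numbers proportional to the configured
    shares; each cell takes the class of its nearest nucleus, producing
    contiguous patches with realized areas near the shares.
    """
    if cfg.habitat_classes < 1:
        raise ValidationError("need at least one habitat class")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    nrows, ncols = cfg.habitat_shape
    cs = cfg.habitat_cellsize
    width, height = ncols * cs, nrows * cs
    xll, yll = -width / 2.0, -height / 2.0
    legend = {i + 1: f"class_{i + 1}" for i in range(cfg.habitat_classes)}
    if cfg.habitat_classes == 1:
        return HabitatRaster(np.ones((nrows, ncols), int), cs, xll, yll, legend)
    shares = np.asarray(cfg.habitat_shares if cfg.habitat_shares is not None
                        else np.full(cfg.habitat_classes, 1.0 / cfg.habitat_classes))
    shares = shares / shares.sum()
    per_class = np.maximum(
        1, np.round(shares * cfg.habitat_seeds_per_class
                    * cfg.habitat_classes).astype(int))
    labels = np.repeat(np.arange(1, cfg.habitat_classes + 1), per_class)
    nuclei = np.column_stack([rng.uniform(xll, xll + width, labels.size),
                              rng.uniform(yll, yll + height, labels.size)])
    X, Y = np.meshgrid(xll + (np.arange(ncols) + 0.5) * cs,
                       yll + (nrows - np.arange(nrows) - 0.5) * cs)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    d2 = ((pts[:, None, :] - nuclei[None, :, :]) ** 2).sum(axis=2)
    values = labels[np.argmin(d2, axis=1)].reshape(nrows, ncols)
    return HabitatRaster(values, cs, xll, yll, legend)


def simulate_population(cfg: SimConfig, n_animals: int = 6,
                        species_labels=("AF", "RF"), spacing: float = 4_000.0,
                        rng=None) -> list[Trajectory]:
    """A small neighbourhood of residents on a grid of dens, for smoke tests."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    streams = rng.spawn(n_animals)
    out = []
    cols = int(np.ceil(np.sqrt(n_animals)))
    for i, stream in enumerate(streams):
        den = ((i % cols) * spacing, (i // cols) * spacing)
        c = replace(cfg, den=den)
        sp = species_labels[i % len(species_labels)]
        out.append(simulate_forager(c, rng=stream,
                                    animal_id=f"{sp}{i:02d}", species=sp))
    return out
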