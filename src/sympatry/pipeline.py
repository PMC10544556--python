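"""Configuration-driven orchestration of the full analysis.

``run(config)`` executes screening -> T-LoCoH -> dyad interactions ->
habitat composition -> summary statistics, writing per-stage CSV/GeoJSON
outputs and a machine-readable manifest (parameters, seeds, per-animal
decisions) so a run is reproducible from its manifest alone.  Stage errors
are recorded per animal/dyad and the batch continues where that is safe.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping as shapely_mapping

from ._version import __version__
from .errors import ConfigurationError, DegenerateError, SympatryError
from .habitat import composition_table, read_ascii_grid, reclassify
from .interactions import (DEFAULT_BUFFER, DEFAULT_NEIGHBOR_THRESHOLD,
                           analyze_dyad, find_dyads, overlap_index)
from .screening import assess_residency, empirical_variogram, remove_excursions
from .tlocoh import (DEFAULT_IVG, DEFAULT_LEVELS, TlocohParams, build_hullset,
                     isopleths, suggest_a, suggest_s)
from .trajectory import compute_vmax, project_to_plane, read_fix_table


@dataclass
class RunConfig:
    """Full-run configuration; defaults match the pipeline's standard
    settings (12-h inter-visit gap, 50/95% levels, 3.2 km neighbour rule,
    5-min simultaneity buffer, 999 permutations)."""

    fixes_csv: str = ""
    dialect: dict | None = None
    species: dict = field(default_factory=dict)   # animal id -> label
    out_dir: str = "sympatry_run"
    seed: int = 0
    # Screening.
    variogram_bin_h: float = 24.0
    plateau_window_h: tuple = (120.0, 240.0)
    tail_window_h: tuple = (600.0, 960.0)
    residency_tol: float = 0.5
    # T-LoCoH; per-animal overrides win over globals, absent values are
    # derived per animal from the diagnostics.
    s: float | None = None
    a: float | None = None
    s_by_animal: dict = field(default_factory=dict)
    a_by_animal: dict = field(default_factory=dict)
    ivg: float = DEFAULT_IVG
    levels: tuple = DEFAULT_LEVELS
    # Interactions.
    neighbor_threshold: float = DEFAULT_NEIGHBOR_THRESHOLD
    buffer_s: float = DEFAULT_BUFFER
    p_method: str = "chisq"
    n_perm: int = 999
    # Habitat.
    habitat_raster: str | None = None
    habitat_mapping: dict = field(default_factory=dict)
    habitat_legend: dict = field(default_factory=dict)
    habitat_exclude: tuple = ()
    habitat_stage: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("plateau_window_h", "tail_window_h", "levels",
                    "habitat_exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def polygons_to_geojson(features: list, path):
    """Write (shapely geometry, properties dict) pairs as a GeoJSON file."""
    fc = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "geometry": shapely_mapping(geom),
         "properties": props}
        for geom, props in features]}
    Path(path).write_text(json.dumps(fc))


def overlap_summary(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Per species-pair summary of overlap indices (mean, SE, min, max,
    median, n) — the shape of a published overlap table."""
    def agg(g):
        v = g["overlap"]
        return pd.Series({
            "mean": v.mean(),
            "se": v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            "min": v.min(), "max": v.max(), "median": v.median(),
            "n": len(v)})
    return (overlaps.groupby(["level", "pair_type"])
            .apply(agg, include_groups=False).reset_index())


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written to
    ``out_dir/manifest.json``)."""
    if config.habitat_stage and not config.habitat_raster:
        raise ConfigurationError(
            "habitat stage enabled but no habitat_raster configured")
    if not config.fixes_csv:
        raise ConfigurationError("fixes_csv is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config": _jsonable(asdict(config)),
        "animals": {},
        "dyads": [],
        "errors": {},
    }

    trajectories, report = read_fix_table(config.fixes_csv, config.dialect)
    manifest["read_report"] = _jsonable(asdict(report))
    trajectories = [project_to_plane(tr) for tr in trajectories]

    residents, hullset_by_id = {}, {}
    hr, core = {}, {}
    iso_features, hull_rows, screening_rows = [], [], []
    for tr in trajectories:
        entry: dict = {"n_fixes": tr.n}
        try:
            vg = empirical_variogram(tr, config.variogram_bin_h)
            verdict = assess_residency(vg, config.plateau_window_h,
                                       config.tail_window_h,
                                       config.residency_tol)
            entry["resident"] = bool(verdict.resident)
            entry["variogram_ratio"] = verdict.ratio
            if not verdict.resident:
                manifest["animals"][tr.animal_id] = entry
                continue
            filt = remove_excursions(tr)
            entry["n_excursion_fixes"] = int(filt.flagged.sum())
            entry["n_excursions"] = len(filt.excursions)
            for seg in filt.excursions:
                screening_rows.append({
                    "animal_id": tr.animal_id, "start_fix": seg.start,
                    "stop_fix": seg.stop, "n_fixes": seg.n_fixes,
                    "max_distance_m": seg.max_distance_m})
            kept = filt.kept
            v_max = compute_vmax(kept)
            s = (config.s_by_animal.get(tr.animal_id) or config.s
                 or suggest_s(kept, v_max=v_max))
            a = (config.a_by_animal.get(tr.animal_id) or config.a
                 or suggest_a(kept, s, v_max=v_max))
            entry.update(v_max=v_max, s=s, a=a)
            params = TlocohParams(s=s, a=a, ivg=config.ivg,
                                  levels=config.levels)
            hs = build_hullset(kept, params, v_max=v_max)
            hullset_by_id[tr.animal_id] = hs
            residents[tr.animal_id] = kept
            for ordering in ("density", "nsv", "mnlv"):
                for iso in isopleths(hs, ordering):
                    iso_features.append((iso.polygon, {
                        "animal": tr.animal_id, "level": iso.level,
                        "ordering": ordering, "area_m2": iso.area,
                        "n_fixes": iso.n_fixes}))
                    if ordering == "density":
                        if iso.level == max(config.levels):
                            hr[tr.animal_id] = iso.polygon
                        if iso.level == min(config.levels):
                            core[tr.animal_id] = iso.polygon
            for h in hs.hulls:
                hull_rows.append({
                    "animal_id": tr.animal_id, "parent": h.parent,
                    "area_m2": h.area, "n_enclosed": h.n_enclosed,
                    "nsv": h.nsv, "mnlv": h.mnlv})
        except SympatryError as exc:
            manifest["errors"][tr.animal_id] = str(exc)
        manifest["animals"][tr.animal_id] = _jsonable(entry)

    pd.DataFrame(screening_rows).to_csv(out / "excursions.csv", index=False)
    pd.DataFrame(hull_rows).to_csv(out / "hull_metrics.csv", index=False)
    polygons_to_geojson(iso_features, out / "isopleths.geojson")

    # Dyads.
    species = {aid: config.species.get(aid, "NA") for aid in hr}
    dyads = find_dyads(hr, config.neighbor_threshold, species, cores=core)
    dyad_rows, overlap_rows, shared_features = [], [], []
    rng = np.random.default_rng(config.seed)
    for dy in dyads:
        row = {"A": dy.id_a, "B": dy.id_b, "pair_type": dy.pair_type,
               "boundary_distance_m": dy.boundary_distance}
        ov95 = overlap_index(dy.hr_a, dy.hr_b)
        overlap_rows.append({"A": dy.id_a, "B": dy.id_b, "level": 0.95,
                             "pair_type": dy.pair_type, "overlap": ov95})
        if dy.core_a is not None and dy.core_b is not None:
            overlap_rows.append({
                "A": dy.id_a, "B": dy.id_b, "level": 0.50,
                "pair_type": dy.pair_type,
                "overlap": overlap_index(dy.core_a, dy.core_b)})
        row["overlap_95"] = ov95
        try:
            res = analyze_dyad(dy, residents[dy.id_a], residents[dy.id_b],
                               config.buffer_s, p_method=config.p_method,
                               n_rotations=config.n_perm, rng=rng)
            odds = res.temporal.table.odds
            row.update({
                "L_A": res.spatial_a.L, "p_A": res.spatial_a.p,
                "L_B": res.spatial_b.L, "p_B": res.spatial_b.p,
                "L_ixn": res.temporal.L_ixn, "p_ixn": res.temporal.p,
                "spatial_label": res.spatial_label,
                "temporal_label": res.temporal_label,
                "odds_AB": odds[0], "odds_A0": odds[1],
                "odds_0B": odds[2], "odds_00": odds[3]})
            shared_features.append((dy.shared, {"A": dy.id_a, "B": dy.id_b}))
        except SympatryError as exc:
            row["error"] = str(exc)
            manifest["errors"][f"{dy.id_a}-{dy.id_b}"] = str(exc)
        dyad_rows.append(row)
        manifest["dyads"].append(
            {k: _jsonable(v) for k, v in row.items()})
    pd.DataFrame(dyad_rows).to_csv(out / "dyads.csv", index=False)
    overlaps = pd.DataFrame(overlap_rows)
    overlaps.to_csv(out / "overlaps.csv", index=False)
    if len(overlaps):
        overlap_summary(overlaps).to_csv(out / "overlap_summary.csv",
                                         index=False)
    polygons_to_geojson(shared_features, out / "shared_areas.geojson")

    # Habitat composition of the 50% NSV / MNLV isopleths.
    if config.habitat_raster:
        raster = read_ascii_grid(config.habitat_raster,
                                 legend=config.habitat_legend or None)
        if config.habitat_mapping:
            raster = reclassify(raster,
                                {int(k): int(v) for k, v
                                 in config.habitat_mapping.items()},
                                config.habitat_legend or None)
        polys = {}
        for aid, hs in hullset_by_id.items():
            polys[aid] = {}
            for ordering in ("nsv", "mnlv"):
                iso = isopleths(hs, ordering, (min(config.levels),))[0]
                polys[aid][ordering] = iso.polygon
        table, errors = composition_table(
            polys, raster, set(config.habitat_exclude))
        table.to_csv(out / "habitat_composition.csv", index=False)
        for key, exc in errors.items():
            manifest["errors"][f"habitat:{key}"] = str(exc)
        manifest["habitat_rows"] = len(table)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj
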