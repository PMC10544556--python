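"""Categorical landcover rasters and habitat composition of isopleths.

Rasters are plain integer class grids with square cells, read and written as
ESRI ASCII grids (a simple, text-based interchange format).  Landcover
products usually carry many fine classes; :func:`reclassify` collapses them
to the handful that matter for the analysis (e.g. barren land, wetland,
tundra, shrubland, forest, intertidal flats, sea ice).  Composition of a
polygon (typically a 50% NSV or MNLV isopleth) uses the deterministic
cell-centre rule: a cell contributes iff its centre lies in the polygon, and
proportions are computed over non-excluded classes (water and infrastructure
are excluded by configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError, DegenerateError, ValidationError

DEFAULT_NODATA = -9999


@dataclass
class HabitatRaster:
    """Integer class grid.  Row 0 is the *top* row (ESRI ASCII convention)."""

    values: np.ndarray             # (nrows, ncols) int
    cellsize: float                # metres
    xll: float                     # x of lower-left corner
    yll: float
    legend: dict = field(default_factory=dict)   # class id -> name
    nodata: int = DEFAULT_NODATA

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")
        self.values = np.asarray(self.values, dtype=int)

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        """(X, Y) centre coordinate grids matching ``values``."""
        nrows, ncols = self.values.shape
        xs = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        ys = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)


@dataclass
class HabitatComposition:
    animal_id: str | None
    ordering: str | None
    proportions: dict              # class id -> fraction of included cells
    excluded_fraction: float
    n_cells: int


def read_ascii_grid(path, legend: dict | None = None) -> HabitatRaster:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value"):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    values = np.loadtxt(lines[i:], dtype=float).reshape(
        int(header["nrows"]), int(header["ncols"])).astype(int)
    cs = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0) - cs / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0) - cs / 2)
    return HabitatRaster(values, cs, xll, yll, legend or {},
                         int(header.get("nodata_value", DEFAULT_NODATA)))


def write_ascii_grid(raster: HabitatRaster, path):
    """Write an ESRI ASCII grid (.asc)."""
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {raster.xll}\nyllcorner {raster.yll}\n"
                 f"cellsize {raster.cellsize}\nNODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.values, fmt="%d")


def reclassify(raster: HabitatRaster, mapping: dict,
               legend: dict | None = None) -> HabitatRaster:
    """Relabel every cell through ``mapping`` (original id -> target id).

    Every value present in the grid must appear in the mapping or equal the
    no-data value; otherwise a :class:`ConfigurationError` names the
    offending ids.
    """
    present = set(np.unique(raster.values).tolist()) - {raster.nodata}
    unmapped = sorted(present - set(mapping))
    if unmapped:
        raise ConfigurationError(f"raster values not in mapping: {unmapped}")
    out = np.full_like(raster.values, raster.nodata)
    for src, dst in mapping.items():
        out[raster.values == src] = dst
    return replace(raster, values=out, legend=dict(legend or {}))


def composition(polygon, raster: HabitatRaster, exclude: set | frozenset = frozenset(),
                animal_id: str | None = None,
                ordering: str | None = None) -> HabitatComposition:
    """Habitat class proportions of the raster cells whose centres lie in
    ``polygon``, computed over non-excluded, non-nodata cells."""
    X, Y = raster.cell_centers()
    inside = shapely.intersects_xy(polygon, X.ravel(), Y.ravel())
    vals = raster.values.ravel()[inside]
    vals = vals[vals != raster.nodata]
    n_covered = vals.size
    if n_covered == 0:
        raise DegenerateError("polygon covers no raster cells")
    excluded = np.isin(vals, list(exclude)) if exclude else np.zeros(vals.shape, bool)
    included = vals[~excluded]
    if included.size == 0:
        raise DegenerateError("all covered cells are excluded classes")
    ids, counts = np.unique(included, return_counts=True)
    props = {int(i): float(c) / included.size for i, c in zip(ids, counts)}
    return HabitatComposition(animal_id, ordering, props,
                              float(excluded.sum()) / n_covered, int(included.size))


def composition_table(isopleth_polygons: dict, raster: HabitatRaster,
                      exclude: set | frozenset = frozenset()):
    """Long-format composition table, one row per animal x ordering x class.

    ``isopleth_polygons`` maps animal id -> {ordering -> polygon} (typically
    the 50% NSV and MNLV isopleths).  Classes absent inside a polygon get
    proportion 0 so every group has the full class roster — the shape
    multivariate tests expect.  Per-animal failures are collected, not
    raised.

    Returns (DataFrame, dict of errors keyed by (animal, ordering)).
    """
    classes = sorted(set(raster.legend) or
                     set(np.unique(raster.values).tolist()) - {raster.nodata})
    classes = [c for c in classes if c not in exclude]
    rows, errors = [], {}
    for animal, by_ordering in isopleth_polygons.items():
        for ordering, poly in by_ordering.items():
            try:
                comp = composition(poly, raster, exclude, animal, ordering)
            except (DegenerateError, ValidationError) as exc:
                errors[(animal, ordering)] = exc
                continue
            for cid in classes:
                rows.append({
                    "animal_id": animal,
                    "ordering": ordering,
                    "class_id": cid,
                    "class_name": raster.legend.get(cid, str(cid)),
                    "proportion": comp.proportions.get(cid, 0.0),
                })
    return pd.DataFrame(rows), errors
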