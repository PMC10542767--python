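"""Raster I/O, per-cell pipeline execution and area bookkeeping.

Everything here works on ESRI ASCII grids: a 6-line text header (ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value) followed by whitespace-separated
values, rows top-down. Geographic lat/lon coordinates, origin at the lower-left
corner, cell centers half a cell in. Nodata cells are represented as NaN in
memory and never enter any statistic.

Cell areas for the continental tabulation use a spherical Earth with
111.32 km per degree: area = (cellsize * 111.32)^2 * cos(latitude at the cell
center), accurate to well under a percent for the bookkeeping this supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import indices as _indices
from .lifetable import CellSimulator
from .thermal import PhenologyModel

KM_PER_DEGREE = 111.32

ERI_CLASS_LABELS = _indices.ERI_CLASS_LABELS


class AsciiGridError(ValueError):
    """Malformed ESRI ASCII grid."""


@dataclass
class Raster:
    """One georeferenced layer; NaN marks nodata in ``data``."""

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    index_kind: Optional[str] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("raster data must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self):
        return self.data.shape[0]

    @property
    def n_cols(self):
        return self.data.shape[1]

    def lat_centers(self):
        """Latitude of cell centers per array row (row 0 = top)."""
        top = self.yllcorner + self.n_rows * self.cellsize
        return top - (np.arange(self.n_rows) + 0.5) * self.cellsize

    def lon_centers(self):
        return self.xllcorner + (np.arange(self.n_cols) + 0.5) * self.cellsize

    def same_georef(self, other: "Raster") -> bool:
        return (self.data.shape == other.data.shape
                and np.isclose(self.xllcorner, other.xllcorner)
                and np.isclose(self.yllcorner, other.yllcorner)
                and np.isclose(self.cellsize, other.cellsize))

    def cell_areas_km2(self):
        """Per-cell area (km^2), cos-latitude spherical approximation."""
        lat = np.radians(self.lat_centers())
        row_area = (self.cellsize * KM_PER_DEGREE) ** 2 * np.cos(lat)
        return np.repeat(row_area[:, None], self.n_cols, axis=1)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines[:6], start=1):
        parts = line.split()
        if len(parts) != 2:
            raise AsciiGridError(f"{path}: malformed header at line {lineno}: {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise AsciiGridError(f"{path}: unexpected header key at line {lineno}: {parts[0]!r}")
        header[key] = float(parts[1])
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise AsciiGridError(f"{path}: header missing {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for lineno, line in enumerate(lines[6:], start=7):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != ncols:
            raise AsciiGridError(
                f"{path}: line {lineno} has {len(vals)} values, expected {ncols}")
        rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise AsciiGridError(f"{path}: expected {nrows} data rows, found {len(rows)}")
    data = np.asarray(rows, dtype=float)
    nodata = header["nodata_value"]
    data[data == nodata] = np.nan
    return Raster(data, header["xllcorner"], header["yllcorner"],
                  header["cellsize"], nodata)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; values use shortest round-trip float repr."""
    path = Path(path)
    out = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.xllcorner!r}\n")
        fh.write(f"yllcorner {raster.yllcorner!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


@dataclass
class TemperatureGrid:
    """12 monthly minimum and 12 monthly maximum layers, shared georeferencing."""

    tmin: np.ndarray  # (12, nrows, ncols), NaN = nodata
    tmax: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        if self.tmin.shape != self.tmax.shape or self.tmin.shape[0] != 12:
            raise ValueError("tmin/tmax must both have shape (12, nrows, ncols)")
        both = np.isfinite(self.tmin) & np.isfinite(self.tmax)
        if np.any(self.tmax[both] < self.tmin[both]):
            raise ValueError("monthly maximum below monthly minimum")

    @property
    def shape(self):
        return self.tmin.shape[1:]

    def _layer(self, data, kind=None):
        return Raster(data, self.xllcorner, self.yllcorner, self.cellsize,
                      self.nodata, index_kind=kind)

    def valid_mask(self):
        return np.all(np.isfinite(self.tmin), axis=0) & np.all(
            np.isfinite(self.tmax), axis=0)

    def save(self, directory) -> list:
        """Write tmin_01.asc .. tmax_12.asc into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for kind, stack in (("tmin", self.tmin), ("tmax", self.tmax)):
            for m in range(12):
                p = directory / f"{kind}_{m + 1:02d}.asc"
                write_ascii_grid(self._layer(stack[m]), p)
                paths.append(p)
        return paths

    @classmethod
    def load(cls, directory) -> "TemperatureGrid":
        directory = Path(directory)
        layers = {}
        for kind in ("tmin", "tmax"):
            stack = []
            for m in range(12):
                p = directory / f"{kind}_{m + 1:02d}.asc"
                if not p.exists():
                    raise FileNotFoundError(f"missing temperature layer {p}")
                stack.append(read_ascii_grid(p))
            layers[kind] = stack
        ref = layers["tmin"][0]
        for r in layers["tmin"] + layers["tmax"]:
            if not ref.same_georef(r):
                raise ValueError(f"{directory}: temperature layers disagree in georeferencing")
        return cls(np.stack([r.data for r in layers["tmin"]]),
                   np.stack([r.data for r in layers["tmax"]]),
                   ref.xllcorner, ref.yllcorner, ref.cellsize, ref.nodata)


@dataclass
class IndexResult:
    """The three index rasters plus the five-class ERI classification."""

    eri: Raster
    gi: Raster
    ai: Raster
    eri_class: Raster  # class codes 0..4, NaN = nodata

    def as_frame(self) -> pd.DataFrame:
        """Per-cell table: cell_id, lon, lat, eri, gi, ai, eri_class."""
        lat = self.eri.lat_centers()
        lon = self.eri.lon_centers()
        rows = []
        nrows, ncols = self.eri.data.shape
        for r in range(nrows):
            for c in range(ncols):
                e = self.eri.data[r, c]
                label = (ERI_CLASS_LABELS[int(self.eri_class.data[r, c])]
                         if np.isfinite(self.eri_class.data[r, c]) else "")
                rows.append((r * ncols + c, lon[c], lat[r], e,
                             self.gi.data[r, c], self.ai.data[r, c], label))
        return pd.DataFrame(rows, columns=["cell_id", "lon", "lat", "eri",
                                           "gi", "ai", "eri_class"])


def map_indices(grid: TemperatureGrid, model: PhenologyModel, *,
                survival_threshold: float = 0.01,
                reproduction_rule: str = "indicator",
                lambda_floor: float = 1e-6,
                horizon: int = 500,
                cache_decimals: int = 2) -> IndexResult:
    """Run the daily life-table pipeline for every valid grid cell.

    Cells whose 24 monthly values agree after rounding to ``cache_decimals``
    share one simulation; results are cellwise-pure so cell order is
    irrelevant. Nodata propagates to all three indices.
    """
    nrows, ncols = grid.shape
    eri = np.full((nrows, ncols), np.nan)
    gi = np.full((nrows, ncols), np.nan)
    ai = np.full((nrows, ncols), np.nan)
    cls = np.full((nrows, ncols), np.nan)

    sim = CellSimulator(model, horizon=horizon, cache_decimals=cache_decimals)
    valid = grid.valid_mask()
    cell_cache = {}
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            tmin12 = grid.tmin[:, r, c]
            tmax12 = grid.tmax[:, r, c]
            key = tuple(np.round(np.concatenate([tmin12, tmax12]),
                                 cache_decimals))
            if key not in cell_cache:
                series = sim.daily_series(tmin12, tmax12)
                e = _indices.compute_eri(series,
                                         survival_threshold=survival_threshold,
                                         reproduction_rule=reproduction_rule)
                g = _indices.compute_gi(series)
                a = _indices.compute_ai(series, lambda_floor=lambda_floor)
                cell_cache[key] = (e, g, a, _indices.classify_eri(e).code)
            eri[r, c], gi[r, c], ai[r, c], cls[r, c] = cell_cache[key]

    geo = dict(xllcorner=grid.xllcorner, yllcorner=grid.yllcorner,
               cellsize=grid.cellsize, nodata=grid.nodata)
    return IndexResult(
        eri=Raster(eri, index_kind="eri", **geo),
        gi=Raster(gi, index_kind="gi", **geo),
        ai=Raster(ai, index_kind="ai", **geo),
        eri_class=Raster(cls, index_kind="eri_class", **geo))


# ---------------------------------------------------------------------------
# area bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class AreaTable:
    """Per-region, per-ERI-class area (km^2) and percent of the region total."""

    table: pd.DataFrame  # region, eri_class, area_km2, pct_of_region_total
    region_totals: dict

    @classmethod
    def from_class_areas(cls, class_areas: dict, region: str = "all",
                         region_total: Optional[float] = None) -> "AreaTable":
        """Build a table from {class label: area}; percentages against
        ``region_total`` (default: the sum of the class areas)."""
        total = float(region_total if region_total is not None
                      else sum(class_areas.values()))
        rows = [(region, label, float(a), 100.0 * float(a) / total)
                for label, a in class_areas.items()]
        return cls(pd.DataFrame(rows, columns=["region", "eri_class",
                                               "area_km2",
                                               "pct_of_region_total"]),
                   {region: total})

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def tabulate_area(eri_raster: Raster, region_mask: Optional[Raster] = None) -> AreaTable:
    """Tabulate km^2 per region and ERI suitability class.

    ``region_mask`` holds integer region labels (same georeferencing); cells
    without a label are counted under region ``"unassigned"``. Without a mask
    everything falls in one region ``"all"``.
    """
    if region_mask is not None and not eri_raster.same_georef(region_mask):
        raise ValueError("region mask georeferencing differs from the index raster")
    areas = eri_raster.cell_areas_km2()
    valid = np.isfinite(eri_raster.data)
    codes = np.full(eri_raster.data.shape, -1, dtype=int)
    codes[valid] = [_indices.classify_eri(float(v)).code
                    for v in eri_raster.data[valid]]
    if region_mask is None:
        regions = np.where(valid, 0, -999)
        labels = {0: "all"}
    else:
        rm = region_mask.data
        regions = np.where(valid & np.isfinite(rm), rm, np.nan)
        regions = np.where(valid & ~np.isfinite(rm), -1, regions)
        labels = {int(v): str(int(v)) for v in np.unique(regions[np.isfinite(regions)])
                  if v >= 0}
        labels[-1] = "unassigned"
        regions = np.where(np.isfinite(regions), regions, -999).astype(int)

    rows = []
    totals = {}
    for rid, rname in sorted(labels.items()):
        in_region = (regions == rid) & valid
        if not np.any(in_region):
            continue
        total = float(areas[in_region].sum())
        totals[rname] = total
        for code, label in enumerate(ERI_CLASS_LABELS):
            a = float(areas[in_region & (codes == code)].sum())
            rows.append((rname, label, a, 100.0 * a / total if total else 0.0))
    return AreaTable(pd.DataFrame(rows, columns=["region", "eri_class",
                                                 "area_km2",
                                                 "pct_of_region_total"]),
                     totals)


def change_map(current: Raster, future: Raster) -> Raster:
    """Per-cell future - current difference; nodata if either side is nodata."""
    if current.index_kind != future.index_kind:
        raise ValueError(
            f"index kinds differ: {current.index_kind!r} vs {future.index_kind!r}")
    if not current.same_georef(future):
        raise ValueError("rasters differ in georeferencing")
    diff = future.data - current.data
    return Raster(diff, current.xllcorner, current.yllcorner, current.cellsize,
                  current.nodata,
                  index_kind=f"{current.index_kind}_change" if current.index_kind else "change")


def area_change_summary(current: AreaTable, future: AreaTable) -> pd.DataFrame:
    """Signed per-class area changes; percent relative to the region total.

    Columns: region, eri_class, area_current, area_future, change_km2,
    change_pct (of the region's current total area).
    """
    if set(current.region_totals) != set(future.region_totals):
        raise ValueError("area tables cover different regions")
    cur = current.table.rename(columns={"area_km2": "area_current"})
    fut = future.table.rename(columns={"area_km2": "area_future"})
    merged = cur[["region", "eri_class", "area_current"]].merge(
        fut[["region", "eri_class", "area_future"]],
        on=["region", "eri_class"], how="outer", sort=False)
    if merged[["area_current", "area_future"]].isna().any().any():
        raise ValueError("area tables use different class schemes")
    merged["change_km2"] = merged["area_future"] - merged["area_current"]
    merged["change_pct"] = [
        100.0 * ch / current.region_totals[reg]
        for reg, ch in zip(merged["region"], merged["change_km2"])]
    return merged
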