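"""Regular lon/lat rasters and stacks of suitability layers.

:class:`Grid` is a minimal regular-grid raster (row 0 = northernmost row,
as in ESRI ASCII grids) with plain-text I/O.  :class:`SuitabilityStack`
holds the full factorial set of suitability layers indexed by
(algorithm, AOGCM, period) together with per-(algorithm, AOGCM) True Skill
Statistic weights, and can be written to / read from a directory of ASCII
grids plus a CSV manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_PERIODS = ("21ka", "6ka", "0ka")


@dataclass
class Grid:
    """Raster of values on a regular lon/lat grid.

    ``data`` has shape ``(nrows, ncols)`` with row 0 at the top (north);
    ``xll, yll`` are the lower-left corner coordinates and ``cellsize`` the
    cell edge in degrees.
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 0.5
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("grid data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of cell-centre coordinates, same shape as data."""
        nrows, ncols = self.shape
        lon = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        lat = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        nrows, ncols = self.shape
        col = int(np.floor((lon - self.xll) / self.cellsize))
        row = int(np.floor((self.yll + nrows * self.cellsize - lat) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    # ------------------------------------------------------------------ #
    # ESRI ASCII grid I/O (plain text)

    def write_ascii(self, path) -> None:
        nrows, ncols = self.shape
        data = np.where(np.isnan(self.data), self.nodata, self.data)
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.xll}\n"
            f"yllcorner {self.yll}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {self.nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Grid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                header[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        return cls(
            data=data,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cellsize=header["cellsize"],
            nodata=nodata,
        )


@dataclass
class SuitabilityStack:
    """Full factorial stack of suitability maps with TSS weights.

    ``values`` has shape ``(n_algorithms, n_aogcms, n_periods, nrows,
    ncols)`` with suitabilities in [0, 1]; ``tss`` has shape
    ``(n_algorithms, n_aogcms)`` with values in [-1, 1].
    """

    values: np.ndarray
    algorithms: list[str]
    aogcms: list[str]
    periods: list[str]
    tss: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tss = np.asarray(self.tss, dtype=float)
        expected = (len(self.algorithms), len(self.aogcms), len(self.periods))
        if self.values.ndim != 5 or self.values.shape[:3] != expected:
            raise ValueError(f"values must have shape {expected} + grid shape")
        if self.tss.shape != expected[:2]:
            raise ValueError("tss must be indexed by (algorithm, aogcm)")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.algorithms) * len(self.aogcms) * len(self.periods)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[3:]

    def layer(self, algorithm, aogcm, period) -> Grid:
        ia = self.algorithms.index(algorithm) if isinstance(algorithm, str) else algorithm
        ig = self.aogcms.index(aogcm) if isinstance(aogcm, str) else aogcm
        ip = self.periods.index(period) if isinstance(period, str) else period
        return Grid(self.values[ia, ig, ip], self.xll, self.yll, self.cellsize)

    def _grid(self, data: np.ndarray) -> Grid:
        return Grid(data, self.xll, self.yll, self.cellsize)

    # ------------------------------------------------------------------ #
    # directory + manifest I/O

    def write(self, directory) -> Path:
        """Write all layers as ASCII grids plus a manifest.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for ia, alg in enumerate(self.algorithms):
            for ig, gcm in enumerate(self.aogcms):
                for ip, per in enumerate(self.periods):
                    name = f"{alg}_{gcm}_{per}.asc"
                    self.layer(ia, ig, ip).write_ascii(directory / name)
                    rows.append(
                        {
                            "algorithm": alg,
                            "aogcm": gcm,
                            "period": per,
                            "path": name,
                            "tss": self.tss[ia, ig],
                        }
                    )
        manifest = directory / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def read(cls, manifest_path) -> "SuitabilityStack":
        """Load a stack from a manifest (algorithm, aogcm, period, path, tss)."""
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path)
        required = {"algorithm", "aogcm", "period", "path", "tss"}
        if missing := required - set(df.columns):
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        algorithms = list(dict.fromkeys(df["algorithm"]))
        aogcms = list(dict.fromkeys(df["aogcm"]))
        periods = list(dict.fromkeys(df["period"]))
        first = Grid.read_ascii(manifest_path.parent / df["path"].iloc[0])
        values = np.full(
            (len(algorithms), len(aogcms), len(periods)) + first.shape, np.nan
        )
        tss = np.full((len(algorithms), len(aogcms)), np.nan)
        for _, row in df.iterrows():
            g = Grid.read_ascii(manifest_path.parent / row["path"])
            if not g.same_geometry(first):
                raise ValueError(f"layer {row['path']} has mismatched grid geometry")
            ia = algorithms.index(row["algorithm"])
            ig = aogcms.index(row["aogcm"])
            ip = periods.index(row["period"])
            values[ia, ig, ip] = g.data
            tss[ia, ig] = row["tss"]
        if np.isnan(values).all(axis=(3, 4)).any():
            raise ValueError("manifest does not cover the full factorial design")
        return cls(
            values=values,
            algorithms=algorithms,
            aogcms=aogcms,
            periods=periods,
            tss=tss,
            xll=first.xll,
            yll=first.yll,
            cellsize=first.cellsize,
        )
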