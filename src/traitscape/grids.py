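"""Grid specification and gridded environmental predictor stacks.

The pipeline works on a regular lon/lat grid (default 0.5 degree, global
origin at (-180, -90)) with six environmental predictor layers:

==========  =======================================  ==================
name        meaning                                  units
==========  =======================================  ==================
tmin        minimum temperature of coldest month     degrees C
humind      humidity index (precip / PET)            dimensionless
precdryq    precipitation of the driest quarter      mm
precseas    precipitation seasonality (CV monthly)   percent
cec         soil cation exchange capacity (0-30 cm)  cmol+ / kg
ph          soil pH (0-30 cm)                        pH units
==========  =======================================  ==================

Layers are stored as ``(n_rows, n_cols)`` arrays (row 0 = southernmost).
Cells are half-open ``[edge, edge + cell_size)``; a point exactly on a
shared edge belongs to the cell whose lower edge it sits on.  A longitude
of exactly +180 wraps to -180 and a latitude of exactly +90 is clamped to
the top row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PREDICTORS: tuple[str, ...] = ("tmin", "humind", "precdryq", "precseas", "cec", "ph")

#: physical default range of each predictor layer (min, max)
PREDICTOR_RANGES: dict[str, tuple[float, float]] = {
    "tmin": (-35.0, 25.0),
    "humind": (0.05, 3.0),
    "precdryq": (0.0, 800.0),
    "precseas": (5.0, 120.0),
    "cec": (2.0, 60.0),
    "ph": (3.5, 9.0),
}

PREDICTOR_UNITS: dict[str, str] = {
    "tmin": "degC",
    "humind": "1",
    "precdryq": "mm",
    "precseas": "%",
    "cec": "cmol+/kg",
    "ph": "pH",
}


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid; ``origin`` is the lower-left cell edge."""

    origin_lon: float = -180.0
    origin_lat: float = -90.0
    cell_size: float = 0.5
    n_cols: int = 720
    n_rows: int = 360

    def __post_init__(self) -> None:
        if self.n_cols < 1:
            raise ValueError(f"n_cols must be positive, got {self.n_cols}")
        if self.n_rows < 1:
            raise ValueError(f"n_rows must be positive, got {self.n_rows}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (col, row) cell indices (half-open cells)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # +180 wraps onto the -180 meridian; +90 clamps to the top row
        lon = np.where(lon >= 180.0, lon - 360.0, lon)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin_lat) / self.cell_size).astype(int)
        row = np.minimum(row, self.n_rows - 1)
        return col, row

    def cell_center(self, col, row) -> tuple[np.ndarray, np.ndarray]:
        col = np.asarray(col)
        row = np.asarray(row)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat + (row + 0.5) * self.cell_size
        return lon, lat

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def to_dict(self) -> dict:
        return {
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class PredictorStack:
    """Six named predictor layers sharing one grid and one validity mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError(f"mask shape {self.mask.shape} != grid shape {shape}")
        for name, layer in self.layers.items():
            if layer.shape != shape:
                raise ValueError(
                    f"layer {name!r} shape {layer.shape} != grid shape {shape}"
                )
        self._check_physical()

    def _check_physical(self) -> None:
        def _valid(name):
            v = self.layers.get(name)
            if v is None:
                return None
            return v[self.mask & np.isfinite(v)]

        ph = _valid("ph")
        if ph is not None and ph.size and (ph.min() < 0 or ph.max() > 14):
            raise ValueError("ph values must lie in [0, 14]")
        for name in ("precdryq", "precseas", "humind"):
            v = _valid(name)
            if v is not None and v.size and v.min() < 0:
                raise ValueError(f"{name} values must be non-negative")

    @property
    def predictor_names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, col, row) -> pd.DataFrame:
        """Predictor values at the given cells (NaN outside the mask)."""
        col = np.asarray(col, dtype=int)
        row = np.asarray(row, dtype=int)
        out = {}
        inside = (
            (col >= 0)
            & (col < self.grid.n_cols)
            & (row >= 0)
            & (row < self.grid.n_rows)
        )
        valid = np.zeros(col.shape, dtype=bool)
        valid[inside] = self.mask[row[inside], col[inside]]
        for name, layer in self.layers.items():
            v = np.full(col.shape, np.nan)
            v[valid] = layer[row[valid], col[valid]]
            out[name] = v
        return pd.DataFrame(out)

    def to_frame(self) -> pd.DataFrame:
        """Long table (col, row, lon, lat, predictor columns) of valid cells."""
        rows, cols = np.nonzero(self.mask)
        lon, lat = self.grid.cell_center(cols, rows)
        df = pd.DataFrame({"col": cols, "row": rows, "lon": lon, "lat": lat})
        for name, layer in self.layers.items():
            df[name] = layer[rows, cols]
        return df

    # -- plain-text round trip (cell CSV + JSON grid-spec sidecar) ----------

    def write_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".gridspec.json")
        sidecar.write_text(json.dumps(self.grid.to_dict(), sort_keys=True))

    @classmethod
    def read_csv(cls, path) -> "PredictorStack":
        path = Path(path)
        grid = GridSpec.from_dict(
            json.loads(path.with_suffix(".gridspec.json").read_text())
        )
        df = pd.read_csv(path)
        shape = (grid.n_rows, grid.n_cols)
        mask = np.zeros(shape, dtype=bool)
        mask[df["row"], df["col"]] = True
        layers = {}
        for name in df.columns:
            if name in ("col", "row", "lon", "lat"):
                continue
            layer = np.full(shape, np.nan)
            layer[df["row"], df["col"]] = df[name]
            layers[name] = layer
        return cls(grid=grid, layers=layers, mask=mask)
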