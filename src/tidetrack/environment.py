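"""Regular lon/lat environment grids: bathymetry, M2 tide, seasonal temperature.

The grid is the state space of the geolocation hidden Markov model.  Cells
are centre-registered; ``bathymetry`` is metres positive-down with values
``<= 0`` marking land.  Tidal forcing is a single harmonic constituent
(amplitude in metres, phase in radians) and the temperature field is a
seasonal sinusoid about a per-cell mean, peaking on ``temp_peak_doy``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: kilometres per degree of latitude on the reference sphere
KM_PER_DEG_LAT = 111.32

#: period of the principal lunar semidiurnal (M2) tidal constituent, hours
M2_PERIOD_HOURS = 12.4206

DAYS_PER_YEAR = 365.25


@dataclass
class EnvironmentGrid:
    """Regular lon/lat grid of environmental fields.

    Parameters
    ----------
    lon_centers, lat_centers
        1-D arrays of cell-centre coordinates (degrees), strictly increasing
        and uniformly spaced.
    bathymetry
        ``(ny, nx)`` seabed depth, metres positive-down; ``<= 0`` is land.
    tide_amplitude, tide_phase
        ``(ny, nx)`` M2 amplitude (m, ``>= 0``) and phase (radians in
        ``[0, 2*pi)``).
    temp_mean, temp_seasonal_amplitude
        ``(ny, nx)`` annual-mean temperature (degC) and the amplitude of the
        seasonal sinusoid about it.
    temp_peak_doy
        Day-of-year at which temperature peaks (default mid-August).
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    bathymetry: np.ndarray
    tide_amplitude: np.ndarray
    tide_phase: np.ndarray
    temp_mean: np.ndarray
    temp_seasonal_amplitude: np.ndarray
    temp_peak_doy: float = 227.0

    def __post_init__(self) -> None:
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        for name in ("bathymetry", "tide_amplitude", "tide_phase",
                     "temp_mean", "temp_seasonal_amplitude"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (self.ny, self.nx):
                raise ValueError(f"{name} must have shape (ny, nx)={self.ny, self.nx}, "
                                 f"got {arr.shape}")
        for axis in (self.lon_centers, self.lat_centers):
            d = np.diff(axis)
            if len(axis) < 2 or np.any(d <= 0) or not np.allclose(d, d[0]):
                raise ValueError("grid axes must be strictly increasing and uniform")
        if np.any(self.tide_amplitude < 0):
            raise ValueError("tide amplitude must be >= 0")
        if np.any((self.tide_phase < 0) | (self.tide_phase >= 2 * np.pi)):
            raise ValueError("tide phase must lie in [0, 2*pi)")
        if not self.sea.any():
            raise ValueError("grid has no sea cells")

    # -- geometry -------------------------------------------------------

    @property
    def nx(self) -> int:
        return len(self.lon_centers)

    @property
    def ny(self) -> int:
        return len(self.lat_centers)

    @property
    def dlon(self) -> float:
        return float(self.lon_centers[1] - self.lon_centers[0])

    @property
    def dlat(self) -> float:
        return float(self.lat_centers[1] - self.lat_centers[0])

    @property
    def central_lat(self) -> float:
        return float(np.mean(self.lat_centers))

    @property
    def km_per_deg_lon(self) -> float:
        """km per degree of longitude at the domain's central latitude."""
        return KM_PER_DEG_LAT * math.cos(math.radians(self.central_lat))

    @property
    def cell_width_km(self) -> float:
        """Characteristic cell width: mean of the lon and lat cell extents in km."""
        return 0.5 * (self.dlat * KM_PER_DEG_LAT + self.dlon * self.km_per_deg_lon)

    @property
    def sea(self) -> np.ndarray:
        """Boolean ``(ny, nx)`` mask of sea cells."""
        return self.bathymetry > 0

    # -- lookups --------------------------------------------------------

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """Nearest-cell (row, col) of a position; raises if outside the grid."""
        i = round((lat - self.lat_centers[0]) / self.dlat)
        j = round((lon - self.lon_centers[0]) / self.dlon)
        if not (0 <= i < self.ny and 0 <= j < self.nx):
            raise ValueError(f"position ({lat}, {lon}) outside grid")
        return int(i), int(j)

    def contains(self, lat: float, lon: float) -> bool:
        half_lat, half_lon = self.dlat / 2, self.dlon / 2
        return (self.lat_centers[0] - half_lat <= lat <= self.lat_centers[-1] + half_lat
                and self.lon_centers[0] - half_lon <= lon <= self.lon_centers[-1] + half_lon)

    def is_sea(self, lat: float, lon: float) -> bool:
        if not self.contains(lat, lon):
            return False
        i, j = self.cell_index(lat, lon)
        return bool(self.sea[i, j])

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return float(self.lat_centers[i]), float(self.lon_centers[j])

    def temperature(self, day_of_year: float) -> np.ndarray:
        """Per-cell water temperature (degC) on the given day of year."""
        phase = 2 * np.pi * (day_of_year - self.temp_peak_doy) / DAYS_PER_YEAR
        return self.temp_mean + self.temp_seasonal_amplitude * np.cos(phase)

    # -- plain-text round trip -----------------------------------------

    _FIELDS = ("bathymetry", "tide_amplitude", "tide_phase",
               "temp_mean", "temp_seasonal_amplitude")

    def to_dir(self, path: str | Path) -> None:
        """Write the grid as a stack of plain CSV files plus a JSON header."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "lon_centers.csv", self.lon_centers, delimiter=",")
        np.savetxt(path / "lat_centers.csv", self.lat_centers, delimiter=",")
        for name in self._FIELDS:
            np.savetxt(path / f"{name}.csv", getattr(self, name), delimiter=",")
        (path / "grid.json").write_text(
            json.dumps({"temp_peak_doy": self.temp_peak_doy}))

    @classmethod
    def from_dir(cls, path: str | Path) -> "EnvironmentGrid":
        path = Path(path)
        meta = json.loads((path / "grid.json").read_text())
        kwargs = {name: np.loadtxt(path / f"{name}.csv", delimiter=",", ndmin=2)
                  for name in cls._FIELDS}
        return cls(
            lon_centers=np.loadtxt(path / "lon_centers.csv", delimiter=",", ndmin=1),
            lat_centers=np.loadtxt(path / "lat_centers.csv", delimiter=",", ndmin=1),
            temp_peak_doy=float(meta["temp_peak_doy"]),
            **kwargs,
        )
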