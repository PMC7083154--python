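"""Geographic utilities: inter-island distances, terrain ruggedness, scaling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import Island

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise island distances (D_ij).

    When built with ``rescale=True`` entries are divided by the maximum
    pairwise distance, so the matrix is dimensionless with max 1; this keeps
    the HalfCauchy(0, 1) hyperprior on the spatial decay rate weakly
    informative regardless of archipelago extent.
    """

    islands: list[str]
    d: np.ndarray
    rescaled: bool = False

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.islands)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def compute_distance_matrix(islands: list[Island],
                            rescale: bool = True) -> DistanceMatrix:
    """Haversine distance matrix between island coordinates.

    With ``rescale`` (default) distances are divided by the maximum pairwise
    distance so the largest entry is exactly 1.
    """
    codes = [i.code for i in islands]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate island codes in distance matrix input")
    lat = np.array([i.lat for i in islands])
    lon = np.array([i.lon for i in islands])
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = np.asarray(d, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against fp noise
    if rescale:
        dmax = d.max()
        if dmax > 0:
            d = d / dmax
    return DistanceMatrix(islands=codes, d=d, rescaled=rescale)


def standardize(values) -> np.ndarray:
    """Z-score with sample (n-1) standard deviation; mean 0, sd 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize: zero spread in values "
                         f"{x.tolist()}")
    return (x - x.mean()) / sd


def covariate_vector(islands: list[Island], name: str,
                     log_area: bool = False) -> np.ndarray:
    """Standardized covariate across islands; area optionally log-transformed
    first (island areas are strongly right-skewed)."""
    raw = np.array([isl.covariate(name) for isl in islands], dtype=float)
    if name == "area" and log_area:
        raw = np.log(raw)
    try:
        return standardize(raw)
    except ValueError as exc:
        raise ValueError(f"covariate {name!r}: {exc}") from exc


@dataclass
class ElevationGrid:
    """Rectangular elevation raster (metres) with square cells."""

    values: np.ndarray
    cell_size: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("elevation grid contains non-finite values")


def load_elevation_grid(path) -> ElevationGrid:
    """Read a plain-text elevation matrix whose first line is 'cellsize <m>'."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[0].lower() != "cellsize":
            raise ValueError("first line must be 'cellsize <metres>'")
        cell = float(header[1])
        values = np.loadtxt(fh)
    return ElevationGrid(values=np.atleast_2d(values), cell_size=cell)


def compute_tri(grid: ElevationGrid) -> float:
    """Mean Terrain Ruggedness Index over interior cells.

    Per-cell TRI is the square root of the summed squared elevation
    differences between the cell and its 8 neighbours; the island-level value
    is the mean over all interior cells.  Invariant to adding a constant
    elevation everywhere, and scales linearly with elevation scaling.
    """
    z = grid.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("TRI needs a grid of at least 3x3 cells")
    centre = z[1:-1, 1:-1]
    sq = np.zeros_like(centre)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = z[1 + di:z.shape[0] - 1 + di, 1 + dj:z.shape[1] - 1 + dj]
            sq += (nb - centre) ** 2
    return float(np.sqrt(sq).mean())
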