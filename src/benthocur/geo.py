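"""Great-circle geometry, threshold clustering, neighbour queries and grid joins.

All distances are great-circle (haversine) distances on a sphere of radius
``EARTH_RADIUS_M`` = 6 371 000 m.  At the site scales this toolkit works with
(metres to a few kilometres) the difference between the sphere and the WGS 84
ellipsoid is negligible relative to GPS positioning error.

Coordinates are decimal degrees, latitude in [-90, 90], longitude in
[-180, 180] (WGS 84).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import BallTree

EARTH_RADIUS_M = 6_371_000.0

#: metres subtended by one degree of arc on the sphere (pi * R / 180)
METRES_PER_DEGREE = np.pi * EARTH_RADIUS_M / 180.0

#: pseudo-sites are clusters separated by at least this distance
PSEUDOSITE_THRESHOLD_M = 1000.0
#: subsites are finer clusters separated by at least this distance
SUBSITE_THRESHOLD_M = 100.0


def _check_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or broadcastable arrays; returns metres.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def pairwise_haversine_m(lat, lon) -> np.ndarray:
    """Full n x n great-circle distance matrix in metres."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return haversine_m(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def mean_centre(lat, lon) -> tuple[float, float]:
    """Geographic mean centre: arithmetic mean of latitudes and longitudes.

    Raises on empty input.  Not antimeridian-safe: sites whose longitudes
    span more than 180 degrees are flagged with a ValueError rather than
    silently averaged across the wrap.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("mean_centre of empty point set")
    _check_latlon(lat, lon)
    if lon.max() - lon.min() > 180.0:
        raise ValueError("site spans the antimeridian; mean centre undefined")
    return float(lat.mean()), float(lon.mean())


class NeighbourIndex:
    """Ball-tree index over geographic points for radius queries.

    Results agree exactly with a brute-force haversine scan over the same
    points (asserted in the test suite).
    """

    def __init__(self, lat, lon):
        self.lat = np.asarray(lat, dtype=float)
        self.lon = np.asarray(lon, dtype=float)
        _check_latlon(self.lat, self.lon)
        self.n = self.lat.size
        if self.n:
            pts = np.column_stack([np.radians(self.lat), np.radians(self.lon)])
            self._tree = BallTree(pts, metric="haversine")
        else:
            self._tree = None

    def query_radius(self, qlat: float, qlon: float, r_m: float) -> np.ndarray:
        """Indices of points with distance <= r_m, ascending by distance."""
        if self._tree is None:
            return np.array([], dtype=int)
        q = np.radians([[qlat, qlon]])
        # small epsilon so boundary points at exactly r_m are included
        rad = r_m / EARTH_RADIUS_M + 1e-15
        ind, dist = self._tree.query_radius(q, r=rad, return_distance=True,
                                            sort_results=True)
        idx, d = ind[0], dist[0] * EARTH_RADIUS_M
        return idx[d <= r_m + 1e-9]


def threshold_clusters(lat, lon, threshold_m: float) -> np.ndarray:
    """Single-linkage clusters: connected components of the < threshold graph.

    Two points are linked when their great-circle distance is strictly below
    ``threshold_m``; clusters are the connected components, so distinct
    clusters are pairwise at least ``threshold_m`` apart at their closest
    pair.  Returns an integer cluster id per point.  Ids are assigned by
    first appearance so they are invariant to point order up to relabelling.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size == 0:
        raise ValueError("threshold_clusters of empty point set")
    if threshold_m <= 0:
        raise ValueError("threshold must be positive")
    _check_latlon(lat, lon)
    n = lat.size
    if n == 1:
        return np.zeros(1, dtype=int)
    pts = np.column_stack([np.radians(lat), np.radians(lon)])
    tree = BallTree(pts, metric="haversine")
    rad = threshold_m / EARTH_RADIUS_M
    ind, dist = tree.query_radius(pts, r=rad, return_distance=True)
    rows, cols = [], []
    for i, (idx, d) in enumerate(zip(ind, dist)):
        keep = idx[d * EARTH_RADIUS_M < threshold_m]
        rows.extend([i] * len(keep))
        cols.extend(keep)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    # canonicalize: relabel by order of first appearance
    order = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def count_pseudosites(lat, lon) -> int:
    """Number of clusters separated by >= 1000 m (automatic site splitting)."""
    return int(threshold_clusters(lat, lon, PSEUDOSITE_THRESHOLD_M).max()) + 1


def count_subsites(lat, lon) -> int:
    """Number of clusters separated by >= 100 m within one site."""
    return int(threshold_clusters(lat, lon, SUBSITE_THRESHOLD_M).max()) + 1


@dataclass
class GeoGrid:
    """Regular latitude/longitude raster of stratum ids or depths.

    Cells are addressed by their centre coordinates: cell (i, j) has centre
    ``(origin_lat + i * cell_size, origin_lon + j * cell_size)`` with i
    increasing northwards.  ``values`` is row-major (nrows, ncols);
    ``mask`` is True where the cell is missing/nodata.
    """

    origin_lat: float
    origin_lon: float
    cell_size: float
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        lats = self.origin_lat + np.arange(self.nrows) * self.cell_size
        lons = self.origin_lon + np.arange(self.ncols) * self.cell_size
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        return glat, glon

    # -- simple text serialization (origin/cell size/nodata header + values) --

    @classmethod
    def read_ascii(cls, path) -> "GeoGrid":
        """Read a plain-text regular raster.

        Header lines ``ncols``, ``nrows``, ``xllcenter``, ``yllcenter``,
        ``cellsize``, ``nodata_value`` followed by nrows lines of ncols
        values, north row first (standard ASCII-grid layout).
        """
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            data = np.loadtxt(fh)
        ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
        data = np.asarray(data, dtype=float).reshape(nrows, ncols)
        data = data[::-1]  # file stores the northernmost row first
        nodata = hdr.get("nodata_value", np.nan)
        mask = (data == nodata) | ~np.isfinite(data)
        vals = data.copy()
        vals[mask] = np.nan
        return cls(origin_lat=hdr["yllcenter"], origin_lon=hdr["xllcenter"],
                   cell_size=hdr["cellsize"], values=vals, mask=mask)

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        vals = self.values.copy()
        vals[self.mask] = nodata
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcenter {float(self.origin_lon)!r}\n")
            fh.write(f"yllcenter {float(self.origin_lat)!r}\n")
            fh.write(f"cellsize {float(self.cell_size)!r}\n")
            fh.write(f"nodata_value {float(nodata)!r}\n")
            for row in vals[::-1]:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def nearest_stratum(lat, lon, grid: GeoGrid) -> np.ndarray:
    """Stratum id of the nearest non-missing grid-cell centre per point.

    This is the nearest-neighbour join used to attach each image to an
    environmental stratum (e.g. a bottom-layer Ecological Marine Unit).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    glat, glon = grid.cell_centres()
    valid = ~grid.mask
    if not valid.any():
        raise ValueError("grid has no valid cells")
    vlat = glat[valid]
    vlon = glon[valid]
    vvals = grid.values[valid]
    tree = BallTree(np.column_stack([np.radians(vlat), np.radians(vlon)]),
                    metric="haversine")
    q = np.column_stack([np.radians(lat), np.radians(lon)])
    _, ind = tree.query(q, k=1)
    return vvals[ind[:, 0]]


def bilinear_depth(grid: GeoGrid, lat: float, lon: float) -> float:
    """Bilinear interpolation of the four surrounding cell values.

    Standard bilinear interpolation in lat/lon space (the convention used to
    attach per-image depths from a gridded bathymetry product).  Raises if
    the point is outside the grid of cell centres or any surrounding corner
    is missing.
    """
    fi = (lat - grid.origin_lat) / grid.cell_size
    fj = (lon - grid.origin_lon) / grid.cell_size
    if fi < 0 or fj < 0 or fi > grid.nrows - 1 or fj > grid.ncols - 1:
        raise ValueError("point outside grid extent")
    i0 = min(int(np.floor(fi)), grid.nrows - 2) if grid.nrows > 1 else 0
    j0 = min(int(np.floor(fj)), grid.ncols - 2) if grid.ncols > 1 else 0
    i1 = min(i0 + 1, grid.nrows - 1)
    j1 = min(j0 + 1, grid.ncols - 1)
    ti = fi - i0
    tj = fj - j0
    weights = {(i0, j0): (1 - ti) * (1 - tj), (i0, j1): (1 - ti) * tj,
               (i1, j0): ti * (1 - tj), (i1, j1): ti * tj}
    # a masked corner only matters when it carries weight (points exactly on
    # a node or cell edge never touch the far corners)
    if any(grid.mask[i, j] and w > 0 for (i, j), w in weights.items()):
        raise ValueError("missing corner value for bilinear interpolation")
    return float(sum(grid.values[i, j] * w for (i, j), w in weights.items()
                     if w > 0))
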