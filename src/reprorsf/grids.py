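"""Synthetic covariate landscapes for habitat-selection analyses.

A :class:`Landscape` is a stack of aligned single-band grids on a common
10-m raster: elevation (m), slope (degrees), terrain ruggedness (VRM),
distance to water (m), and four fractional vegetation-cover classes
(annual and perennial grasses/forbs, shrubs, trees; percent 0-100).
Elevation is generated as a spectrally synthesised Gaussian random field;
the derived terrain layers use the standard GIS constructions (Horn
slope/aspect, Sappington vector ruggedness, Euclidean distance allocation).

Grids are row-major, north-up: row 0 is the northern edge, and ``origin``
is the lower-left corner of the raster in projected metres (the ESRI
ASCII-grid convention). All coordinates refer to cell centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Grid",
    "Landscape",
    "generate_elevation",
    "slope_degrees",
    "vrm",
    "distance_to_water",
    "generate_vegetation",
    "generate_landscape",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_points",
    "write_points",
]

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster. ``values`` uses NaN internally for nodata."""

    values: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the raster's outer edge."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, x0 + ncols * self.cell_size, y0, y0 + nrows * self.cell_size)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) < xmax) & (
            np.asarray(y) >= ymin
        ) & (np.asarray(y) < ymax)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each projected point."""
        xmin, _, _, ymax = self.extent
        col = np.floor((np.asarray(x) - xmin) / self.cell_size).astype(int)
        row = np.floor((ymax - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point (NaN outside extent)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        out = np.full(x.shape, np.nan)
        row, col = self.index_of(x[inside], y[inside])
        out[inside] = self.values[row, col]
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def like(self, values: np.ndarray) -> "Grid":
        return Grid(values, self.cell_size, self.origin, self.nodata)


LAYER_NAMES = (
    "elevation",
    "slope",
    "ruggedness",
    "dist_water",
    "annual",
    "perennial",
    "shrub",
    "tree",
)

COVER_LAYERS = ("annual", "perennial", "shrub", "tree")


@dataclass
class Landscape:
    """Aligned stack of covariate grids sharing shape, origin and cell size."""

    layers: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if grids:
            ref = grids[0]
            for g in grids[1:]:
                if g.shape != ref.shape or g.origin != ref.origin or g.cell_size != ref.cell_size:
                    raise ValueError("all landscape layers must be aligned")

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def template(self) -> Grid:
        return next(iter(self.layers.values()))

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.template.extent

    def sample(self, x, y, names: list[str] | None = None) -> dict[str, np.ndarray]:
        names = names if names is not None else self.names
        return {n: self.layers[n].sample(x, y) for n in names}

    def scalers(self, names: list[str] | None = None) -> dict[str, tuple[float, float]]:
        """Per-layer (mean, SD) over all finite cells, for z-standardisation."""
        names = names if names is not None else self.names
        out = {}
        for n in names:
            v = self.layers[n].values
            v = v[np.isfinite(v)]
            out[n] = (float(v.mean()), float(v.std(ddof=0)))
        return out

    def standardized_arrays(self, names: list[str]) -> np.ndarray:
        """(n_layers, nrows, ncols) stack of z-scored layer values."""
        sc = self.scalers(names)
        return np.stack(
            [(self.layers[n].values - sc[n][0]) / sc[n][1] for n in names]
        )


# ---------------------------------------------------------------------------
# generators


def generate_elevation(
    shape: tuple[int, int],
    cell_size: float = 10.0,
    relief_range: tuple[float, float] = (1400.0, 2800.0),
    roughness: float = 0.7,
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Grid:
    """Spatially autocorrelated elevation field rescaled into ``relief_range``.

    The field is synthesised spectrally: white Gaussian noise is filtered in
    the Fourier domain with a radial power-law |k|^-(1+2*roughness), giving a
    fractal-like surface whose smoothness rises with ``roughness``.
    ``roughness=0`` returns a flat field at the midpoint of the range.
    Deterministic for a given seed.
    """
    nrows, ncols = shape
    if nrows < 16 or ncols < 16:
        raise ValueError("elevation grid must be at least 16x16")
    lo, hi = relief_range
    if not lo < hi:
        raise ValueError("relief_range must satisfy min < max")
    if roughness < 0:
        raise ValueError("roughness must be non-negative")
    if roughness == 0:
        vals = np.full(shape, 0.5 * (lo + hi))
        return Grid(vals, cell_size, origin)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    ky = np.fft.fftfreq(nrows)[:, None]
    kx = np.fft.fftfreq(ncols)[None, :]
    k = np.hypot(ky, kx)
    k[0, 0] = np.inf  # kill the DC mode; mean is set by rescaling
    filt = k ** -(1.0 + 2.0 * roughness)
    fld = np.fft.ifft2(np.fft.fft2(noise) * filt).real
    fld = (fld - fld.min()) / (fld.max() - fld.min())
    return Grid(lo + fld * (hi - lo), cell_size, origin)


def _horn_gradients(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 finite-difference gradients (dz/dx east, dz/dy north).

    Edge cells use linear extrapolation of the border (odd reflection),
    the shrunken-window equivalent of a one-sided difference: planar
    surfaces keep their exact gradient all the way to the edge.
    """
    z = np.pad(grid.values, 1, mode="reflect", reflect_type="odd")
    c = grid.cell_size
    # neighbours relative to each cell (rows increase southwards)
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * c)
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * c)
    return dzdx, dzdy


def slope_degrees(elevation: Grid) -> Grid:
    """Slope in degrees from the Horn 3x3 kernel; nodata (NaN) propagates."""
    if min(elevation.shape) < 3:
        raise ValueError("slope needs at least a 3x3 grid")
    dzdx, dzdy = _horn_gradients(elevation)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[np.isnan(elevation.values)] = np.nan  # kernel skips the centre cell
    return elevation.like(slope)


def vrm(elevation: Grid, window: int = 3) -> Grid:
    """Sappington vector ruggedness measure on a moving window.

    Unit surface-normal vectors are decomposed from Horn slope/aspect; the
    per-cell VRM is 1 - |sum of normals| / n over the window. Planar
    surfaces (any uniform incline) score exactly 0; values approach 1 as
    normals disperse. Window edges reuse the nearest border cells.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(elevation.shape):
        raise ValueError("window larger than the grid")
    dzdx, dzdy = _horn_gradients(elevation)
    slope = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(dzdy, -dzdx)
    xy = np.sin(slope)
    nx = xy * np.cos(aspect)
    ny = xy * np.sin(aspect)
    nz = np.cos(slope)
    sums = [
        ndimage.uniform_filter(comp, size=window, mode="nearest") * window**2
        for comp in (nx, ny, nz)
    ]
    resultant = np.sqrt(sums[0] ** 2 + sums[1] ** 2 + sums[2] ** 2)
    out = 1.0 - resultant / float(window**2)
    return elevation.like(np.clip(out, 0.0, 1.0))


def distance_to_water(
    water_points: np.ndarray | list[tuple[float, float]], template: Grid
) -> Grid:
    """Euclidean distance (m) from each cell centre to the nearest water point."""
    pts = np.atleast_2d(np.asarray(water_points, dtype=float))
    if pts.size == 0:
        raise ValueError("at least one water point is required")
    if pts.shape[1] != 2:
        raise ValueError("water points must be (x, y) pairs")
    if not template.contains(pts[:, 0], pts[:, 1]).any():
        raise ValueError("no water point falls inside the grid extent")
    xs, ys = template.cell_centers()
    tree = cKDTree(pts)
    d, _ = tree.query(np.column_stack([xs.ravel(), ys.ravel()]))
    return template.like(d.reshape(template.shape))


def generate_vegetation(
    landscape: Landscape,
    target_correlations: dict[str, dict[str, float]],
    seed: int | None = None,
    mean: float = 40.0,
    sd: float = 15.0,
    smooth_sigma: float = 3.0,
) -> dict[str, Grid]:
    """Percent-cover grids with prescribed correlations to terrain layers.

    Each cover field is a linear blend of the (z-scored) terrain drivers named
    in ``target_correlations[cover]`` plus smoothed independent noise, scaled
    so the realised Pearson correlation with each driver matches its signed
    target (up to Monte-Carlo error and mild attenuation from clipping to
    [0, 100]).
    """
    rng = np.random.default_rng(seed)
    template = landscape.template
    out: dict[str, Grid] = {}
    for cover in COVER_LAYERS:
        targets = target_correlations.get(cover, {})
        total_r2 = 0.0
        fld = np.zeros(template.shape)
        for driver, r in targets.items():
            if abs(r) >= 1:
                raise ValueError(f"|target correlation| must be < 1 (got {r})")
            if driver not in landscape:
                raise ValueError(f"unknown terrain driver {driver!r}")
            v = landscape[driver].values
            z = (v - np.nanmean(v)) / np.nanstd(v)
            fld = fld + r * z
            total_r2 += r * r
        if total_r2 >= 1:
            raise ValueError("sum of squared target correlations must be < 1")
        noise = ndimage.gaussian_filter(rng.standard_normal(template.shape), smooth_sigma)
        noise = (noise - noise.mean()) / noise.std()
        fld = fld + np.sqrt(1.0 - total_r2) * noise
        out[cover] = template.like(np.clip(mean + sd * fld, 0.0, 100.0))
    return out


#: correlation structure used by default: herbaceous cover thins out on steep
#: and rugged ground, shrubs avoid the most rugged terrain, trees tolerate it.
DEFAULT_VEG_CORRELATIONS: dict[str, dict[str, float]] = {
    "annual": {"slope": -0.55},
    "perennial": {"slope": -0.45},
    "shrub": {"ruggedness": -0.35},
    "tree": {"slope": 0.30},
}


def generate_landscape(
    shape: tuple[int, int] = (128, 128),
    cell_size: float = 10.0,
    relief_range: tuple[float, float] = (1400.0, 2800.0),
    roughness: float = 0.7,
    n_water: int = 4,
    veg_correlations: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
    vrm_window: int = 3,
) -> Landscape:
    """Full default landscape: elevation, slope, VRM, distance-to-water, covers."""
    rng = np.random.default_rng(seed)
    elev = generate_elevation(
        shape, cell_size, relief_range, roughness, seed=int(rng.integers(2**31))
    )
    layers = {"elevation": elev, "slope": slope_degrees(elev)}
    layers["ruggedness"] = vrm(elev, window=vrm_window)
    xmin, xmax, ymin, ymax = elev.extent
    water = np.column_stack(
        [rng.uniform(xmin, xmax, n_water), rng.uniform(ymin, ymax, n_water)]
    )
    layers["dist_water"] = distance_to_water(water, elev)
    partial = Landscape(dict(layers))
    covers = generate_vegetation(
        partial,
        veg_correlations if veg_correlations is not None else DEFAULT_VEG_CORRELATIONS,
        seed=int(rng.integers(2**31)),
    )
    layers.update(covers)
    return Landscape(layers)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text single-band raster interchange)


def write_ascii_grid(grid: Grid, path) -> None:
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata:.6f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def write_points(points, path) -> None:
    """Write (x, y) locations (e.g. water sources) as 2-column text."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    np.savetxt(path, pts, fmt="%.6f", header="x y")


def read_points(path) -> np.ndarray:
    """Read 2-column (x, y) delimited text into an (n, 2) array."""
    pts = np.atleast_2d(np.loadtxt(path))
    if pts.shape[1] != 2:
        raise ValueError("points file must have exactly two columns (x, y)")
    return pts


def read_ascii_grid(path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nodata = header.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return Grid(
        vals,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=nodata,
    )
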