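"""Regular 2-D grids, synthetic velocity fields and subdomain geometry.

The connectivity machinery operates on a planar Cartesian grid: the
exposure-time and connectivity definitions are geometry-agnostic, so a
depth-integrated 2-D stand-in for a full circulation model is sufficient
for method development and testing.  Geographic (lon/lat) coordinates
enter only through an optional equirectangular georeference used when
samples carry positions in degrees.

The scenario velocity fields emulate a shelf-edge system: an eastward
jet along one band of the grid, a westward return flow in another, and
a quiet shallow sector — the flow configuration that creates a
dispersal barrier between the bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid2D",
    "VelocityField",
    "Subdomain",
    "LonLatGeoref",
    "make_grid",
    "barrier_jet_field",
    "sector_subdomains",
    "DEFAULT_SECTOR_NAMES",
]

#: Sector names, ordered north (deep trench) to south (shallow area).
DEFAULT_SECTOR_NAMES = ("NT", "SL", "SE", "SH")

#: Metres per degree of latitude for the equirectangular georeference.
M_PER_DEG_LAT = 111_195.0


@dataclass(frozen=True)
class Grid2D:
    """Uniform rectangular grid.

    Cell centres are at ``x0 + (i + 0.5) dx``; array layout is ``(ny, nx)``
    with row 0 the southernmost (smallest y).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid needs nx, ny >= 2, got {self.nx}x{self.ny}")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"cell sizes must be positive, got dx={self.dx}, dy={self.dy}")

    @property
    def cell_area(self) -> float:
        """Area of one cell in m²."""
        return self.dx * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def total_area(self) -> float:
        return self.nx * self.ny * self.cell_area

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.dy


@dataclass(frozen=True)
class VelocityField:
    """Per-cell velocity components (m s⁻¹) on a :class:`Grid2D`.

    ``u`` and ``v`` are ``(ny, nx)`` arrays; a steady field is assumed
    unless a caller swaps fields between steps.  ``time_step_valid`` is
    the duration (s) for which a snapshot applies (informational for
    steady fields).
    """

    u: np.ndarray
    v: np.ndarray
    time_step_valid: float = np.inf

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape:
            raise ValueError(f"u and v shapes differ: {u.shape} vs {v.shape}")
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise ValueError("velocity components must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max()))


@dataclass(frozen=True)
class Subdomain:
    """A named set of grid cells (Ω) with its area A (m²)."""

    id: int
    label: str
    mask: np.ndarray
    area: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"subdomain {self.label!r} has an empty mask")
        object.__setattr__(self, "mask", mask)

    def centroid(self, grid: Grid2D) -> tuple[float, float]:
        """Area-weighted centroid (x, y) in grid coordinates (m)."""
        jj, ii = np.nonzero(self.mask)
        return (
            float(np.mean(grid.x_centers()[ii])),
            float(np.mean(grid.y_centers()[jj])),
        )


@dataclass(frozen=True)
class LonLatGeoref:
    """Equirectangular mapping between planar metres and degrees.

    ``lon0``/``lat0`` correspond to the grid origin; x grows eastward and
    y northward.  Adequate for the O(100 km) study boxes this package
    targets; not a projection library.
    """

    lon0: float
    lat0: float

    def to_xy(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        y = (lat - self.lat0) * M_PER_DEG_LAT
        x = (lon - self.lon0) * M_PER_DEG_LAT * np.cos(np.deg2rad(self.lat0))
        return x, y

    def to_lonlat(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.lat0 + y / M_PER_DEG_LAT
        lon = self.lon0 + x / (M_PER_DEG_LAT * np.cos(np.deg2rad(self.lat0)))
        return lon, lat


def make_grid(
    nx: int,
    ny: int,
    dx: float,
    dy: float,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Grid2D:
    """Build a uniform planar grid with cell areas ``dx * dy``."""
    return Grid2D(nx=int(nx), ny=int(ny), dx=float(dx), dy=float(dy), origin=origin)


def barrier_jet_field(
    grid: Grid2D,
    jet_center_y: float,
    jet_width: float,
    u_jet: float,
    u_return: float,
    return_center_y: float | None = None,
    return_width: float | None = None,
) -> VelocityField:
    """Zonal jet + return-flow field with a cross-stream dispersal barrier.

    The zonal velocity is the sum of two Gaussian bands,

        u(y) = u_jet exp(-((y - y_jet)/w)²) + u_return exp(-((y - y_ret)/w_ret)²)

    with v = 0 everywhere.  Because u depends on y only, the discrete
    divergence vanishes identically, so the field is mass-conserving for
    any conservative transport scheme.

    Parameters
    ----------
    jet_center_y, jet_width:
        Centre (m, grid frame) and e-folding half-width (m) of the jet.
    u_jet, u_return:
        Peak speeds (m s⁻¹); a westward return flow has ``u_return < 0``.
    return_center_y, return_width:
        Return band geometry; defaults mirror the jet band on the
        opposite side of the jet centre, two jet widths away.
    """
    if jet_width <= 0:
        raise ValueError(f"jet_width must be positive, got {jet_width}")
    y = grid.y_centers()
    if not (y[0] - grid.dy / 2 <= jet_center_y <= y[-1] + grid.dy / 2):
        raise ValueError(
            f"jet_center_y={jet_center_y} lies outside the grid y-range "
            f"[{y[0] - grid.dy / 2}, {y[-1] + grid.dy / 2}]"
        )
    if return_center_y is None:
        return_center_y = jet_center_y + 2.0 * jet_width
    if return_width is None:
        return_width = jet_width

    u_profile = u_jet * np.exp(-(((y - jet_center_y) / jet_width) ** 2))
    u_profile = u_profile + u_return * np.exp(
        -(((y - return_center_y) / return_width) ** 2)
    )
    u = np.broadcast_to(u_profile[:, None], grid.shape).copy()
    v = np.zeros(grid.shape)
    return VelocityField(u=u, v=v)


def sector_subdomains(
    grid: Grid2D,
    n_sectors: int = 4,
    n_along: int = 5,
    sector_names: tuple[str, ...] | None = None,
) -> list[Subdomain]:
    """Tile the grid into ``n_sectors`` cross-stream bands × ``n_along`` tiles.

    Sectors are horizontal (east–west) bands ordered north to south; the
    default names are NT (trench), SL (slope), SE (shelf edge), SH
    (shallow).  Within a sector, tiles are numbered 1..n_along from west
    to east, giving labels NT1..NT5, SL1..SL5, SE1..SE5, SH1..SH5 for the
    default 4×5 layout.
    """
    if sector_names is None:
        if n_sectors == len(DEFAULT_SECTOR_NAMES):
            sector_names = DEFAULT_SECTOR_NAMES
        else:
            sector_names = tuple(f"S{k + 1}" for k in range(n_sectors))
    if len(sector_names) != n_sectors:
        raise ValueError("sector_names length must equal n_sectors")
    if grid.ny % n_sectors != 0 or grid.nx % n_along != 0:
        raise ValueError(
            f"a {n_sectors}x{n_along} tiling does not divide the "
            f"{grid.ny}x{grid.nx} grid evenly"
        )
    band_h = grid.ny // n_sectors
    tile_w = grid.nx // n_along

    subdomains: list[Subdomain] = []
    dom_id = 0
    for s, name in enumerate(sector_names):
        # sector 0 is the northernmost band = top rows of the array
        j_hi = grid.ny - s * band_h
        j_lo = j_hi - band_h
        for a in range(n_along):
            mask = np.zeros(grid.shape, dtype=bool)
            mask[j_lo:j_hi, a * tile_w : (a + 1) * tile_w] = True
            subdomains.append(
                Subdomain(
                    id=dom_id,
                    label=f"{name}{a + 1}",
                    mask=mask,
                    area=float(mask.sum()) * grid.cell_area,
                )
            )
            dom_id += 1
    return subdomains


def discrete_divergence(grid: Grid2D, field: VelocityField) -> np.ndarray:
    """Centred discrete divergence ∂u/∂x + ∂v/∂y (s⁻¹) on cell centres."""
    du = np.gradient(field.u, grid.dx, axis=1)
    dv = np.gradient(field.v, grid.dy, axis=0)
    return du + dv
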