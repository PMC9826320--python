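"""Landscape heterogeneity and urban index around study sites.

Works on single-band categorical land-cover grids (ESRI ASCII grid format,
plain text) with either a planar or a geographic (lon/lat degree)
georeference. For each site and buffer radius, pixels whose centres fall
within the circle are counted per land-cover category; from the counts the
urban index (share of pixels in urban categories) and the landscape
heterogeneity (effective number of land covers, the exponential of the
Shannon-Wiener index, i.e. the Hill number of order q = 1) are derived.
Default radii follow the multi-scale design of 250 m to 5000 m in 250 m
steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

DEFAULT_RADII_M = tuple(range(250, 5001, 250))


@dataclass
class CategoricalGrid:
    """A single-band categorical raster with a simple georeference.

    ``data`` is row-major with row 0 at the *top* (north). ``xll``/``yll``
    locate the lower-left corner; ``cellsize`` is in the coordinate units
    (metres for ``crs='planar'``, degrees for ``crs='geographic'``).
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: int = -9999
    crs: str = "planar"  # "planar" | "geographic"

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return xs, ys

    def contains(self, x: float, y: float) -> bool:
        return (
            self.xll <= x <= self.xll + self.ncols * self.cellsize
            and self.yll <= y <= self.yll + self.nrows * self.cellsize
        )


def read_ascii_grid(path, crs: str = "planar") -> CategoricalGrid:
    """Read an ESRI ASCII grid (.asc): 5-6 header lines then the matrix."""
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req!r}")
    data = np.array(rows, dtype=int)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return CategoricalGrid(
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=int(header.get("nodata_value", -9999)),
        crs=crs,
    )


def write_ascii_grid(grid: CategoricalGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
            f"xllcorner {grid.xll:.10g}\nyllcorner {grid.yll:.10g}\n"
            f"cellsize {grid.cellsize:.10g}\nNODATA_value {grid.nodata}\n"
        )
        for row in grid.data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


@dataclass
class LandscapeProfile:
    """Category counts within one buffer, with derived landscape statistics."""

    site_id: str
    radius: float
    counts: dict[int, int]
    urban_index: float
    effective_n_landcovers: float


@dataclass
class PairModerators:
    """Urban-minus-nonurban differences in landscape moderators for one pair."""

    population_pair_id: str
    radius: float
    d_urban_index: float
    d_heterogeneity: float
    pair_distance_km: float


def pair_distance(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if abs(lon) > 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def _distances_to_point(grid: CategoricalGrid, x: float, y: float) -> np.ndarray:
    """Per-pixel-centre distance to (x, y), in metres."""
    xs, ys = grid.pixel_centres()
    if grid.crs == "planar":
        dx = xs[None, :] - x
        dy = ys[:, None] - y
        return np.sqrt(dx**2 + dy**2)
    # geographic: exact great-circle distance per pixel centre
    lat_r = np.radians(ys)[:, None]
    lat0 = math.radians(y)
    dphi = lat_r - lat0
    dlmb = np.radians(xs[None, :] - x)
    a = np.sin(dphi / 2) ** 2 + np.cos(lat_r) * math.cos(lat0) * np.sin(dlmb / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * 1000.0 * np.arcsin(np.sqrt(a))


def buffer_extract(
    grid: CategoricalGrid, x: float, y: float, radius_m: float
) -> dict[int, int]:
    """Count pixels (by category) whose centres lie within ``radius_m`` of a site.

    For planar grids coordinates and cellsize are metres; for geographic
    grids the site is (lon, lat) in degrees and per-pixel great-circle
    distances decide inclusion. Nodata pixels are ignored.
    """
    if not grid.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside raster extent")
    half_pixel = grid.cellsize / 2.0
    if grid.crs == "geographic":
        half_pixel *= math.pi / 180.0 * EARTH_RADIUS_KM * 1000.0
    if radius_m < half_pixel:
        raise ValueError(
            f"radius {radius_m} m is below half a pixel ({half_pixel:.1f} m)"
        )
    dist = _distances_to_point(grid, x, y)
    inside = dist <= radius_m
    values = grid.data[inside]
    values = values[values != grid.nodata]
    if values.size == 0:
        raise ValueError("buffer contains no valid pixels")
    cats, counts = np.unique(values, return_counts=True)
    return {int(c): int(n) for c, n in zip(cats, counts)}


def effective_landcovers(counts: Mapping[int, int] | Sequence[int]) -> float:
    """Effective number of land covers: exp of the Shannon-Wiener index.

    With p_k the share of pixels in category k (zero-count categories
    ignored), returns exp(-sum p_k ln p_k) — the Hill number of order 1,
    between 1 (single category) and the category richness (uniform mix).
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    vals = vals[vals > 0]
    total = vals.sum()
    if total <= 0:
        raise ValueError("all counts are zero")
    p = vals / total
    return float(np.exp(-np.sum(p * np.log(p))))


def urban_index(
    counts: Mapping[int, int], urban_category_ids: Iterable[int]
) -> float:
    """Share of buffer pixels classified as urban land cover, in [0, 1]."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all counts are zero")
    urban_ids = set(urban_category_ids)
    if not urban_ids:
        raise ValueError("urban category set is empty")
    return sum(n for c, n in counts.items() if c in urban_ids) / total


@dataclass
class SiteErrors:
    errors: list[tuple[str, float, str]] = field(default_factory=list)


def multiscale_profile(
    grid: CategoricalGrid,
    sites: Mapping[str, tuple[float, float]],
    urban_category_ids: Iterable[int],
    radii_m: Sequence[float] = DEFAULT_RADII_M,
    errors: SiteErrors | None = None,
) -> list[LandscapeProfile]:
    """Landscape profiles for each site across the buffer radii.

    Per-site failures (outside extent, empty buffer) are collected in
    ``errors`` rather than aborting the whole extraction.
    """
    urban_ids = list(urban_category_ids)
    profiles = []
    for site_id, (x, y) in sites.items():
        for radius in radii_m:
            try:
                counts = buffer_extract(grid, x, y, radius)
            except ValueError as exc:
                if errors is not None:
                    errors.errors.append((site_id, radius, str(exc)))
                continue
            profiles.append(
                LandscapeProfile(
                    site_id=site_id,
                    radius=radius,
                    counts=counts,
                    urban_index=urban_index(counts, urban_ids),
                    effective_n_landcovers=effective_landcovers(counts),
                )
            )
    return profiles


def profiles_to_frame(profiles: Sequence[LandscapeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": p.site_id,
                "radius": p.radius,
                "urban_index": p.urban_index,
                "effective_n_landcovers": p.effective_n_landcovers,
                "total_pixels": sum(p.counts.values()),
            }
            for p in profiles
        ]
    )


def pair_moderators(
    profiles: Sequence[LandscapeProfile],
    pairs: Mapping[str, tuple[str, str]],
    coordinates: Mapping[str, tuple[float, float]] | None = None,
) -> list[PairModerators]:
    """Build per-pair landscape moderators at every radius both sites cover.

    ``pairs`` maps population_pair_id -> (urban_site_id, nonurban_site_id);
    ``coordinates`` (lon, lat per site) enables the pair distance, which is
    set to nan when unavailable.
    """
    by_site: dict[tuple[str, float], LandscapeProfile] = {
        (p.site_id, p.radius): p for p in profiles
    }
    out = []
    radii = sorted({p.radius for p in profiles})
    for pair_id, (urb, non) in pairs.items():
        if coordinates and urb in coordinates and non in coordinates:
            d_km = pair_distance(*coordinates[urb], *coordinates[non])
        else:
            d_km = math.nan
        for radius in radii:
            pu = by_site.get((urb, radius))
            pn = by_site.get((non, radius))
            if pu is None or pn is None:
                continue
            out.append(
                PairModerators(
                    population_pair_id=pair_id,
                    radius=radius,
                    d_urban_index=pu.urban_index - pn.urban_index,
                    d_heterogeneity=pu.effective_n_landcovers - pn.effective_n_landcovers,
                    pair_distance_km=d_km,
                )
            )
    return out


def urban_index_difference_test(
    differences: Sequence[float], level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Intercept-only linear model of paired urban-index differences.

    Equivalent to a one-sample mean: returns (mean difference, SE, CI) with
    SE = sd / sqrt(n).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / math.sqrt(d.size))
    from urbanvar.meta_engine import wald_ci

    return mean, se, wald_ci(mean, se, level)
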