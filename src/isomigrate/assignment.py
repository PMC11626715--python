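"""Continuous-surface isotope-based natal-origin assignment.

For one specimen the chain is: per-pixel normal likelihood of the
measured value against each isoscape (SD = quadrature of the isoscape's
per-pixel SD and the specimen's total measurement SD), cellwise product
across isotope systems (climate-driven d2H and geology-driven
87Sr/86Sr are treated as independent), normalization into a posterior
origin surface, reduction to a binary "highly probable" region at 2:1
odds (the smallest set of highest-probability cells holding >= 2/3 of
the posterior mass), and derived movement metrics: minimum migration
distance, origin-region centroid, travel-bearing distribution and the
putative-local screen (< 100 km).

Nodata cells (e.g. ocean) carry zero prior; the posterior is defined
over land cells only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from isomigrate import geo
from isomigrate.grid import GeoGrid, Isoscape

log = logging.getLogger(__name__)


class DegeneratePosteriorError(ValueError):
    """Every cell's joint density underflowed to zero."""


@dataclass(frozen=True)
class AssignmentOptions:
    """Tunable knobs of the assignment chain.

    odds: the odds-ratio defining the highly probable region (2 -> 2:1,
        i.e. the region holds >= 2/3 of posterior mass).
    odds_mode: "mass" selects cells by cumulative posterior mass (the
        odds reading of the isopleth); "cell_rank" takes the top third
        of cells by rank instead.
    local_threshold_km: minimum-distance cutoff of the putative-local
        screen (strictly less-than).
    distance_weighted: weight the bearing density by origin-capture
        distance.
    """

    odds: float = 2.0
    odds_mode: str = "mass"
    local_threshold_km: float = 100.0
    distance_weighted: bool = True
    bin_width_deg: float = 1.0


@dataclass
class PosteriorSurface:
    """Normalized per-pixel origin probability for one specimen."""

    probs: GeoGrid
    specimen_id: str = ""

    def __post_init__(self) -> None:
        p = self.probs.values[self.probs.mask]
        if p.size == 0:
            raise ValueError("posterior has no valid cells")
        if np.any(p < 0):
            raise ValueError("posterior probabilities must be >= 0")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"posterior mass {total} != 1")


@dataclass
class BinarySurface:
    """The 2:1-odds highly probable origin region as a 0/1 grid."""

    mask_grid: GeoGrid
    odds: float
    contained_mass: float

    @property
    def cells(self) -> np.ndarray:
        return self.mask_grid.values == 1.0

    @property
    def n_cells(self) -> int:
        return int(np.nansum(self.mask_grid.values))

    def area_km2(self) -> float:
        """Total area of the region (spherical cell areas on geographic
        grids, cell^2 on cartesian grids)."""
        spec = self.mask_grid.spec
        sel = self.cells
        if spec.crs == "geographic":
            lat = spec.y_centers()
            dlam = np.radians(spec.cell)
            # area of a lon-lat quadrangle row: R^2 * dlon * (sin(top)-sin(bot))
            top = np.radians(lat + spec.cell / 2)
            bot = np.radians(lat - spec.cell / 2)
            row_area = geo.EARTH_RADIUS_KM**2 * dlam * (np.sin(top) - np.sin(bot))
            return float(np.sum(row_area[:, None] * sel))
        return float(sel.sum() * spec.cell**2)


@dataclass
class AssignmentResult:
    specimen_id: str
    posterior: PosteriorSurface
    binary: BinarySurface
    min_distance_km: float
    centroid_lon: float
    centroid_lat: float
    direction_pdf: np.ndarray
    circular_mean_deg: float
    resultant_length: float
    putative_local: bool = dc_field(default=False)


def likelihood_surface(value: float, total_sd: float,
                       isoscape: Isoscape) -> GeoGrid:
    """Per-pixel normal density of a measured value given the isoscape.

    The effective SD at each pixel is
    sqrt(isoscape_sd^2 + total_sd^2), so both map uncertainty and the
    specimen's measurement/transfer uncertainty widen the likelihood.
    """
    if total_sd <= 0:
        raise ValueError("total_sd must be positive")
    mean = isoscape.mean.values
    sd = np.sqrt(isoscape.sd.values**2 + total_sd**2)
    with np.errstate(invalid="ignore"):
        dens = np.exp(-0.5 * ((value - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    dens = np.where(isoscape.mean.mask & isoscape.sd.mask, dens, np.nan)
    return GeoGrid(dens, isoscape.spec)


def joint_posterior(surfaces: Sequence[GeoGrid],
                    specimen_id: str = "") -> PosteriorSurface:
    """Cellwise product of density surfaces, normalized to sum to one."""
    if len(surfaces) == 0:
        raise ValueError("need at least one density surface")
    spec = surfaces[0].spec
    prod = np.ones((spec.nrows, spec.ncols))
    valid = np.ones((spec.nrows, spec.ncols), dtype=bool)
    for s in surfaces:
        if s.spec != spec:
            raise ValueError("density surfaces must share grid geometry")
        valid &= s.mask
        prod = prod * np.where(s.mask, s.values, 1.0)
    prod = np.where(valid, prod, np.nan)
    total = np.nansum(prod)
    if not np.isfinite(total) or total <= 0:
        raise DegeneratePosteriorError("joint density is zero everywhere")
    return PosteriorSurface(GeoGrid(prod / total, spec), specimen_id)


def odds_ratio_binary(posterior: PosteriorSurface,
                      odds: float = 2.0, mode: str = "mass") -> BinarySurface:
    """Binarize a posterior into its highly probable region.

    mode="mass" (default): add cells in descending probability until the
    cumulative mass first reaches odds/(odds+1); cells tied with the
    last-added probability are all included.  mode="cell_rank": take the
    top 1/(odds+1) fraction of valid cells by rank (the "top third of
    pixels" reading for 2:1 odds).
    """
    if odds <= 0:
        raise ValueError("odds must be positive")
    grid = posterior.probs
    p = grid.values
    valid = grid.mask
    flat = p[valid]
    order = np.argsort(flat)[::-1]
    sorted_p = flat[order]

    if mode == "mass":
        target = odds / (odds + 1.0)
        csum = np.cumsum(sorted_p)
        k = int(np.searchsorted(csum, target - 1e-12)) + 1
        k = min(k, sorted_p.size)
        # include all cells tied with the last admitted probability
        thresh = sorted_p[k - 1]
        sel_flat = flat >= thresh
    elif mode == "cell_rank":
        n_keep = max(1, int(np.ceil(flat.size / (odds + 1.0))))
        thresh = sorted_p[n_keep - 1]
        sel_flat = flat >= thresh
    else:
        raise ValueError("mode must be 'mass' or 'cell_rank'")

    mask_vals = np.where(valid, 0.0, np.nan)
    rows, cols = np.nonzero(valid)
    mask_vals[rows[sel_flat], cols[sel_flat]] = 1.0
    contained = float(flat[sel_flat].sum())
    return BinarySurface(GeoGrid(mask_vals, grid.spec), odds=odds,
                         contained_mass=contained)


def min_distance(binary: BinarySurface, capture_lon: float,
                 capture_lat: float) -> float:
    """Shortest distance (km) from the capture point to the region.

    Zero when the capture cell itself is in the region; otherwise the
    minimum distance to the centres of region cells.
    """
    spec = binary.mask_grid.spec
    sel = binary.cells
    if not sel.any():
        raise ValueError("binary surface has an empty mask")
    r, c = spec.index_of(capture_lon, capture_lat)
    if sel[r, c]:
        return 0.0
    X, Y = spec.center_mesh()
    d = geo.distance_km(capture_lon, capture_lat, X[sel], Y[sel], spec.crs)
    return float(np.min(d))


def screen_putative_local(min_distance_km: float, capture_in_mask: bool,
                          threshold_km: float = 100.0) -> bool:
    """True when an origin at/near the capture site cannot be excluded."""
    return bool(capture_in_mask or min_distance_km < threshold_km)


def stack_binaries(binaries: Sequence[BinarySurface]) -> GeoGrid:
    """Per-pixel percentage of individuals whose region includes the pixel."""
    if len(binaries) == 0:
        raise ValueError("need at least one binary surface")
    spec = binaries[0].mask_grid.spec
    count = np.zeros((spec.nrows, spec.ncols))
    valid = np.zeros((spec.nrows, spec.ncols), dtype=bool)
    for b in binaries:
        if b.mask_grid.spec != spec:
            raise ValueError("binary surfaces must share grid geometry")
        count += np.where(b.cells, 1.0, 0.0)
        valid |= b.mask_grid.mask
    vals = np.where(valid, 100.0 * count / len(binaries), np.nan)
    return GeoGrid(vals, spec)


def direction_distribution(
    posterior: PosteriorSurface,
    capture_lon: float,
    capture_lat: float,
    bin_width_deg: float = 1.0,
    distance_weighted: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Probability density of the travel bearing (origin -> capture).

    For every candidate origin cell, the initial bearing from the cell
    to the capture point receives that cell's posterior mass, optionally
    multiplied by the origin-capture distance (so distant origins, which
    imply more travel, weigh more).  Returns ``(density, circular_mean,
    resultant_length)``; density bins are half-open ``[b, b + width)``
    degrees clockwise from north and sum to one.

    A cell whose centre coincides with the capture point has no defined
    bearing; its mass is spread uniformly over all bins (logged).
    """
    if not (0 < bin_width_deg <= 360):
        raise ValueError("bin_width_deg must be in (0, 360]")
    grid = posterior.probs
    spec = grid.spec
    valid = grid.mask
    X, Y = spec.center_mesh()
    probs = grid.values[valid]
    xs, ys = X[valid], Y[valid]
    dists = geo.distance_km(xs, ys, capture_lon, capture_lat, spec.crs)
    bearings = geo.bearing_deg(xs, ys, capture_lon, capture_lat, spec.crs)

    weights = probs * dists if distance_weighted else probs.copy()
    at_capture = dists == 0.0
    n_bins = int(round(360.0 / bin_width_deg))
    density = np.zeros(n_bins)
    if at_capture.any():
        stranded = probs[at_capture] if not distance_weighted else np.zeros(0)
        # distance weighting already zeroes the undefined-bearing cell;
        # unweighted mode spreads its mass uniformly
        if stranded.size:
            log.info("capture coincides with %d cell centre(s); mass spread "
                     "uniformly over bearings", int(at_capture.sum()))
            density += stranded.sum() / n_bins
        weights = weights[~at_capture]
        bearings = bearings[~at_capture]
    idx = np.minimum((bearings / bin_width_deg).astype(int), n_bins - 1)
    np.add.at(density, idx, weights)
    total = density.sum()
    if total > 0:
        density = density / total
    centers = (np.arange(n_bins) + 0.5) * bin_width_deg
    rad = np.radians(centers)
    s = float(np.sum(density * np.sin(rad)))
    c = float(np.sum(density * np.cos(rad)))
    resultant = float(np.hypot(s, c))
    circ_mean = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return density, circ_mean, resultant


def binary_centroid(binary: BinarySurface) -> tuple[float, float]:
    """Mean position of region cells.

    Geographic grids use the 3-D unit-vector mean (robust across the
    antimeridian); cartesian grids use the arithmetic mean.
    """
    spec = binary.mask_grid.spec
    sel = binary.cells
    if not sel.any():
        raise ValueError("binary surface has an empty mask")
    X, Y = spec.center_mesh()
    xs, ys = X[sel], Y[sel]
    if spec.crs == "geographic":
        lam = np.radians(xs)
        phi = np.radians(ys)
        vx = np.mean(np.cos(phi) * np.cos(lam))
        vy = np.mean(np.cos(phi) * np.sin(lam))
        vz = np.mean(np.sin(phi))
        lon = float(np.degrees(np.arctan2(vy, vx)))
        lat = float(np.degrees(np.arctan2(vz, np.hypot(vx, vy))))
        return lon, lat
    return float(xs.mean()), float(ys.mean())


def assign_specimen(
    specimen: pd.Series | dict,
    h_isoscape: Isoscape | None,
    sr_isoscape: Isoscape | None = None,
    options: AssignmentOptions = AssignmentOptions(),
) -> AssignmentResult:
    """Run the full assignment chain for one specimen.

    ``specimen`` must provide ``id``, ``lon``, ``lat`` and, for each
    isotope system used, a value and positive SD (``d2h``/``d2h_sd``,
    ``sr``/``sr_sd``).  Either isoscape may be omitted; at least one is
    required.
    """
    s = dict(specimen)
    surfaces: list[GeoGrid] = []
    if h_isoscape is not None and np.isfinite(s.get("d2h", np.nan)):
        surfaces.append(likelihood_surface(float(s["d2h"]), float(s["d2h_sd"]),
                                           h_isoscape))
    if sr_isoscape is not None and np.isfinite(s.get("sr", np.nan)):
        surfaces.append(likelihood_surface(float(s["sr"]), float(s["sr_sd"]),
                                           sr_isoscape))
    if not surfaces:
        raise ValueError("specimen has no usable isotope value")

    posterior = joint_posterior(surfaces, specimen_id=str(s["id"]))
    binary = odds_ratio_binary(posterior, odds=options.odds,
                               mode=options.odds_mode)
    cap_lon, cap_lat = float(s["lon"]), float(s["lat"])
    dist = min_distance(binary, cap_lon, cap_lat)
    spec = binary.mask_grid.spec
    r, c = spec.index_of(cap_lon, cap_lat)
    in_mask = bool(binary.cells[r, c])
    local = screen_putative_local(dist, in_mask, options.local_threshold_km)
    lon_c, lat_c = binary_centroid(binary)
    density, circ_mean, resultant = direction_distribution(
        posterior, cap_lon, cap_lat, bin_width_deg=options.bin_width_deg,
        distance_weighted=options.distance_weighted)
    return AssignmentResult(
        specimen_id=str(s["id"]), posterior=posterior, binary=binary,
        min_distance_km=dist, centroid_lon=lon_c, centroid_lat=lat_c,
        direction_pdf=density, circular_mean_deg=circ_mean,
        resultant_length=resultant, putative_local=local,
    )


def assign_table(
    specimens: pd.DataFrame,
    h_isoscape: Isoscape | None,
    sr_isoscape: Isoscape | None = None,
    options: AssignmentOptions = AssignmentOptions(),
) -> tuple[pd.DataFrame, list[AssignmentResult]]:
    """Assign every specimen in a table; returns (metrics, results).

    The metrics frame has one row per specimen: id, min_distance_km,
    centroid_lon, centroid_lat, circular_mean_deg, resultant_length,
    contained_mass, area_km2, putative_local.
    """
    results = []
    rows = []
    for _, spec_row in specimens.iterrows():
        res = assign_specimen(spec_row, h_isoscape, sr_isoscape, options)
        results.append(res)
        rows.append({
            "id": res.specimen_id,
            "lon": float(spec_row["lon"]),
            "lat": float(spec_row["lat"]),
            "min_distance_km": res.min_distance_km,
            "centroid_lon": res.centroid_lon,
            "centroid_lat": res.centroid_lat,
            "circular_mean_deg": res.circular_mean_deg,
            "resultant_length": res.resultant_length,
            "contained_mass": res.binary.contained_mass,
            "area_km2": res.binary.area_km2(),
            "putative_local": res.putative_local,
        })
    return pd.DataFrame(rows), results
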