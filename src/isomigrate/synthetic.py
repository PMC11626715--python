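"""Synthetic worlds with known ground truth.

Downstream stages (isoscape regression, assignment, connectivity) are
validated on data whose generating process is fully known: smooth
regional isotope fields built by Gaussian-smoothing white noise and
rescaling to a target range, predictor layers with a controlled
correlation to the field, strontium training points with site-level
noise, and specimens whose wing values are the field value at a known
true origin plus calibration residual and analytical noise.

The default noise magnitudes mirror the measurement process they stand
in for: +/-2 permil analytical precision for wing d2H, ~0.0001 analytical
reproducibility and 0.001 intra-site spread for 87Sr/86Sr, and a ~12
permil residual for the precipitation-to-wing transfer (a calibration
with r^2 ~ 0.5 over a continental d2H range implies a residual scatter
of that order).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from isomigrate import geo
from isomigrate.grid import GEOGRAPHIC, GeoGrid, GridSpec, Isoscape, PredictorStack

SPECIMEN_COLUMNS = [
    "id", "lon", "lat", "date", "season_region", "d2h", "d2h_sd", "sr", "sr_sd",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes for specimen and training-point generation.

    All SDs are standard deviations in the units of their isotope system
    (permil for d2H, absolute ratio for 87Sr/86Sr).
    """

    analytical_sd_h: float = 2.0
    analytical_sd_sr: float = 0.0001
    site_sd_sr: float = 0.001
    residual_sd_wing: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("analytical_sd_h", "analytical_sd_sr", "site_sd_sr",
                     "residual_sd_wing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """Smoothness and range of a synthetic isotope field.

    ``smooth_sigma`` is the Gaussian kernel width in cells; the smoothed
    white-noise field is affinely rescaled so its min/max equal
    ``vmin``/``vmax`` exactly.
    """

    vmin: float
    vmax: float
    smooth_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.vmax <= self.vmin:
            raise ValueError("vmax must exceed vmin")
        if self.smooth_sigma <= 0:
            raise ValueError("smooth_sigma must be positive")


@dataclass(frozen=True)
class DisplacementSpec:
    """Distribution of the capture-site -> natal-origin displacement.

    Distance is Normal(mean_km, sd_km) truncated at zero; the bearing
    from capture to origin is fixed when ``bearing_deg`` is given, else
    uniform on [0, 360).
    """

    mean_km: float = 0.0
    sd_km: float = 0.0
    bearing_deg: float | None = None


@dataclass
class SyntheticWorld:
    """Co-registered isoscapes, predictors and the specimen ground truth."""

    h_isoscape: Isoscape
    sr_isoscape: Isoscape
    predictor_stack: PredictorStack
    truth_table: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(columns=["id", "true_lon", "true_lat"])
    )

    def __post_init__(self) -> None:
        if self.h_isoscape.spec != self.sr_isoscape.spec:
            raise ValueError("isoscapes must share grid geometry")


def _smooth_unit_field(rng: np.random.Generator, spec: GridSpec,
                       sigma: float) -> np.ndarray:
    field = gaussian_filter(rng.standard_normal((spec.nrows, spec.ncols)),
                            sigma=sigma, mode="reflect")
    return field


def make_isoscape(
    seed: int,
    grid_spec: GridSpec,
    field_spec: FieldSpec,
    sd_spec: float | tuple[float, float] = 2.0,
    mask: np.ndarray | None = None,
) -> Isoscape:
    """Generate a smooth isotope field with a per-pixel SD grid.

    ``sd_spec`` is either a constant SD or a ``(lo, hi)`` pair giving a
    spatially varying SD field (an independent smooth field rescaled to
    that range).  ``mask`` optionally marks nodata cells (True = keep).
    """
    if grid_spec.nrows < 8 or grid_spec.ncols < 8:
        raise ValueError("grid must be at least 8x8")
    rng = np.random.default_rng(seed)
    raw = _smooth_unit_field(rng, grid_spec, field_spec.smooth_sigma)
    lo, hi = raw.min(), raw.max()
    mean = (raw - lo) / (hi - lo) * (field_spec.vmax - field_spec.vmin) + field_spec.vmin

    if isinstance(sd_spec, tuple):
        sd_lo, sd_hi = sd_spec
        if sd_lo <= 0 or sd_hi < sd_lo:
            raise ValueError("varying SD requires 0 < lo <= hi")
        raw_sd = _smooth_unit_field(rng, grid_spec, field_spec.smooth_sigma)
        a, b = raw_sd.min(), raw_sd.max()
        sd = (raw_sd - a) / (b - a) * (sd_hi - sd_lo) + sd_lo
    else:
        if sd_spec <= 0:
            raise ValueError("SD must be positive")
        sd = np.full_like(mean, float(sd_spec))

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        mean = np.where(mask, mean, np.nan)
        sd = np.where(mask, sd, np.nan)
    return Isoscape(GeoGrid(mean, grid_spec), GeoGrid(sd, grid_spec))


def make_predictor_stack(
    isoscape: Isoscape,
    n_informative: int = 3,
    n_noise: int = 3,
    corr: float = 0.9,
    seed: int = 0,
) -> PredictorStack:
    """Predictor layers with controlled correlation to the isoscape mean.

    Informative layers are affine transforms of
    ``corr * z(field) + sqrt(1 - corr^2) * z(noise)`` so their expected
    Pearson correlation with the field equals ``corr``; noise layers are
    independent smooth fields.
    """
    if n_informative < 1:
        raise ValueError("need at least one informative layer")
    if not 0.0 <= corr <= 1.0:
        raise ValueError("corr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    spec = isoscape.spec
    mean = isoscape.mean.values
    valid = isoscape.mean.mask
    z = (mean - np.nanmean(mean)) / np.nanstd(mean)

    layers: dict[str, GeoGrid] = {}
    for i in range(n_informative):
        w = _smooth_unit_field(rng, spec, sigma=1.0)
        w = (w - w.mean()) / w.std()
        combo = corr * z + np.sqrt(max(0.0, 1.0 - corr**2)) * w
        a = rng.uniform(-5, 5)
        b = rng.uniform(0.5, 2.0)
        vals = np.where(valid, a + b * combo, np.nan)
        layers[f"info{i + 1}"] = GeoGrid(vals, spec)
    for j in range(n_noise):
        # white noise: spatially smoothing these would induce spurious
        # sample correlation with the (smooth) field at desk-scale grids
        w = rng.standard_normal((spec.nrows, spec.ncols))
        vals = np.where(valid, rng.uniform(-5, 5) + rng.uniform(0.5, 2.0) * w, np.nan)
        layers[f"noise{j + 1}"] = GeoGrid(vals, spec)
    return PredictorStack(layers)


def sample_training_points(
    isoscape: Isoscape,
    n: int,
    noise: NoiseSpec,
    clustered: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample training points (lon, lat, ratio) from an isoscape.

    Each point's value is the field value at its cell plus
    ``Normal(0, site_sd_sr)``.  With ``clustered=True`` sampling density
    is concentrated (90%) in the western half of the grid, emulating the
    uneven density of literature compilations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    spec = isoscape.spec
    rows, cols = np.nonzero(isoscape.mean.mask)
    if rows.size == 0:
        raise ValueError("isoscape has no valid cells")

    if clustered:
        west = cols < spec.ncols // 2
        pools = [(rows[west], cols[west]), (rows[~west], cols[~west])]
        weights = [0.9, 0.1]
        n_west = int(round(n * weights[0])) if pools[0][0].size else 0
        counts = [n_west, n - n_west]
        picks: list[np.ndarray] = []
        for (pr, pc), cnt in zip(pools, counts):
            if cnt > 0 and pr.size == 0:
                raise ValueError("clustered sampling pool is empty")
            if cnt > 0:
                idx = rng.integers(0, pr.size, size=cnt)
                picks.append(np.stack([pr[idx], pc[idx]], axis=1))
        chosen = np.concatenate(picks, axis=0)
    else:
        idx = rng.integers(0, rows.size, size=n)
        chosen = np.stack([rows[idx], cols[idx]], axis=1)

    r, c = chosen[:, 0], chosen[:, 1]
    lon = spec.x0 + (c + rng.uniform(0, 1, size=n)) * spec.cell
    lat = spec.y0 + (spec.nrows - r - rng.uniform(0, 1, size=n)) * spec.cell
    value = isoscape.mean.values[r, c] + rng.normal(0.0, noise.site_sd_sr, size=n)
    return pd.DataFrame({"lon": lon, "lat": lat, "ratio": value})


def simulate_specimens(
    world: SyntheticWorld,
    n: int,
    capture_sites: Sequence[tuple[float, float]],
    displacement: DisplacementSpec,
    noise: NoiseSpec,
    season_region: str = "",
    start_day: int = 244,
    max_retries: int = 50,
    include_map_error: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate specimens with known natal origins.

    Each specimen is assigned a capture site (cycled from
    ``capture_sites``), a true origin displaced from it per
    ``displacement``, and wing values equal to the field value at the
    origin plus transfer residual and analytical noise (d2H) or
    site-level plus analytical noise (Sr).  With ``include_map_error``
    (default) the local field value itself deviates from the smooth
    isoscape mean by the isoscape's per-pixel SD — the micro-scale
    heterogeneity that SD grid represents — so assignment against the
    isoscape is exactly correctly specified.  Capture dates are assigned
    as consecutive days starting at day-of-year ``start_day``.

    Returns ``(specimens, truth)``; the truth table is also appended to
    ``world.truth_table``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = world.h_isoscape.spec
    for lon, lat in capture_sites:
        if not spec.contains(lon, lat):
            raise ValueError(f"capture site ({lon}, {lat}) off grid")

    rng = np.random.default_rng(noise.seed)
    records, truths = [], []
    for i in range(n):
        cap_lon, cap_lat = capture_sites[i % len(capture_sites)]
        origin = None
        for _ in range(max_retries):
            dist = max(0.0, rng.normal(displacement.mean_km, displacement.sd_km)) \
                if displacement.sd_km > 0 else displacement.mean_km
            brg = (displacement.bearing_deg if displacement.bearing_deg is not None
                   else rng.uniform(0.0, 360.0))
            ox, oy = geo.move(cap_lon, cap_lat, brg, dist, spec.crs)
            if spec.contains(ox, oy):
                r, c = spec.index_of(ox, oy)
                if (world.h_isoscape.mean.mask[r, c]
                        and world.sr_isoscape.mean.mask[r, c]):
                    origin = (float(ox), float(oy), r, c)
                    break
        if origin is None:
            raise RuntimeError(
                f"could not place origin for specimen {i} within "
                f"{max_retries} retries"
            )
        ox, oy, r, c = origin
        h_local = world.h_isoscape.mean.values[r, c]
        sr_local = world.sr_isoscape.mean.values[r, c]
        if include_map_error:
            h_local += rng.normal(0.0, world.h_isoscape.sd.values[r, c])
            sr_local += rng.normal(0.0, world.sr_isoscape.sd.values[r, c])
        d2h = (h_local
               + rng.normal(0.0, noise.residual_sd_wing)
               + rng.normal(0.0, noise.analytical_sd_h))
        sr = (sr_local
              + rng.normal(0.0, noise.site_sd_sr)
              + rng.normal(0.0, noise.analytical_sd_sr))
        day = start_day + i
        date = (pd.Timestamp("2019-01-01") + pd.Timedelta(days=day - 1)).date()
        sid = f"SYN{i + 1:04d}"
        records.append({
            "id": sid, "lon": cap_lon, "lat": cap_lat,
            "date": date.isoformat(), "season_region": season_region,
            "d2h": d2h,
            "d2h_sd": float(np.hypot(noise.residual_sd_wing, noise.analytical_sd_h)),
            "sr": sr,
            "sr_sd": float(np.hypot(noise.site_sd_sr, noise.analytical_sd_sr)),
        })
        truths.append({"id": sid, "true_lon": ox, "true_lat": oy})

    specimens = pd.DataFrame(records, columns=SPECIMEN_COLUMNS)
    truth = pd.DataFrame(truths)
    if world.truth_table.empty:
        world.truth_table = truth.copy()
    else:
        world.truth_table = pd.concat([world.truth_table, truth],
                                      ignore_index=True)
    return specimens, truth


def make_standard_world(
    seed: int = 0,
    nrows: int = 40,
    ncols: int = 40,
    corr: float = 0.9,
    n_informative: int = 3,
    n_noise: int = 3,
    h_sd: float = 2.0,
    sr_sd: float = 0.0005,
) -> SyntheticWorld:
    """The package's standard desk-scale test world.

    A 1-degree geographic grid spanning lon [-10, 30], lat [0, 40]
    (roughly the west Afro-Palearctic footprint), with a wing-d2H-like
    field on [-150, -20] permil and a Sr field on [0.704, 0.774] — the
    observed range of bioavailable ratios in the region.
    """
    spec = GridSpec(nrows=nrows, ncols=ncols, x0=-10.0, y0=0.0, cell=1.0,
                    crs=GEOGRAPHIC)
    h = make_isoscape(seed, spec, FieldSpec(vmin=-150.0, vmax=-20.0,
                                            smooth_sigma=5.0), sd_spec=h_sd)
    sr = make_isoscape(seed + 1000, spec, FieldSpec(vmin=0.704, vmax=0.774,
                                                    smooth_sigma=5.0), sd_spec=sr_sd)
    stack = make_predictor_stack(sr, n_informative=n_informative,
                                 n_noise=n_noise, corr=corr, seed=seed + 2000)
    return SyntheticWorld(h_isoscape=h, sr_isoscape=sr, predictor_stack=stack)


def write_specimens_csv(specimens: pd.DataFrame, path) -> None:
    specimens.to_csv(path, index=False, columns=SPECIMEN_COLUMNS)


def read_specimens_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(SPECIMEN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"specimen table missing columns: {sorted(missing)}")
    return df
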