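"""Isotope scale and transfer calibrations.

Four numeric transforms used before geographic assignment:

* reference-scale rescaling of legacy d2H data measured against
  superseded standard values (the two-point/least-squares line mapping
  a standard's old accepted value to its current one);
* an inter-method bridge fitted by OLS on duplicate measurements;
* the precipitation -> wing-tissue transfer applied to a growing-season
  precipitation isoscape, propagating uncertainty through the slope and
  the transfer residual;
* total 87Sr/86Sr uncertainty combining measurement uncertainty with the
  procedural-blank term (blank SD scaled by the blank/sample signal
  ratio).

Uncorrelated uncertainties combine in quadrature by default; an
arithmetic-sum mode is available behind ``combine="sum"`` flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from isomigrate.grid import GeoGrid, GridSpec, Isoscape


@dataclass(frozen=True)
class ReferenceScalePair:
    """One laboratory standard's value on the old and new scales."""

    standard_name: str
    old_value: float
    new_value: float


@dataclass(frozen=True)
class LinearTransfer:
    """A fitted linear map y = intercept + slope * x (permil units)."""

    intercept: float
    slope: float
    residual_sd: float = 0.0
    r2: float = float("nan")

    def apply(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def inverse(self) -> "LinearTransfer":
        if self.slope == 0:
            raise ValueError("transfer with zero slope is not invertible")
        return LinearTransfer(intercept=-self.intercept / self.slope,
                              slope=1.0 / self.slope)


# The transfer printed for the Afro-Palearctic wing-chitin isoscape:
# d2H_wing = -39.80 + 0.80 * d2H_gsp (r^2 = 0.53).  The residual SD used
# in assignment is a user input, not a constant.
WING_TRANSFER = LinearTransfer(intercept=-39.80, slope=0.80, r2=0.53)

# Current and superseded accepted values for keratin standards.
KHS_PAIR = ReferenceScalePair("KHS", old_value=-54.1, new_value=-35.3)
CBS_PAIR = ReferenceScalePair("CBS", old_value=-197.0, new_value=-157.0)


@dataclass(frozen=True)
class SrUncertainty:
    measurement_sd: float
    blank_sd: float
    blank_signal: float
    sample_signal: float
    total_sd: float


def rescale_reference(values, pairs: Sequence[ReferenceScalePair]) -> np.ndarray:
    """Map values measured against old standard values onto the new scale.

    Fits the least-squares line old -> new over the supplied standards;
    with exactly two standards this is the exact two-point line, so each
    anchor's old value maps to its new value exactly.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two reference standards")
    old = np.array([p.old_value for p in pairs], dtype=float)
    new = np.array([p.new_value for p in pairs], dtype=float)
    if np.ptp(old) == 0:
        raise ValueError("reference standards have identical old values; "
                         "transform is singular")
    slope, intercept = np.polyfit(old, new, 1)
    return intercept + slope * np.asarray(values, dtype=float)


def fit_method_bridge(x, y=None) -> LinearTransfer:
    """OLS calibration between two analytical methods.

    Accepts either two aligned arrays of duplicate measurements or a
    two-column table (method B, method A).  Returns the line predicting
    method-A values from method-B values, with the residual SD
    (sqrt(SSR / (n - 2))) and r^2.
    """
    if y is None:
        arr = np.asarray(x, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("expected a two-column table of duplicate pairs")
        xb, ya = arr[:, 0], arr[:, 1]
    else:
        xb = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
    if xb.size != ya.size:
        raise ValueError("duplicate arrays must be the same length")
    if xb.size < 3:
        raise ValueError("need at least three duplicate pairs")
    if np.ptp(xb) == 0:
        raise ValueError("all x values identical; bridge is singular")
    res = stats.linregress(xb, ya)
    fitted = res.intercept + res.slope * xb
    ssr = float(np.sum((ya - fitted) ** 2))
    residual_sd = float(np.sqrt(ssr / (xb.size - 2)))
    return LinearTransfer(intercept=float(res.intercept), slope=float(res.slope),
                          residual_sd=residual_sd, r2=float(res.rvalue**2))


def precip_to_wing(gsp_isoscape: Isoscape, transfer: LinearTransfer,
                   combine: str = "quadrature") -> Isoscape:
    """Calibrate a precipitation isoscape to wing tissue.

    The mean grid is mapped through the transfer line.  The SD grid
    combines the precipitation SD scaled by |slope| with the transfer's
    residual SD — in quadrature by default, arithmetically with
    ``combine="sum"``.
    """
    mean = transfer.apply(gsp_isoscape.mean.values)
    scaled_sd = np.abs(transfer.slope) * gsp_isoscape.sd.values
    if combine == "quadrature":
        sd = np.sqrt(scaled_sd**2 + transfer.residual_sd**2)
    elif combine == "sum":
        sd = scaled_sd + transfer.residual_sd
    else:
        raise ValueError("combine must be 'quadrature' or 'sum'")
    sd = np.where(gsp_isoscape.sd.mask, sd, np.nan)
    mean = np.where(gsp_isoscape.mean.mask, mean, np.nan)
    spec = gsp_isoscape.spec
    return Isoscape(GeoGrid(mean, spec), GeoGrid(sd, spec))


def _resample_grid(src: GeoGrid, target: GridSpec, order: int) -> np.ndarray:
    """Sample a grid at the target's cell centres (order 1 = bilinear,
    0 = nearest), treating nodata as missing."""
    sspec = src.spec
    tx = target.x_centers()
    ty = target.y_centers()
    # fractional (row, col) indices of target centres in the source array
    cols = (tx - sspec.x0) / sspec.cell - 0.5
    rows = sspec.nrows - (ty - sspec.y0) / sspec.cell - 0.5
    cgrid, rgrid = np.meshgrid(cols, rows)
    vals = np.where(src.mask, src.values, 0.0)
    out = ndimage.map_coordinates(vals, [rgrid, cgrid], order=order,
                                  mode="nearest")
    weight = ndimage.map_coordinates(src.mask.astype(float), [rgrid, cgrid],
                                     order=order, mode="nearest")
    inside = ((cgrid >= -0.5) & (cgrid <= sspec.ncols - 0.5)
              & (rgrid >= -0.5) & (rgrid <= sspec.nrows - 0.5))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((weight > 0.999) & inside, out / np.maximum(weight, 1e-12),
                       np.nan)
    return out


def resample_to_grid(src: Isoscape, target: GridSpec) -> Isoscape:
    """Resample an isoscape onto another grid geometry.

    The mean grid is interpolated bilinearly; the SD grid uses
    nearest-neighbour sampling (interpolating SDs would understate
    local uncertainty).  Nodata is preserved; disjoint extents error.
    """
    s = src.spec
    if (s.x_max <= target.x0 or target.x_max <= s.x0
            or s.y_max <= target.y0 or target.y_max <= s.y0):
        raise ValueError("source and target extents are disjoint")
    if src.spec == target:
        return Isoscape(GeoGrid(src.mean.values.copy(), target),
                        GeoGrid(src.sd.values.copy(), target))
    mean = _resample_grid(src.mean, target, order=1)
    sd = _resample_grid(src.sd, target, order=0)
    sd = np.where(np.isfinite(mean), sd, np.nan)
    return Isoscape(GeoGrid(mean, target), GeoGrid(sd, target))


def sr_total_uncertainty(measurement_sd: float, blank_sd: float,
                         blank_signal: float, sample_signal: float,
                         combine: str = "quadrature") -> SrUncertainty:
    """Total 87Sr/86Sr uncertainty including the procedural-blank bias.

    The blank term is the blank measurement SD scaled by the
    blank/sample signal-intensity ratio; it is propagated with the
    sample measurement SD (quadrature by default).
    """
    if sample_signal <= 0:
        raise ValueError("sample_signal must be positive")
    for name, v in (("measurement_sd", measurement_sd), ("blank_sd", blank_sd),
                    ("blank_signal", blank_signal)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    blank_term = blank_sd * (blank_signal / sample_signal)
    if combine == "quadrature":
        total = float(np.hypot(measurement_sd, blank_term))
    elif combine == "sum":
        total = measurement_sd + blank_term
    else:
        raise ValueError("combine must be 'quadrature' or 'sum'")
    return SrUncertainty(measurement_sd=measurement_sd, blank_sd=blank_sd,
                         blank_signal=blank_signal, sample_signal=sample_signal,
                         total_sd=total)
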