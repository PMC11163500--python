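"""Radiochromic film dosimetry pipeline (EBT3-style, red channel).

Films darken with absorbed dose; the analysis chain converts a 48-bit RGB
scan into a dose map:

1. extract the red channel (the most dose-sensitive one for this film type);
2. form the net optical density against an unexposed film of the same batch,
   netOD = log10(I_unexposed / I_exposed);
3. map netOD to dose through a third-degree-polynomial calibration fitted to
   films exposed to known doses between 0 and 2 Gy;
4. median-filter to suppress scanner/grain noise;
5. read off profiles and output factors from the calibrated dose maps.

Pixel pitch follows from the scanner resolution: spacing_mm = 25.4 / dpi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import Polynomial
from scipy.ndimage import median_filter as _nd_median

from .scan_analysis import _outer_crossing

__all__ = [
    "CalibrationCurve",
    "FilmScan",
    "dose_map",
    "film_output_factor",
    "fit_calibration",
    "median_filter",
    "net_response",
    "read_film_tiff",
    "red_channel",
    "write_film_tiff",
]

#: Median-filter window (pixels) applied before picking output-factor ROIs.
OUTPUT_FILTER_PX = 5
#: Central ROI (pixels) over which the output-factor dose is averaged.
OUTPUT_ROI_PX = 5
#: Beam-quality transfer factor between the calibration beam and the
#: measurement beam; film response is weakly energy dependent, so the
#: transfer is taken as unity by default (adjustable).
BEAM_QUALITY_FACTOR = 1.0


@dataclass(frozen=True)
class FilmScan:
    """A scanned film: 3-channel 16-bit pixels plus scan/exposure metadata."""

    pixels: np.ndarray
    dpi: float
    monitor_units: float | None = None
    field_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("film scans must have exactly 3 channels")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if px.min() < 0 or px.max() >= 2**16:
            raise ValueError("pixel values must fit 16-bit depth")
        object.__setattr__(self, "pixels", px)

    @property
    def spacing_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass(frozen=True)
class CalibrationCurve:
    """Cubic netOD -> dose calibration over a stated response range.

    The polynomial must be strictly increasing over the calibrated response
    range and map zero response to (near) zero dose.
    """

    coefficients: np.ndarray  # ascending powers
    response_range: tuple[float, float]
    dose_range: tuple[float, float] = (0.0, 2.0)
    batch_id: str = ""

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (4,):
            raise ValueError("calibration must be a third-degree polynomial")
        object.__setattr__(self, "coefficients", coeffs)
        poly = Polynomial(coeffs)
        lo, hi = self.response_range
        grid = np.linspace(lo, hi, 512)
        if np.any(poly.deriv()(grid) <= 0):
            raise ValueError("calibration must be strictly increasing over "
                             "the calibrated response range")
        if abs(poly(0.0)) > 0.02:
            raise ValueError("calibration maps zero response to "
                             f"{poly(0.0):+.3f} Gy; expected ~0")

    def __call__(self, response: np.ndarray) -> np.ndarray:
        return Polynomial(self.coefficients)(np.asarray(response, dtype=float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def red_channel(scan: FilmScan) -> np.ndarray:
    """The red (first) channel of the scan, unchanged."""
    return scan.pixels[:, :, 0].copy()


def net_response(exposed: np.ndarray, unexposed: np.ndarray) -> np.ndarray:
    """Net optical density per pixel: log10(I_unexposed / I_exposed)."""
    exposed = np.asarray(exposed, dtype=float)
    unexposed = np.asarray(unexposed, dtype=float)
    if exposed.shape != unexposed.shape:
        raise ValueError("exposed and unexposed images must share a shape")
    if np.any(exposed <= 0) or np.any(unexposed <= 0):
        raise ValueError("intensities must be positive to form an optical "
                         "density")
    return np.log10(unexposed / exposed)


def fit_calibration(doses, responses, batch_id: str = "") -> CalibrationCurve:
    """Least-squares cubic fit of dose (Gy) against net response.

    Requires at least four distinct points spanning doses within [0, 2] Gy;
    the fitted polynomial is verified to be monotone increasing over the
    calibrated response range.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be equal-length 1D")
    if len(np.unique(responses)) < 4:
        raise ValueError("need at least 4 distinct calibration points")
    if doses.min() < -1e-9 or doses.max() > 2.0 + 1e-9:
        raise ValueError("calibration doses must lie within [0, 2] Gy")
    if len(np.unique(responses)) != len(responses):
        raise ValueError("duplicate response values in calibration data")

    poly = Polynomial.fit(responses, doses, deg=3).convert()
    rng = (float(responses.min()), float(responses.max()))
    try:
        return CalibrationCurve(coefficients=poly.coef, response_range=rng,
                                batch_id=batch_id)
    except ValueError as exc:
        raise ValueError(
            f"calibration fit rejected ({exc}); acquire more or cleaner "
            "calibration points") from exc


def median_filter(image: np.ndarray, window: int) -> np.ndarray:
    """2D median filter with reflected edges; window must be odd >= 3."""
    if window < 3 or window % 2 == 0:
        raise ValueError("median filter window must be an odd integer >= 3")
    return _nd_median(np.asarray(image, dtype=float), size=window,
                      mode="reflect")


def dose_map(scan: FilmScan, unexposed_ref: FilmScan,
             calibration: CalibrationCurve,
             max_out_of_range: float = 0.01) -> tuple[np.ndarray, float]:
    """Calibrated per-pixel dose map (Gy) and its pixel spacing (mm).

    Responses outside the calibrated range are clipped; if more than
    ``max_out_of_range`` of the pixels fall outside, the map is rejected
    rather than silently extrapolated.
    """
    response = net_response(red_channel(scan), red_channel(unexposed_ref))
    lo, hi = calibration.response_range
    # pixel noise legitimately scatters responses a little past the fitted
    # range; only flag pixels clearly beyond it
    margin = 0.05 * (hi - lo)
    outside = (response < lo - margin) | (response > hi + margin)
    if outside.mean() > max_out_of_range:
        raise ValueError(
            f"{outside.mean():.1%} of pixels outside the calibrated response "
            "range; recalibrate or crop the scan")
    dose = calibration(np.clip(response, lo, hi)) * BEAM_QUALITY_FACTOR
    return dose, scan.spacing_mm


def _center_indices(dose: np.ndarray) -> tuple[int, int]:
    """Field centre (row, col) from 50% crossings of orthogonal profiles."""
    row_profile = dose[dose.shape[0] // 2, :]
    col_profile = dose[:, dose.shape[1] // 2]

    def center(profile: np.ndarray) -> int:
        idx = np.arange(profile.size, dtype=float)
        level = 0.5 * profile.max()
        left = _outer_crossing(idx, profile, level, "left")
        right = _outer_crossing(idx, profile, level, "right")
        return int(round(0.5 * (left + right)))

    return center(col_profile), center(row_profile)


def film_output_factor(dose_maps_clin: list[np.ndarray],
                       dose_maps_msr: list[np.ndarray],
                       roi_px: int = OUTPUT_ROI_PX,
                       filter_px: int = OUTPUT_FILTER_PX
                       ) -> tuple[float, float]:
    """Film output factor with type-A uncertainty from repeated films.

    Each repeat map is median filtered, centred on its field via the 50%
    crossings of the two orthogonal central profiles, and read out over a
    small central ROI; the output factor is the ratio of the mean clinical
    to mean reference central dose, and the uncertainty combines the
    standard errors of both means in quadrature.
    """
    if not dose_maps_clin or not dose_maps_msr:
        raise ValueError("need at least one repeat per field")

    def central_values(maps: list[np.ndarray]) -> np.ndarray:
        vals = []
        for m in maps:
            filtered = median_filter(m, filter_px)
            cy, cx = _center_indices(filtered)
            h = roi_px // 2
            roi = filtered[cy - h:cy + h + 1, cx - h:cx + h + 1]
            if roi.shape != (roi_px, roi_px):
                raise ValueError("ROI extends beyond the film")
            # the ROI must sit inside the flat core of the field: its mean
            # and the centre pixel must agree closely
            if abs(roi.mean() - filtered[cy, cx]) > 0.05 * filtered[cy, cx]:
                raise ValueError("ROI larger than the flat region of the "
                                 "field; reduce roi_px")
            vals.append(float(roi.mean()))
        return np.asarray(vals)

    clin = central_values(dose_maps_clin)
    msr = central_values(dose_maps_msr)
    ratio = clin.mean() / msr.mean()
    rel = 0.0
    for vals in (clin, msr):
        if vals.size > 1:
            rel += (vals.std(ddof=1) / np.sqrt(vals.size) / vals.mean()) ** 2
    return float(ratio), float(ratio * np.sqrt(rel))


# ---------------------------------------------------------------------------
# TIFF I/O (uncompressed 48-bit RGB, as produced by flatbed film scanners)
# ---------------------------------------------------------------------------


def write_film_tiff(path: str | Path, scan: FilmScan) -> None:
    import tifffile

    tifffile.imwrite(Path(path), scan.pixels.astype(np.uint16),
                     photometric="rgb",
                     resolution=(scan.dpi, scan.dpi),
                     compression=None)


def read_film_tiff(path: str | Path, dpi: float | None = None,
                   **metadata) -> FilmScan:
    import tifffile

    with tifffile.TiffFile(Path(path)) as tif:
        pixels = tif.asarray()
        if dpi is None:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            if xres is None:
                raise ValueError("TIFF carries no resolution tag; pass dpi=")
            num, den = xres.value
            dpi = num / den
    return FilmScan(pixels=pixels, dpi=float(dpi), **metadata)
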