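"""Beam-scan analytics: lateral profile and depth-dose metrics.

Operational quantities used to commission a circular radiosurgery beam from
water-phantom scans:

* dosimetric field size — full width at half maximum (FWHM) of the lateral
  profile, with the half level crossings located by linear interpolation;
* 20%-80% penumbra width per edge;
* depth of dose maximum and percentage dose at depth from a percentage
  depth-dose (PDD) curve.

Profiles are (positions_mm, values) pairs with uniform, increasing positions.
Level crossings use the *outermost* crossing on each side, which is robust to
noisy shoulders near the field edge; all metrics are invariant under positive
rescaling of the signal and translation of the position axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PDDMetrics",
    "ProfileMetrics",
    "fwhm",
    "normalize_profile",
    "pdd_metrics",
    "penumbra",
    "profile_metrics",
    "read_profile_csv",
    "write_profile_csv",
]


@dataclass(frozen=True)
class ProfileMetrics:
    """Summary metrics of a lateral beam profile (all lengths in mm)."""

    fwhm: float
    penumbra_left: float
    penumbra_right: float
    center: float
    normalization_value: float


@dataclass(frozen=True)
class PDDMetrics:
    """Depth-dose metrics: depth of maximum and percent dose at depths."""

    d_max: float
    percent_dose_at: dict[float, float]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_profile(positions, values) -> tuple[np.ndarray, np.ndarray]:
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.ndim != 1 or positions.shape != values.shape:
        raise ValueError("profile must be two equal-length 1D arrays")
    if positions.size < 3:
        raise ValueError("profile too short")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    return positions, values


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _outer_crossing(positions: np.ndarray, values: np.ndarray, level: float,
                    side: str) -> float:
    """Outermost linearly interpolated crossing of ``level`` on a side.

    ``side='left'`` walks in from the left end, ``side='right'`` from the
    right end, returning the first position where the signal rises through
    the level.
    """
    above = values >= level
    if side == "left":
        indices = range(len(values) - 1)
    elif side == "right":
        indices = range(len(values) - 2, -1, -1)
    else:
        raise ValueError("side must be 'left' or 'right'")
    for i in indices:
        lo, hi = (i, i + 1) if side == "left" else (i + 1, i)
        if not above[lo] and above[hi]:
            frac = (level - values[lo]) / (values[hi] - values[lo])
            return float(positions[lo] + frac * (positions[hi] - positions[lo]))
    raise ValueError(f"profile never crosses {level:g} on the {side} side")


def _count_crossings(values: np.ndarray, level: float) -> int:
    above = values >= level
    return int(np.count_nonzero(np.diff(above.astype(int)) != 0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_profile(positions, values, smoothing_window: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale a profile so its (optionally smoothed) maximum is 100.

    Returns the positions, the scaled values and the normalisation value
    (the signal level mapped to 100%).  No smoothing is applied by default —
    sharp few-mm profiles are easily biased by it; pass an odd window for
    noisy measured data.
    """
    positions, values = _as_profile(positions, values)
    ref = _moving_average(values, smoothing_window) if smoothing_window else values
    norm = float(ref.max())
    if norm <= 0:
        raise ValueError("profile has no positive values to normalise to")
    return positions, values * (100.0 / norm), norm


def fwhm(positions, values) -> float:
    """Full width at half maximum of a single-lobed profile, in mm.

    The 50% level (of the profile maximum) must be crossed on both sides;
    crossings are located by linear interpolation between bracketing samples
    and the outermost crossing is used on each side.
    """
    positions, values = _as_profile(positions, values)
    level = 0.5 * values.max()
    if _count_crossings(values, level) > 2:
        warnings.warn("multiple 50% crossings; using the outermost pair",
                      stacklevel=2)
    left = _outer_crossing(positions, values, level, "left")
    right = _outer_crossing(positions, values, level, "right")
    return right - left


def penumbra(positions, values, side: str) -> float:
    """20%-80% penumbra width of one field edge, in mm."""
    positions, values = _as_profile(positions, values)
    vmax = values.max()
    lo = _outer_crossing(positions, values, 0.2 * vmax, side)
    hi = _outer_crossing(positions, values, 0.8 * vmax, side)
    return abs(hi - lo)


def profile_metrics(positions, values,
                    smoothing_window: int | None = None) -> ProfileMetrics:
    """FWHM, both penumbrae, field centre and normalisation of a profile.

    The centre is the midpoint of the two 50% crossings, mirroring how the
    detector is centred on the radiation field before a scan.
    """
    positions, norm_vals, norm = normalize_profile(positions, values,
                                                   smoothing_window)
    left = _outer_crossing(positions, norm_vals, 50.0, "left")
    right = _outer_crossing(positions, norm_vals, 50.0, "right")
    return ProfileMetrics(
        fwhm=right - left,
        penumbra_left=penumbra(positions, norm_vals, "left"),
        penumbra_right=penumbra(positions, norm_vals, "right"),
        center=0.5 * (left + right),
        normalization_value=norm,
    )


def pdd_metrics(depths, values, depths_of_interest=(),
                smooth_window: int = 5) -> PDDMetrics:
    """Depth of maximum and percentage dose at requested depths.

    The depth of maximum is the maximum of a locally smoothed curve (moving
    average, default 5 samples), refined by a parabolic fit through the three
    samples around the discrete maximum.  Percentage doses are linear
    interpolations of the smoothed curve, relative to its maximum.
    """
    depths, values = _as_profile(depths, values)
    if np.any(values <= 0):
        raise ValueError("PDD values must be positive")
    smooth = _moving_average(values, smooth_window)
    i = int(np.argmax(smooth))
    if 0 < i < len(smooth) - 1:
        denom = smooth[i - 1] - 2 * smooth[i] + smooth[i + 1]
        delta = 0.5 * (smooth[i - 1] - smooth[i + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        step = depths[i + 1] - depths[i] if delta >= 0 else depths[i] - depths[i - 1]
        d_max = float(depths[i] + delta * step)
    else:
        d_max = float(depths[i])
    vmax = float(smooth.max())

    percent: dict[float, float] = {}
    for d in depths_of_interest:
        if not depths[0] <= d <= depths[-1]:
            raise ValueError(f"requested depth {d} mm outside scanned range")
        percent[float(d)] = float(np.interp(d, depths, smooth) / vmax * 100.0)
    return PDDMetrics(d_max=d_max, percent_dose_at=percent)


# ---------------------------------------------------------------------------
# CSV I/O (two-column tables: position_mm,value)
# ---------------------------------------------------------------------------


def read_profile_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float)


def write_profile_csv(path: str | Path, positions, values,
                      position_label: str = "position_mm") -> None:
    pd.DataFrame({position_label: np.asarray(positions, float),
                  "value": np.asarray(values, float)}).to_csv(path, index=False)
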