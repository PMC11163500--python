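"""Synthetic measurement generator with known ground truth.

Every input the analysis pipeline consumes — lateral dose profiles, depth
dose curves, film scans and detector output readings — can be generated here
with the statistical structure of water-phantom and film measurements of a
3-25 mm circular-cone 3 MV radiosurgery beam:

* lateral dose: top-hat fluence of the nominal cone diameter, scaled by the
  geometric beam divergence with depth (SSD 450 mm), convolved with a
  two-Gaussian (core + tail) dose-deposition kernel whose defaults are
  calibrated so the 3 mm beam at 7 mm depth shows FWHM 3.0 mm and a
  20-80% penumbra of about 1.35 mm;
* depth dose: build-up/fall-off curve A*(1-exp(-mu1*z))*exp(-mu2*z) with
  coefficients anchored so the depth of maximum is about 4.8 mm for the
  3 mm cone and 7.8 mm for the 25 mm reference cone, with the matching
  percentage doses at 100 mm depth;
* film: a monotone cubic netOD -> dose truth inverted to pixel intensities,
  with multiplicative pixel noise;
* output readings: a true output-factor curve divided by the published total
  detector correction, so correcting the readings recovers the truth.

Every generator is a pure function of its parameters and an explicit seed,
and returns its ground truth alongside the samples; no analysis stage reads
the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .beam_model import DoseKernel, RadialDoseMap, convolve_radial, extract_profile, top_hat
from .detector_response import packaged_factor_table
from .film_dosimetry import FilmScan
from .output_factors import OFFitParams
from .scan_analysis import ProfileMetrics, profile_metrics

__all__ = [
    "BeamSpec",
    "DEFAULT_OF_PARAMS",
    "FilmModel",
    "ORSeries",
    "SyntheticPDD",
    "SyntheticProfile",
    "make_dose_profile",
    "make_film_set",
    "make_or_series",
    "make_pdd",
]

#: Depth at which the beam shape is anchored (profile reference depth, mm).
REFERENCE_DEPTH_MM = 7.0

#: Field-size growth with depth (beam divergence plus phantom scatter),
#: anchored to the measured FWHM of the 3 mm cone: 3.0 mm at 7 mm depth
#: growing to 4.8 mm at 250 mm.  Values are multipliers of the nominal size.
DEPTH_FIELD_SCALE = {7.0: 1.0, 50.0: 3.3 / 3.0, 100.0: 3.6 / 3.0,
                     200.0: 4.4 / 3.0, 250.0: 4.8 / 3.0}

#: Kernel-width multipliers vs depth, tracking the measured penumbra growth
#: of the 3 mm cone between 7 and 250 mm depth.
DEPTH_KERNEL_SCALE = {7.0: 1.0, 50.0: 1.15, 100.0: 1.31, 200.0: 1.62,
                      250.0: 1.77}

#: PDD coefficients (mu1, mu2) per cone diameter, anchored so d_max is
#: ~4.8 mm for the 3 mm cone (percentage dose 35.6% at 100 mm) and ~7.8 mm
#: for the 25 mm cone (41.2% at 100 mm); interpolated linearly in diameter.
_PDD_ANCHORS = {3.0: (0.92666, 0.010973), 25.0: (0.50839, 0.0098251)}

#: Default ground-truth output-factor curve (saturating two-component form),
#: shaped like the measured film output factors of the 3-25 mm cone set.
DEFAULT_OF_PARAMS = OFFitParams(p=1.0, a=3.0, b=1.1, n=3.0)


@dataclass(frozen=True)
class BeamSpec:
    """Parameters of one synthetic cone beam.

    The kernel defaults reproduce the measured 3 mm beam shape at 7 mm
    depth; ``noise_level`` is the additive scan noise relative to the
    profile maximum (a short-dwell scanning detector shows noise at the few
    per-mille level).
    """

    nominal_diameter: float = 3.0
    sigma_core: float = 0.85
    sigma_tail: float = 1.5
    tail_weight: float = 0.2
    noise_level: float = 0.005
    spacing: float = 0.1

    def __post_init__(self) -> None:
        if not 3.0 <= self.nominal_diameter <= 25.0:
            raise ValueError("nominal diameter must be within 3-25 mm")
        if self.sigma_core <= 0 or self.sigma_tail <= 0:
            raise ValueError("kernel sigmas must be positive")
        if not 0 <= self.tail_weight < 1:
            raise ValueError("tail weight must be in [0, 1)")

    def kernel(self, depth: float = REFERENCE_DEPTH_MM) -> DoseKernel:
        """Dose-deposition kernel broadened for the requested depth."""
        depths = np.array(sorted(DEPTH_KERNEL_SCALE))
        scales = np.array([DEPTH_KERNEL_SCALE[d] for d in depths])
        s = float(np.interp(depth, depths, scales))
        return DoseKernel.two_gaussian(self.sigma_core * s,
                                       self.sigma_tail * s,
                                       self.tail_weight,
                                       spacing=self.spacing)

    def diameter_at(self, depth: float) -> float:
        """Effective field diameter at depth, from the anchored growth table."""
        depths = np.array(sorted(DEPTH_FIELD_SCALE))
        scales = np.array([DEPTH_FIELD_SCALE[d] for d in depths])
        return self.nominal_diameter * float(np.interp(depth, depths, scales))


@dataclass(frozen=True)
class FilmModel:
    """Ground-truth film response model.

    ``dose_coefficients`` are the ascending-power coefficients of the true
    cubic netOD -> dose mapping, monotone over the calibrated range;
    intensities are 16-bit scanner counts.
    """

    dose_coefficients: tuple[float, ...] = (0.0, 2.0, 1.0, 4.0)
    unexposed_intensity: float = 40000.0
    pixel_noise: float = 0.01
    dpi: float = 600.0

    def __post_init__(self) -> None:
        grid = np.linspace(0.0, self.netod_for(2.0), 256)
        deriv = np.polynomial.Polynomial(self.dose_coefficients).deriv()
        if np.any(deriv(grid) <= 0):
            raise ValueError("truth cubic must be monotone over 0-2 Gy")

    def dose_for(self, netod: np.ndarray) -> np.ndarray:
        return np.polynomial.Polynomial(self.dose_coefficients)(netod)

    def netod_for(self, dose: np.ndarray) -> np.ndarray:
        """Invert the monotone truth cubic (dense-grid interpolation)."""
        grid = np.linspace(0.0, 1.0, 4001)
        return np.interp(dose, self.dose_for(grid), grid)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticProfile:
    """A generated lateral scan with its noiseless truth."""

    positions: np.ndarray
    values: np.ndarray
    noiseless: np.ndarray
    truth: ProfileMetrics
    dose_map: RadialDoseMap
    depth: float
    spec: BeamSpec


def make_dose_profile(spec: BeamSpec | None = None,
                      depth: float = REFERENCE_DEPTH_MM,
                      seed: int = 0) -> SyntheticProfile:
    """Lateral dose profile of a cone beam at depth, with ground truth.

    The noiseless curve is the top-hat fluence (divergence-scaled diameter)
    convolved with the depth-broadened kernel; seeded additive Gaussian
    noise of ``spec.noise_level`` x maximum is applied to the returned
    samples.  The truth metrics are evaluated on the noiseless curve.
    """
    spec = spec or BeamSpec()
    if not min(DEPTH_KERNEL_SCALE) <= depth <= max(DEPTH_KERNEL_SCALE):
        raise ValueError("depth outside the anchored 7-250 mm range")
    kernel = spec.kernel(depth)
    diameter = spec.diameter_at(depth)
    dose = convolve_radial(top_hat(diameter), kernel, spacing=spec.spacing,
                           half_width=diameter / 2 + kernel.support_radius
                           + 2.0)
    positions, noiseless = extract_profile(dose, "x")
    rng = np.random.default_rng(seed)
    noisy = noiseless + rng.normal(
        0.0, spec.noise_level * noiseless.max(), noiseless.shape)
    return SyntheticProfile(
        positions=positions,
        values=noisy,
        noiseless=noiseless,
        truth=profile_metrics(positions, noiseless),
        dose_map=dose,
        depth=depth,
        spec=spec,
    )


@dataclass(frozen=True)
class SyntheticPDD:
    """A generated depth-dose curve with its analytic depth of maximum."""

    depths: np.ndarray
    values: np.ndarray
    noiseless: np.ndarray
    d_max_true: float
    mu1: float
    mu2: float


def make_pdd(field_diameter: float = 3.0, seed: int = 0,
             noise_level: float = 0.005, z_max: float = 250.0,
             step: float = 0.2, mu1: float | None = None,
             mu2: float | None = None) -> SyntheticPDD:
    """Central-axis depth-dose curve with a known analytic maximum.

    Shape A*(1-exp(-mu1*z))*exp(-mu2*z): exponential build-up against
    exponential attenuation-plus-scatter fall-off; coefficients interpolated
    between the 3 mm and 25 mm anchors.  ``mu2 = 0`` degenerates to a
    monotone saturating curve with its maximum at the range end.
    """
    diameters = np.array(sorted(_PDD_ANCHORS))
    if mu1 is None:
        mu1 = float(np.interp(field_diameter, diameters,
                              [_PDD_ANCHORS[d][0] for d in diameters]))
    if mu2 is None:
        mu2 = float(np.interp(field_diameter, diameters,
                              [_PDD_ANCHORS[d][1] for d in diameters]))
    depths = np.arange(0.0, z_max + step / 2, step)
    noiseless = (1.0 - np.exp(-mu1 * depths)) * np.exp(-mu2 * depths)
    d_max = np.log1p(mu1 / mu2) / mu1 if mu2 > 0 else float(depths[-1])
    rng = np.random.default_rng(seed)
    noisy = noiseless + rng.normal(0.0, noise_level * noiseless.max(),
                                   noiseless.shape)
    return SyntheticPDD(depths=depths, values=noisy, noiseless=noiseless,
                        d_max_true=float(d_max), mu1=mu1, mu2=mu2)


def make_film_set(dose_truth, model: FilmModel | None = None,
                  n_repeats: int = 5, seed: int = 0,
                  shape: tuple[int, int] = (64, 64)
                  ) -> tuple[list[FilmScan], FilmScan, dict]:
    """Repeated film exposures of a known dose, plus an unexposed reference.

    ``dose_truth`` is either a scalar dose in Gy (uniform film, e.g. a
    calibration exposure) or a 2D dose image in Gy.  Pixel intensities are
    the inverse of the truth response model with multiplicative Gaussian
    noise per repeat; the green and blue channels darken with smaller
    sensitivity, as radiochromic film does.

    Returns (films, unexposed_reference, truth) where truth records the dose
    image and the model.
    """
    model = model or FilmModel()
    dose_img = np.asarray(dose_truth, dtype=float)
    if dose_img.ndim == 0:
        dose_img = np.full(shape, float(dose_img))
    elif dose_img.ndim != 2:
        raise ValueError("dose_truth must be a scalar or a 2D image")
    if dose_img.min() < 0 or dose_img.max() > 2.0:
        raise ValueError("film truth doses must lie within 0-2 Gy")

    netod = model.netod_for(dose_img)
    rng = np.random.default_rng(seed)
    i0 = model.unexposed_intensity

    def channels(od_red: np.ndarray) -> np.ndarray:
        # lower sensitivity in green/blue, as for real radiochromic scans
        stack = [i0 * 10.0 ** (-f * od_red) for f in (1.0, 0.45, 0.15)]
        return np.stack(stack, axis=-1)

    films = []
    for _ in range(n_repeats):
        clean = channels(netod)
        noisy = clean * rng.normal(1.0, model.pixel_noise, clean.shape)
        films.append(FilmScan(
            pixels=np.clip(noisy, 1, 2**16 - 1).astype(np.uint16),
            dpi=model.dpi, monitor_units=200.0))
    unexposed_clean = channels(np.zeros_like(netod))
    unexposed = FilmScan(
        pixels=np.clip(
            unexposed_clean * rng.normal(1.0, model.pixel_noise,
                                         unexposed_clean.shape),
            1, 2**16 - 1).astype(np.uint16),
        dpi=model.dpi)
    truth = {"dose": dose_img, "model": model,
             "spacing_mm": 25.4 / model.dpi}
    return films, unexposed, truth


@dataclass(frozen=True)
class ORSeries:
    """Generated detector readings with the underlying truth."""

    field_sizes: np.ndarray
    readings: np.ndarray  # (n_fields, n_repeats) signal per MU
    msr_readings: np.ndarray  # (n_repeats,)
    true_of: np.ndarray
    k_total: np.ndarray


def _k_total_interp(field_sizes: np.ndarray) -> np.ndarray:
    table = packaged_factor_table()
    sizes = np.array(sorted(table))
    k = np.array([table[s].k_total for s in sizes])
    return np.interp(field_sizes, sizes, k)


def make_or_series(field_sizes=(3.0, 4.0, 5.0, 7.5, 10.0, 12.5, 15.0, 20.0,
                                25.0),
                   true_of_params: OFFitParams = DEFAULT_OF_PARAMS,
                   seed: int = 0, noise_level: float = 0.002,
                   n_repeats: int = 5) -> ORSeries:
    """Detector output readings per field with a known output-factor truth.

    Each reading is the true output factor divided by the detector's total
    correction (interpolated from the packaged published table) with
    multiplicative seeded noise — so correcting the measured output ratio
    with ``k_total`` recovers the true output factor up to noise.
    """
    field_sizes = np.asarray(field_sizes, dtype=float)
    true_of = true_of_params(field_sizes)
    k = _k_total_interp(field_sizes)
    rng = np.random.default_rng(seed)
    readings = (true_of / k)[:, None] * rng.normal(
        1.0, noise_level, (field_sizes.size, n_repeats))
    msr = rng.normal(1.0, noise_level, n_repeats)
    return ORSeries(field_sizes=field_sizes, readings=readings,
                    msr_readings=msr, true_of=true_of, k_total=k)
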