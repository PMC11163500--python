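"""Output ratios, corrected output factors and the field-size response fit.

The *output ratio* of a clinical cone relative to the machine-specific
reference (msr) cone is the ratio of detector signal per monitor unit::

    OR = M_det(f_clin) / M_det(f_msr)

Applying the detector's total perturbation correction yields the *output
factor*, OF = OR x k_total.  Across nominal field sizes s the output factor
follows a saturating two-component curve::

    OF(s) = p * s^n / (a^n + s^n) * (1 - exp(-b * s))

with the sigmoidal first factor describing collimator/source occlusion and
the exponential factor the build-up of phantom scatter.  The fit is a
multi-start nonlinear least-squares; uncertainties on ratios are type A
(k = 1), from the scatter of repeated readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "OFFitParams",
    "ORRecord",
    "compare_fits",
    "corrected_output_factor",
    "fit_of_curve",
    "of_model",
    "output_ratio",
]

#: Deterministic multi-start grid for the nonlinear fit, spanning the
#: plausible half-saturation sizes and sigmoid sharpness.
_FIT_STARTS = ((2.0, 1.0), (5.0, 2.0), (10.0, 3.0), (2.0, 3.0), (10.0, 1.0))


@dataclass(frozen=True)
class ORRecord:
    """One output-ratio measurement (clinical vs msr field)."""

    field_size: float
    m_clin: float
    m_msr: float
    or_value: float
    uncertainty: float

    def __post_init__(self) -> None:
        if self.m_clin <= 0 or self.m_msr <= 0:
            raise ValueError("signals must be positive")


@dataclass(frozen=True)
class OFFitParams:
    """Parameters of the field-size response curve OF(s)."""

    p: float
    a: float
    b: float
    n: float

    def __call__(self, s) -> np.ndarray:
        return of_model(np.asarray(s, dtype=float), self.p, self.a, self.b,
                        self.n)


def of_model(s, p, a, b, n):
    """Saturating output-factor curve p*s^n/(a^n+s^n)*(1-exp(-b*s))."""
    s = np.asarray(s, dtype=float)
    return p * s**n / (a**n + s**n) * (1.0 - np.exp(-b * s))


def output_ratio(m_clin, m_msr, field_size: float = float("nan")) -> ORRecord:
    """Output ratio from signal-per-MU readings.

    Scalars give a bare ratio; arrays of repeated readings give the ratio of
    means with a type-A (k=1) uncertainty, combining the standard errors of
    the two means in quadrature.
    """
    m_clin = np.atleast_1d(np.asarray(m_clin, dtype=float))
    m_msr = np.atleast_1d(np.asarray(m_msr, dtype=float))
    if np.any(m_clin <= 0) or np.any(m_msr <= 0):
        raise ValueError("signals must be positive")
    ratio = float(m_clin.mean() / m_msr.mean())
    rel = 0.0
    for vals in (m_clin, m_msr):
        if vals.size > 1:
            rel += (vals.std(ddof=1) / np.sqrt(vals.size) / vals.mean()) ** 2
    return ORRecord(field_size=field_size, m_clin=float(m_clin.mean()),
                    m_msr=float(m_msr.mean()), or_value=ratio,
                    uncertainty=float(ratio * np.sqrt(rel)))


def corrected_output_factor(or_record: ORRecord | float,
                            k_total: float) -> float:
    """Output factor: detector output ratio times the total correction."""
    if k_total <= 0:
        raise ValueError("k_total must be positive")
    value = or_record.or_value if isinstance(or_record, ORRecord) else float(or_record)
    return value * k_total


def fit_of_curve(sizes, of_values) -> tuple[OFFitParams, dict]:
    """Fit the field-size response curve to measured output factors.

    Requires at least five points spanning the size range, with values in
    (0, 1.2].  Five deterministic starting points are tried and the lowest
    residual sum wins; the report carries per-point residuals and the
    maximum absolute residual.
    """
    sizes = np.asarray(sizes, dtype=float)
    of_values = np.asarray(of_values, dtype=float)
    if sizes.ndim != 1 or sizes.shape != of_values.shape:
        raise ValueError("sizes and of_values must be equal-length 1D")
    if sizes.size < 5:
        raise ValueError("need at least 5 field sizes to constrain the fit")
    if np.any(of_values <= 0) or np.any(of_values > 1.2):
        raise ValueError("output factors must lie in (0, 1.2]")

    def residual(theta):
        p, a, b, n = theta
        return of_model(sizes, p, a, b, n) - of_values

    best = None
    tried = []
    for a0, n0 in _FIT_STARTS:
        x0 = (float(of_values.max()), a0, 0.5, n0)
        tried.append(x0)
        try:
            sol = least_squares(residual, x0=x0,
                                bounds=([1e-6] * 4, [10.0, 50.0, 10.0, 10.0]),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"output-factor fit failed from all starts: {tried}")

    params = OFFitParams(*best.x)
    resid = residual(best.x)
    report = {
        "residuals": resid,
        "max_abs_residual": float(np.max(np.abs(resid))),
        "rms_residual": float(np.sqrt(np.mean(resid**2))),
        "starts_tried": tried,
    }
    return params, report


def compare_fits(params_a: OFFitParams, params_b: OFFitParams,
                 size_range: tuple[float, float] = (4.0, 25.0),
                 step: float = 0.1) -> float:
    """Maximum absolute difference between two fitted curves over a range."""
    lo, hi = size_range
    if not hi > lo > 0:
        raise ValueError("size range must be positive and increasing")
    grid = np.arange(lo, hi + step / 2, step)
    return float(np.max(np.abs(params_a(grid) - params_b(grid))))
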