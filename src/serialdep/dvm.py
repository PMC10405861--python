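"""The derivative-of-von-Mises (DvM) serial-bias curve and its readouts.

The response error on the current trial is modelled as a function of the
signed orientation distance x (previous minus current stimulus, degrees):

    y(x) = -a * kappa * sin(x') * exp(kappa * cos(x')) / (2 * pi * I0(kappa))

where x' = x * pi / 180 (degrees of distance map one-to-one onto degrees
of phase), ``a`` is a signed amplitude parameter, ``kappa`` >= 0 the
concentration, and ``I0`` the modified Bessel function of order zero.  The
symmetry axis mu is fixed at 0.  Signed distances between orientations
live in (-90, +90], so only the rising flank and peak region of each lobe
are ever evaluated; shallow (small-kappa) curves peak near +/-90 and do
not return to zero within the measured range.

Two behavioural readouts summarise a fitted curve:

* ``curve_amplitude`` -- half the peak-to-trough excursion, *signed so that
  attraction is positive* (response error pulled toward the previous
  stimulus, i.e. same sign as x at the peak) and repulsion negative.  Note
  the model formula carries a leading minus sign, so attractive curves have
  a < 0.
* ``curve_fwhm`` -- full width at half maximum of the positive-x lobe, or
  ``None`` when the curve is flat or so shallow that a half-maximum
  crossing would fall outside (0, 90) degrees (the width is then not
  computed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e

A_BOUNDS = (-15.0, 15.0)
KAPPA_BOUNDS = (0.0, 200.0)

#: distance-axis degrees -> radians
_DEG2RAD = math.pi / 180.0

__all__ = [
    "DvMParams",
    "A_BOUNDS",
    "KAPPA_BOUNDS",
    "dvm_value",
    "peak_location_deg",
    "curve_amplitude",
    "curve_fwhm",
    "params_from_amplitude_fwhm",
    "max_fwhm_for_amplitude",
    "max_amplitude_for_fwhm",
    "attainable_fwhm_range",
]


@dataclass(frozen=True)
class DvMParams:
    """Parameters of the DvM bias curve (mu is fixed at 0)."""

    a: float
    kappa: float
    mu: float = 0.0

    def __post_init__(self):
        if not (A_BOUNDS[0] <= self.a <= A_BOUNDS[1]):
            raise ValueError(f"a={self.a} outside {A_BOUNDS}")
        if not (KAPPA_BOUNDS[0] <= self.kappa <= KAPPA_BOUNDS[1]):
            raise ValueError(f"kappa={self.kappa} outside {KAPPA_BOUNDS}")
        if self.mu != 0.0:
            raise ValueError("mu is fixed at 0")


def dvm_value(x_deg, params: DvMParams):
    """Evaluate the DvM curve at signed distance(s) ``x_deg`` (degrees).

    Returns the predicted response error in degrees.  Numerically stable
    for the full kappa range: exp(k cos x)/I0(k) is computed as
    exp(k (cos x - 1))/i0e(k).
    """
    x = np.asarray(x_deg, dtype=float)
    xr = (x - params.mu) * _DEG2RAD
    k = params.kappa
    y = (
        -(params.a * k / (2.0 * math.pi))
        * np.sin(xr)
        * np.exp(k * (np.cos(xr) - 1.0))
        / i0e(k)
    )
    return y if y.ndim else float(y)


def peak_location_deg(kappa: float) -> float:
    """Location (degrees, in (0, 90]) of the positive-x extremum.

    Setting d/dx [sin x exp(k cos x)] = 0 gives
    cos x = (-1 + sqrt(1 + 4 k^2)) / (2 k), solved in closed form; the
    kappa -> 0 limit is a pure sine peaking at 90 degrees.
    """
    if kappa <= 0.0:
        return 90.0
    c = (-1.0 + math.sqrt(1.0 + 4.0 * kappa * kappa)) / (2.0 * kappa)
    return math.degrees(math.acos(min(c, 1.0)))


def curve_amplitude(params: DvMParams) -> float:
    """Half the peak-to-trough amplitude of the curve, in degrees.

    Signed behaviourally: positive when the curve is attractive (same sign
    as x at its positive-x extremum), negative when repulsive.  The curve is
    odd about mu=0, so this equals the curve value at its positive-x peak.
    """
    if params.a == 0.0 or params.kappa == 0.0:
        return 0.0
    xp = params.mu + peak_location_deg(params.kappa)
    return float(dvm_value(xp, params))


def curve_fwhm(params: DvMParams, tol: float = 1e-10):
    """Full width at half maximum of the positive-x lobe, in degrees.

    Returns ``None`` when the amplitude is zero or when either half-maximum
    crossing falls outside (0, 90) degrees -- shallow, small-kappa curves
    peak so close to 90 that the descending crossing lies beyond the
    measurable distance range and the width is not computed.  Crossings are
    located by bisection to well below 0.1 degrees.
    """
    amp = curve_amplitude(params)
    if amp == 0.0 or not math.isfinite(amp):
        return None
    xp = params.mu + peak_location_deg(params.kappa)
    half = abs(amp) / 2.0

    def f(x):
        return abs(dvm_value(x, params)) - half

    lo_a, lo_b = params.mu + tol, xp
    hi_a, hi_b = xp, params.mu + 90.0 - tol
    if xp >= 90.0 - tol or f(lo_a) >= 0.0 or f(hi_b) >= 0.0:
        # a crossing would fall outside (0, 90): width not computed
        return None
    lo = brentq(f, lo_a, lo_b, xtol=1e-9)
    hi = brentq(f, hi_a, hi_b, xtol=1e-9)
    return float(hi - lo)


def _unit_attractive(kappa: float) -> DvMParams:
    """Attraction-positive curve with |a| = 1 (a = -1 under the sign of the
    model formula)."""
    return DvMParams(a=-1.0, kappa=kappa)


_KAPPA_FWHM_DEFINED = None  # lazily computed definability boundary


def _kappa_fwhm_defined() -> float:
    """Smallest kappa whose FWHM is defined (descending half-maximum
    crossing inside (0, 90))."""
    global _KAPPA_FWHM_DEFINED
    if _KAPPA_FWHM_DEFINED is None:
        lo, hi = 1e-6, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if curve_fwhm(_unit_attractive(mid)) is None:
                lo = mid
            else:
                hi = mid
        _KAPPA_FWHM_DEFINED = hi
    return _KAPPA_FWHM_DEFINED


def attainable_fwhm_range() -> tuple[float, float]:
    """(narrowest, widest) FWHM attainable with kappa in (0, 200]."""
    return (
        curve_fwhm(_unit_attractive(KAPPA_BOUNDS[1])),
        curve_fwhm(_unit_attractive(_kappa_fwhm_defined())),
    )


def params_from_amplitude_fwhm(
    amplitude_deg: float, fwhm_deg: float, tol: float = 1e-6
) -> DvMParams:
    """Invert the readouts: parameters whose curve has the requested signed
    amplitude and FWHM.

    For amplitude 0 the width is moot and kappa = 1 is returned by
    convention.  Raises ``ValueError`` when the width is unattainable
    within kappa in [0, 200] or when the implied |a| exceeds 15.
    """
    if amplitude_deg == 0.0:
        return DvMParams(a=0.0, kappa=1.0)
    w_narrowest, w_widest = attainable_fwhm_range()
    if not (w_narrowest <= fwhm_deg <= w_widest):
        raise ValueError(
            f"FWHM {fwhm_deg} deg unattainable within kappa bounds "
            f"(range [{w_narrowest:.2f}, {w_widest:.2f}] deg)"
        )
    kappa = brentq(
        lambda k: curve_fwhm(_unit_attractive(k)) - fwhm_deg,
        _kappa_fwhm_defined(),
        KAPPA_BOUNDS[1],
        xtol=tol,
    )
    unit_amp = curve_amplitude(_unit_attractive(kappa))  # > 0
    a = -amplitude_deg / unit_amp
    if not (A_BOUNDS[0] <= a <= A_BOUNDS[1]):
        raise ValueError(
            f"amplitude {amplitude_deg} deg at FWHM {fwhm_deg} deg implies "
            f"a={a:.2f} outside {A_BOUNDS}"
        )
    return DvMParams(a=a, kappa=kappa)


def max_fwhm_for_amplitude(amplitude_deg: float) -> float:
    """Largest FWHM representable together with ``amplitude_deg`` under the
    |a| <= 15 bound.

    Wide curves (small kappa) have small per-unit-|a| peaks, so a given
    amplitude caps the attainable width: peak height is |a| times the
    unit-curve peak, which shrinks as the curve broadens.
    """
    k_def = _kappa_fwhm_defined()
    k_hi = KAPPA_BOUNDS[1]
    need = abs(amplitude_deg) / A_BOUNDS[1]
    if need <= curve_amplitude(_unit_attractive(k_def)):
        return attainable_fwhm_range()[1]
    if need > curve_amplitude(_unit_attractive(k_hi)):
        raise ValueError(f"amplitude {amplitude_deg} deg unattainable at any width")
    k_min = brentq(
        lambda k: curve_amplitude(_unit_attractive(k)) - need, k_def, k_hi, xtol=1e-9
    )
    return curve_fwhm(_unit_attractive(k_min))


def max_amplitude_for_fwhm(fwhm_deg: float) -> float:
    """Largest |amplitude| representable at width ``fwhm_deg`` under the
    |a| <= 15 bound (the unit-curve peak at that width, scaled by 15)."""
    kappa = brentq(
        lambda k: curve_fwhm(_unit_attractive(k)) - fwhm_deg,
        _kappa_fwhm_defined(),
        KAPPA_BOUNDS[1],
        xtol=1e-9,
    )
    return A_BOUNDS[1] * curve_amplitude(_unit_attractive(kappa))
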