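"""Angle arithmetic on the 180-degree-periodic orientation space.

Orientations (e.g. of a Gabor grating) live on a half-circle: theta and
theta + 180 are the same physical stimulus.  All statistics are therefore
computed on *doubled* angles (the standard axial-data treatment): multiply
by two, work on the full circle, halve the result.  Signed distances
between orientations live in (-90, +90], with positive values denoting a
clockwise displacement.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "wrap_signed",
    "signed_diff",
    "circ_mean",
    "circ_sd",
    "circ_dist",
]


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap_orientation(theta):
    """Wrap angles (degrees) into the orientation space [0, 180).

    Accepts scalars or arrays; raises ``ValueError`` on non-finite input.
    """
    theta = np.asarray(theta, dtype=float)
    _check_finite(theta, "theta")
    out = np.mod(theta, 180.0)
    # guard against -1e-16 % 180 -> 180.0 on some platforms
    out = np.where(out >= 180.0, out - 180.0, out)
    return out if out.ndim else float(out)


def wrap_signed(delta):
    """Wrap signed angular differences (degrees) into (-90, +90].

    ``delta`` and ``delta - 180`` denote the same physical relation between
    two orientations; the representative with magnitude <= 90 is returned,
    with the +90 convention at the boundary.
    """
    delta = np.asarray(delta, dtype=float)
    _check_finite(delta, "delta")
    d = np.mod(delta, 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    return d if d.ndim else float(d)


def signed_diff(theta_a, theta_b):
    """Signed circular difference ``theta_a - theta_b`` in (-90, +90] degrees.

    Positive values mean ``theta_a`` is clockwise of ``theta_b``.
    """
    a = np.asarray(theta_a, dtype=float)
    b = np.asarray(theta_b, dtype=float)
    _check_finite(a, "theta_a")
    _check_finite(b, "theta_b")
    return wrap_signed(a - b)


def _resultant(values: np.ndarray):
    """Mean resultant (C, S, R) of doubled angles given signed degrees."""
    t = np.deg2rad(2.0 * values)
    c = float(np.mean(np.cos(t)))
    s = float(np.mean(np.sin(t)))
    return c, s, float(np.hypot(c, s))


def circ_mean(values) -> float:
    """Circular mean of signed orientation differences, in (-90, +90] degrees.

    Computed on the doubled-angle circle and halved back.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("circ_mean of an empty collection is undefined")
    _check_finite(values, "values")
    c, s, _ = _resultant(values)
    return wrap_signed(np.rad2deg(np.arctan2(s, c)) / 2.0)


def circ_sd(values) -> float:
    """Circular standard deviation sqrt(-2 ln R), in orientation degrees.

    ``R`` is the mean resultant length of the doubled angles; the doubled-
    circle SD is halved back to orientation units.  Returns ``inf`` when the
    resultant vanishes.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("circ_sd of an empty collection is undefined")
    _check_finite(values, "values")
    _, _, r = _resultant(values)
    if r <= 0.0:
        return float("inf")
    r = min(r, 1.0)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))) / 2.0)


def circ_dist(x, y):
    """Signed circular difference ``x - y`` between two signed distances,
    wrapped to (-90, +90] degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return wrap_signed(x - y)
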