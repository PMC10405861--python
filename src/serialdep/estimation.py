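"""Serial-dependence estimators: DvM fits, resampling inference, model-free bias.

Two estimation levels mirror how such data are analysed:

* group level -- the DvM curve is fit by least squares to the *pooled* raw
  trials (distance, residual error) of many observers;
* subject level -- single-observer data are first reduced to a moving-
  average bias curve (20-degree window, 1-degree steps) and the DvM is fit
  to the defined curve points.

Because the DvM is linear in its amplitude parameter, the least-squares
problem is profiled: for every concentration kappa the optimal amplitude
is closed-form (clipped to the [-15, 15] bound), leaving a one-dimensional
search over kappa on a dense log-spaced grid followed by bounded scalar
refinement.  Ties resolve to the lowest SSE, then the smallest kappa.

Moving-average smoothing attenuates a narrow bias curve (the 20-degree
window smears the peak), so at the subject level the *model predictions
are passed through the identical smoothing operator* before comparison
with the smoothed data: the fit minimises the distance between the
smoothed curve and the smoothed DvM, and the reported amplitude and FWHM
describe the underlying (unsmoothed) curve.  This makes noiseless
parameter recovery exact and removes the attenuation bias that a direct
fit to smoothed points would inherit.  Smoothed points are weighted by
their window counts (inverse-variance weighting: a window mean of n
trials has variance sigma^2/n), which recovers most of the efficiency of
a fit to the raw trials.

Significance comes from permutation tests that shuffle the pairing of
angular distances and response errors and re-run the *entire* pipeline
(re-smoothing included) on each permutation; amplitude variability from
bootstrap resampling of trials.  The model-free estimator contrasts the
circular mean error after clockwise versus counterclockwise previous
stimuli within a distance range L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .circular import circ_mean, wrap_signed
from .dvm import (
    A_BOUNDS,
    KAPPA_BOUNDS,
    DvMParams,
    curve_amplitude,
    curve_fwhm,
    dvm_value,
)

logger = logging.getLogger(__name__)

#: distance grid (degrees) on which moving-average curves are evaluated
X_GRID = np.arange(-90.0, 91.0, 1.0)
DEFAULT_WINDOW_DEG = 20.0

_KAPPA_GRID = np.concatenate(([0.0], np.geomspace(0.05, KAPPA_BOUNDS[1], 120)))
_DEG2RAD = math.pi / 180.0

__all__ = [
    "BiasCurve",
    "DvMFitResult",
    "ModelFreeBias",
    "X_GRID",
    "moving_average_curve",
    "fit_dvm",
    "estimate_bias",
    "permutation_test",
    "bootstrap_sd",
    "estimate_with_inference",
    "model_free_bias",
    "model_free_permutation",
    "range_covering_area",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class BiasCurve:
    """Moving-average response-error curve on the distance grid."""

    x_grid: np.ndarray
    y_smooth: np.ndarray  # NaN where no trial falls in the window
    n_per_point: np.ndarray
    window_deg: float = DEFAULT_WINDOW_DEG


@dataclass
class DvMFitResult:
    """One DvM fit with its readouts and (optional) inference."""

    params: DvMParams
    amplitude_deg: float
    fwhm_deg: float | None
    r2: float
    n_trials: int
    fit_mode: str
    p_perm: float | None = None
    boot_sd: float | None = None

    def to_dict(self) -> dict:
        return {
            "a": self.params.a,
            "kappa": self.params.kappa,
            "mu": self.params.mu,
            "amplitude_deg": self.amplitude_deg,
            "fwhm_deg": self.fwhm_deg,
            "r2": None if not math.isfinite(self.r2) else self.r2,
            "n_trials": self.n_trials,
            "fit_mode": self.fit_mode,
            "p_perm": self.p_perm,
            "boot_sd": self.boot_sd,
        }


@dataclass
class ModelFreeBias:
    """Model-free bias: circular mean error after clockwise minus after
    counterclockwise previous stimuli within |distance| <= range_deg."""

    range_deg: float
    bias_deg: float
    n_cw: int
    n_ccw: int
    p_perm: float | None = None

    def to_dict(self) -> dict:
        return {
            "range_deg": self.range_deg,
            "bias_deg": self.bias_deg,
            "n_cw": self.n_cw,
            "n_ccw": self.n_ccw,
            "p_perm": self.p_perm,
        }


# ---------------------------------------------------------------------------
# smoothing


def _window_matrix(distances: np.ndarray, x_grid: np.ndarray, half: float):
    """Boolean (grid x trial) membership: distance within half a window of
    the grid point, wrapping the distance axis with period 180."""
    delta = np.mod(distances[None, :] - x_grid[:, None] + 90.0, 180.0) - 90.0
    return np.abs(delta) <= half


def _smooth(member_f: np.ndarray, errors: np.ndarray):
    """Windowed circular mean (doubled angles) given a float membership
    matrix; returns (y, counts) with NaN where the window is empty."""
    t = np.deg2rad(2.0 * errors)
    s = member_f @ np.sin(t)
    c = member_f @ np.cos(t)
    cnt = member_f.sum(axis=1)
    with np.errstate(invalid="ignore"):
        y = np.rad2deg(np.arctan2(s, c)) / 2.0
    y = np.where(cnt > 0, y, np.nan)
    return y, cnt


def moving_average_curve(
    distances, errors, window: float = DEFAULT_WINDOW_DEG
) -> BiasCurve:
    """Moving-average bias curve: at each grid point x, the circular mean of
    errors whose distance lies within [x - w/2, x + w/2] (axis wrapped with
    period 180).  Points with no data are NaN."""
    d = np.asarray(distances, dtype=float)
    e = np.asarray(errors, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one trial")
    member = _window_matrix(d, X_GRID, window / 2.0).astype(float)
    y, cnt = _smooth(member, e)
    return BiasCurve(
        x_grid=X_GRID.copy(), y_smooth=y, n_per_point=cnt, window_deg=window
    )


# ---------------------------------------------------------------------------
# profiled DvM least squares


def _basis_vec(x: np.ndarray, kappa: float) -> np.ndarray:
    """Unit-amplitude attraction-positive DvM shape (the curve for a = -1)."""
    if kappa <= 0.0:
        return np.zeros_like(x)
    xr = x * _DEG2RAD
    from scipy.special import i0e

    return (kappa / (2.0 * math.pi)) * np.sin(xr) * np.exp(
        kappa * (np.cos(xr) - 1.0)
    ) / i0e(kappa)


def _boxcar_basis_vec(x: np.ndarray, kappa: float, window: float) -> np.ndarray:
    """Analytic moving-window average of the unit attraction-positive curve.

    The antiderivative of the DvM is an exponential, and since the curve is
    odd its integral over one 180-degree distance period vanishes, so
    windows that cross +/-90 are handled simply by wrapping the window
    endpoints onto (-90, 90] before evaluating the antiderivative.
    """
    if kappa <= 0.0:
        return np.zeros_like(x)
    from scipy.special import i0e

    h = window / 2.0

    def f(u):
        uw = np.mod(u + 90.0, 180.0) - 90.0  # wrap endpoint onto the period
        return np.exp(kappa * (np.cos(uw * _DEG2RAD) - 1.0))

    return (f(x - h) - f(x + h)) / (2.0 * math.pi * _DEG2RAD * i0e(kappa) * window)


def _basis_matrix(x: np.ndarray) -> np.ndarray:
    return np.vstack([_basis_vec(x, k) for k in _KAPPA_GRID])


def _profiled_fit(B, bb, basis_fn, y):
    """Minimise SSE over (amplitude, kappa) with amplitude profiled out.

    ``B`` is the basis matrix over the kappa grid, ``bb`` the per-row basis
    energies, ``basis_fn(kappa)`` the basis vector used during refinement.
    Returns (amplitude, kappa, sse).  Amplitude is the attraction-positive
    model amplitude, i.e. -a.
    """
    yy = float(y @ y)
    num = B @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = np.where(bb > 0, num / np.where(bb > 0, bb, 1.0), 0.0)
    amp = np.clip(amp, A_BOUNDS[0], A_BOUNDS[1])
    sse = yy - 2.0 * amp * num + amp * amp * bb
    i = int(np.argmin(sse))
    best_amp, best_k, best_sse = float(amp[i]), float(_KAPPA_GRID[i]), float(sse[i])

    lo = _KAPPA_GRID[i - 1] if i > 0 else 0.0
    hi = _KAPPA_GRID[i + 1] if i + 1 < len(_KAPPA_GRID) else KAPPA_BOUNDS[1]

    def sse_at(k: float) -> float:
        b = basis_fn(k)
        bb1 = float(b @ b)
        if bb1 <= 0.0:
            return yy
        n1 = float(b @ y)
        a1 = min(max(n1 / bb1, A_BOUNDS[0]), A_BOUNDS[1])
        return yy - 2.0 * a1 * n1 + a1 * a1 * bb1

    if hi > lo:
        res = minimize_scalar(
            sse_at, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8 * (1 + hi)}
        )
        if res.fun < best_sse:
            k = float(res.x)
            b = basis_fn(k)
            bb1 = float(b @ b)
            a1 = 0.0 if bb1 <= 0 else min(max(float(b @ y) / bb1, A_BOUNDS[0]), A_BOUNDS[1])
            best_amp, best_k, best_sse = a1, k, float(res.fun)
    return best_amp, best_k, best_sse


def _result_from(amp, kappa, sse, y, n_trials, fit_mode, weights=None) -> DvMFitResult:
    params = DvMParams(a=-amp, kappa=kappa)
    if weights is None:
        sstot = float(np.sum((y - np.mean(y)) ** 2))
    else:
        ybar = float(np.sum(weights * y) / np.sum(weights))
        sstot = float(np.sum(weights * (y - ybar) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else float("nan")
    return DvMFitResult(
        params=params,
        amplitude_deg=curve_amplitude(params),
        fwhm_deg=curve_fwhm(params),
        r2=r2,
        n_trials=n_trials,
        fit_mode=fit_mode,
    )


def fit_dvm(
    x_values,
    y_values,
    fit_mode: str = "pooled",
    window: float = DEFAULT_WINDOW_DEG,
) -> DvMFitResult:
    """Least-squares DvM fit to (x, y) points (degrees).

    ``fit_mode="pooled"`` fits the curve directly to raw trial points.
    ``fit_mode="moving_average"`` treats the points as values of a
    ``window``-degree moving average and fits the analytically
    window-averaged curve, so the returned parameters describe the
    underlying (unsmoothed) bias.  NaN points are dropped; at least 10
    defined points are required.  Constant y (zero variance) yields the
    degenerate flat fit (a = 0, undefined r2).
    """
    if fit_mode not in ("pooled", "moving_average"):
        raise ValueError("fit_mode must be 'pooled' or 'moving_average'")
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError(f"need at least 10 defined points, got {x.size}")
    if np.ptp(y) == 0.0:
        params = DvMParams(a=0.0, kappa=1.0)
        return DvMFitResult(
            params=params,
            amplitude_deg=0.0,
            fwhm_deg=None,
            r2=float("nan"),
            n_trials=int(x.size),
            fit_mode=fit_mode,
        )
    if fit_mode == "moving_average":
        def basis_fn(k, x=x):
            return _boxcar_basis_vec(x, k, window)

        B = np.vstack([basis_fn(k) for k in _KAPPA_GRID])
    else:
        def basis_fn(k, x=x):
            return _basis_vec(x, k)

        B = _basis_matrix(x)
    bb = np.einsum("km,km->k", B, B)
    amp, kappa, sse = _profiled_fit(B, bb, basis_fn, y)
    return _result_from(amp, kappa, sse, y, int(x.size), fit_mode)


# ---------------------------------------------------------------------------
# pipeline engine (shared by point estimates, permutations, bootstrap)


class _FitEngine:
    """Precomputed machinery to refit the full pipeline many times on the
    same distance multiset (permutations) or resamples of it (bootstrap)."""

    def __init__(self, distances, errors, level: str, window: float = DEFAULT_WINDOW_DEG):
        if level not in ("group", "subject"):
            raise ValueError("level must be 'group' or 'subject'")
        self.level = level
        self.d = np.asarray(distances, dtype=float)
        self.e = np.asarray(errors, dtype=float)
        if self.d.size != self.e.size or self.d.size == 0:
            raise ValueError("distances and errors must be equal-length, non-empty")
        if level == "subject":
            member = _window_matrix(self.d, X_GRID, window / 2.0)
            cnt = member.sum(axis=1)
            self.mask = cnt > 0
            self.member_f = member[self.mask].astype(float)
            self.x = X_GRID[self.mask]
            # model predictions go through the same smoothing operator as
            # the data: smoothed basis = row-normalised membership @ raw basis
            self._N = self.member_f / self.member_f.sum(axis=1, keepdims=True)
            self._B_raw = _basis_matrix(self.d)
            # window means are weighted by their trial counts (a mean of n
            # trials has variance sigma^2/n); weights enter as sqrt scaling
            self.weights = cnt[self.mask].astype(float)
            self._sw = np.sqrt(self.weights)
            self.B = (self._B_raw @ self._N.T) * self._sw[None, :]
            self.basis_fn = lambda k: (self._N @ _basis_vec(self.d, k)) * self._sw
        else:
            self.x = self.d
            self.weights = None
            self._sw = None
            self.B = _basis_matrix(self.x)
            self.basis_fn = lambda k: _basis_vec(self.x, k)
        self.bb = np.einsum("km,km->k", self.B, self.B)

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    def _y_of(self, errors: np.ndarray) -> np.ndarray:
        if self.level == "subject":
            y, _ = _smooth(self.member_f, errors)
            return y
        return errors

    def fit(self, errors: np.ndarray | None = None):
        """Full-pipeline fit; returns (amplitude, kappa, sse, y)."""
        e = self.e if errors is None else errors
        y = self._y_of(e)
        ys = y if self._sw is None else y * self._sw
        amp, kappa, sse = _profiled_fit(self.B, self.bb, self.basis_fn, ys)
        return amp, kappa, sse, y

    def amplitude(self, errors: np.ndarray | None = None) -> float:
        amp, kappa, _, _ = self.fit(errors)
        return curve_amplitude(DvMParams(a=-amp, kappa=kappa))

    def fit_indices(self, idx: np.ndarray):
        """Pipeline fit on a bootstrap resample of trials (with replacement)."""
        e = self.e[idx]
        d = self.d[idx]
        if self.level == "subject":
            member = self.member_f[:, idx]
            cnt = member.sum(axis=1)
            rows = cnt > 0
            y, _ = _smooth(member[rows], e)
            n_sub = member[rows] / cnt[rows, None]
            sw = np.sqrt(cnt[rows])
            b_raw = self._B_raw[:, idx]
            B = (b_raw @ n_sub.T) * sw[None, :]
            y = y * sw
            basis_fn = lambda k: (n_sub @ _basis_vec(d, k)) * sw  # noqa: E731
        else:
            B = self.B[:, idx]
            y = e
            basis_fn = lambda k: _basis_vec(d, k)  # noqa: E731
        bb = np.einsum("km,km->k", B, B)
        amp, kappa, _ = _profiled_fit(B, bb, basis_fn, y)
        return curve_amplitude(DvMParams(a=-amp, kappa=kappa))


def estimate_bias(distances, errors, level: str = "subject",
                  window: float = DEFAULT_WINDOW_DEG) -> DvMFitResult:
    """Point estimate of serial dependence at the requested level.

    Group level fits pooled raw trials; subject level fits the moving-
    average curve.  ``n_trials`` always counts raw trials.
    """
    engine = _FitEngine(distances, errors, level, window)
    if engine.n_points < 10:
        raise ValueError("fewer than 10 defined points to fit")
    amp, kappa, sse, y = engine.fit()
    return _result_from(
        amp, kappa, sse, y, int(engine.d.size), level_to_mode(level),
        weights=engine.weights,
    )


def level_to_mode(level: str) -> str:
    return "moving_average" if level == "subject" else "pooled"


def permutation_test(
    distances,
    errors,
    level: str = "subject",
    n_perm: int = 1000,
    sided: str = "two",
    seed: int | None = None,
    window: float = DEFAULT_WINDOW_DEG,
    return_distribution: bool = False,
):
    """Permutation p-value for the fitted amplitude.

    The pairing of distances and errors is shuffled ``n_perm`` times and
    the full pipeline (smoothing at subject level, then fitting) is re-run
    on each shuffle.  One-sided: proportion of permuted amplitudes >= the
    observed amplitude (positive serial dependence expected); two-sided:
    proportion with |permuted| >= |observed|.  Ties count as extreme; the
    p-value is the plain proportion without a +1 correction.
    """
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    engine = _FitEngine(distances, errors, level, window)
    observed = engine.amplitude()
    perm_amp = np.empty(n_perm)
    for i in range(n_perm):
        perm_amp[i] = engine.amplitude(rng.permutation(engine.e))
    if sided == "one":
        p = float(np.mean(perm_amp >= observed))
    else:
        p = float(np.mean(np.abs(perm_amp) >= abs(observed)))
    if return_distribution:
        return p, observed, perm_amp
    return p


def bootstrap_sd(
    distances,
    errors,
    level: str = "group",
    n_boot: int = 1000,
    seed: int | None = None,
    window: float = DEFAULT_WINDOW_DEG,
) -> float:
    """SD of the fitted amplitude over ``n_boot`` resamples of the trials
    (drawn with replacement), running the full pipeline on each."""
    engine = _FitEngine(distances, errors, level, window)
    n = engine.e.size
    if n < 10:
        raise ValueError("need at least 10 trials to bootstrap")
    rng = np.random.default_rng(seed)
    amps = np.empty(n_boot)
    for i in range(n_boot):
        amps[i] = engine.fit_indices(rng.integers(0, n, size=n))
    return float(np.std(amps, ddof=1))


def estimate_with_inference(
    distances,
    errors,
    level: str = "subject",
    n_perm: int = 1000,
    n_boot: int = 0,
    sided: str | None = None,
    seed: int | None = None,
    window: float = DEFAULT_WINDOW_DEG,
) -> DvMFitResult:
    """Point estimate plus permutation p-value and optional bootstrap SD.

    The sidedness defaults to the convention of the analysis level:
    one-sided at the group level (attraction expected), two-sided at the
    subject level (either direction possible).
    """
    if sided is None:
        sided = "one" if level == "group" else "two"
    rng = np.random.default_rng(seed)
    result = estimate_bias(distances, errors, level, window)
    result.p_perm = permutation_test(
        distances, errors, level, n_perm=n_perm, sided=sided,
        seed=int(rng.integers(2**31)), window=window,
    )
    if n_boot:
        result.boot_sd = bootstrap_sd(
            distances, errors, level, n_boot=n_boot,
            seed=int(rng.integers(2**31)), window=window,
        )
    return result


# ---------------------------------------------------------------------------
# model-free estimator


def model_free_bias(distances, errors, range_deg: float) -> ModelFreeBias:
    """Circular mean error after clockwise (0 < d <= L) minus after
    counterclockwise (-L <= d < 0) previous stimuli; positive = attraction.
    Distance exactly 0 has no sign and joins neither bin."""
    if not 0.0 < range_deg <= 90.0:
        raise ValueError("range_deg must lie in (0, 90]")
    d = np.asarray(distances, dtype=float)
    e = np.asarray(errors, dtype=float)
    cw = (d > 0.0) & (d <= range_deg)
    ccw = (d < 0.0) & (d >= -range_deg)
    if not cw.any() or not ccw.any():
        raise ValueError("no trials on one side of the distance range")
    bias = wrap_signed(circ_mean(e[cw]) - circ_mean(e[ccw]))
    return ModelFreeBias(
        range_deg=range_deg, bias_deg=float(bias),
        n_cw=int(cw.sum()), n_ccw=int(ccw.sum()),
    )


def model_free_permutation(
    distances, errors, range_deg: float, n_perm: int = 1000, seed: int | None = None
) -> float:
    """Two-sided permutation p-value for the model-free bias, built by
    shuffling the clockwise/counterclockwise bin labels across the
    included trials."""
    d = np.asarray(distances, dtype=float)
    e = np.asarray(errors, dtype=float)
    observed = model_free_bias(d, e, range_deg)
    inc = (d != 0.0) & (np.abs(d) <= range_deg)
    e_inc = e[inc]
    n_cw = observed.n_cw
    rng = np.random.default_rng(seed)
    t = np.deg2rad(2.0 * e_inc)
    sin_t, cos_t = np.sin(t), np.cos(t)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(e_inc.size)
        cw_idx, ccw_idx = idx[:n_cw], idx[n_cw:]
        m_cw = np.rad2deg(
            np.arctan2(sin_t[cw_idx].mean(), cos_t[cw_idx].mean())
        ) / 2.0
        m_ccw = np.rad2deg(
            np.arctan2(sin_t[ccw_idx].mean(), cos_t[ccw_idx].mean())
        ) / 2.0
        perm[i] = wrap_signed(m_cw - m_ccw)
    return float(np.mean(np.abs(perm) >= abs(observed.bias_deg)))


def range_covering_area(params: DvMParams, fraction: float = 0.998) -> float:
    """Smallest L such that [0, L] covers ``fraction`` of the area under the
    positive lobe of |curve| on [0, 90] degrees.  Used to choose the
    model-free distance range from a fitted group curve."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if curve_amplitude(params) == 0.0:
        raise ValueError("flat curve has no defined area range")
    x = np.linspace(0.0, 90.0, 9001)
    y = np.abs(dvm_value(x, params))
    cum = np.concatenate(([0.0], np.cumsum((y[1:] + y[:-1]) / 2.0 * np.diff(x))))
    target = fraction * cum[-1]
    return float(x[int(np.searchsorted(cum, target))])
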