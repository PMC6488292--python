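"""Light-controlled ligand dissociation kinetics of the LOV2/Zdk photoswitch.

The ligand (Zdk) can dissociate directly from the dark, high-affinity state of
LOV2 (rate ``k3``) or rapidly dissociate after a blue-light-driven conformational
change of LOV2.  Photoexcitation occurs at a rate proportional to the blue-light
intensity ``nu`` (rate ``k1 * nu``) and is followed by dissociation from the lit
state at rate ``k2``.  The apparent dissociation rate constant is then

    k_obs(nu) = k1*nu * k2 / (k1*nu + k2) + k3

which rises from ``k3`` in the dark and saturates at ``k2 + k3`` under strong
illumination.  The enforced ligand binding half-life a cell experiences is
``tau = ln(2) / k_obs``.

This module fits single-exponential decays to dissociation traces, fits the
two-step photokinetic model to ``(intensity, k_obs)`` measurements, and converts
blue-light intensity (or LED voltage, via a measured calibration curve) into an
enforced binding half-life.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import FitConvergenceError

__all__ = [
    "DissociationTrace",
    "RateEstimate",
    "PhotoKineticParams",
    "IntensityCalibration",
    "ExponentialDecayModel",
    "PhotoKineticModel",
    "predict_kobs",
    "fit_decay_trace",
    "fit_photokinetic_params",
    "halflife_from_intensity",
    "default_photokinetics",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DissociationTrace:
    """A fluorescence dissociation time course with illumination metadata.

    Attributes
    ----------
    times : array of float
        Acquisition times in seconds, strictly increasing.
    fluorescence : array of float
        Fluorescence in arbitrary units, same length as ``times``.
    illumination_onset_index : int
        Index of the first frame acquired after the blue LED turned on.
    intensity : float
        Blue-light intensity in uW/cm^2.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    illumination_onset_index: int
    intensity: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and fluorescence must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not (0 <= self.illumination_onset_index < t.size):
            raise ValueError(
                f"illumination_onset_index {self.illumination_onset_index} out of range"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", y)


@dataclass(frozen=True)
class RateEstimate:
    """An apparent dissociation rate constant with its standard error."""

    kobs: float
    stderr: float
    n_points: int
    flagged: bool = False  # set when the fitted decay was non-identifiable/non-decaying


@dataclass(frozen=True)
class PhotoKineticParams:
    """Rate constants of the two-step light-dependent unbinding scheme.

    ``k1`` is per (uW/cm^2 * s), ``k2`` and ``k3`` per second.  ``covariance``
    is the 3x3 covariance of ``(k1, k2, k3)`` from the fit (zeros when the
    parameters were specified rather than fitted).
    """

    k1: float
    k2: float
    k3: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.k3 > 0):
            raise ValueError("k1, k2, k3 must all be strictly positive")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "covariance", cov)


@dataclass(frozen=True)
class IntensityCalibration:
    """Measured LED voltage -> blue-light intensity calibration points.

    The LED is non-linear at low voltages, so conversion uses monotone
    piecewise-linear interpolation and refuses to extrapolate.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(v), float(i)) for v, i in self.points)
        if len(pts) < 2:
            raise ValueError("calibration needs at least 2 points")
        volts = np.array([p[0] for p in pts])
        intens = np.array([p[1] for p in pts])
        if not np.all(np.diff(volts) > 0):
            raise ValueError("calibration voltages must be strictly increasing")
        if not np.all(np.diff(intens) >= 0):
            raise ValueError("calibration intensities must be non-decreasing in voltage")
        object.__setattr__(self, "points", pts)

    def to_intensity(self, voltage: float) -> float:
        volts = np.array([p[0] for p in self.points])
        intens = np.array([p[1] for p in self.points])
        if voltage < volts[0] or voltage > volts[-1]:
            raise ValueError(
                f"voltage {voltage} outside calibration range "
                f"[{volts[0]}, {volts[-1]}]; extrapolation refused"
            )
        return float(np.interp(voltage, volts, intens))


def default_photokinetics() -> PhotoKineticParams:
    """Photokinetic parameters anchored to the tunable half-life range.

    The dark-state half-life is 10 s (``k3 = ln2/10``), the fully lit limit is
    0.5 s (``k2 + k3 = ln2/0.5``), and the photoexcitation rate ``k1`` places
    half-saturation of the light-dependent term at 2 uW/cm^2 — well below the
    16 uW/cm^2 maximum exposure, so that the top of the intensity program is
    effectively saturating.
    """
    k3 = LN2 / 10.0
    k2 = LN2 / 0.5 - k3
    k1 = k2 / 2.0
    return PhotoKineticParams(k1=k1, k2=k2, k3=k3)


def predict_kobs(params: PhotoKineticParams, intensity: float | np.ndarray) -> float | np.ndarray:
    """Apparent dissociation rate constant at a given blue-light intensity.

    Monotone non-decreasing in intensity, bounded in ``[k3, k2 + k3)``.
    """
    nu = np.asarray(intensity, dtype=float)
    if np.any(nu < 0):
        raise ValueError("intensity must be non-negative")
    k1nu = params.k1 * nu
    out = k1nu * params.k2 / (k1nu + params.k2) + params.k3
    # k1*nu = 0 gives 0/0-free 0 numerator; guard anyway for nu = 0 arrays
    out = np.where(nu == 0, params.k3, out)
    return float(out) if np.isscalar(intensity) or np.ndim(intensity) == 0 else out


def _decay(t: np.ndarray, kobs: float, y0: float, plateau: float) -> np.ndarray:
    return plateau + (y0 - plateau) * np.exp(-kobs * t)


class ExponentialDecayModel(RegressorMixin, BaseEstimator):
    """Single-exponential decay fit ``y(t) = p + (y0 - p) * exp(-kobs * t)``.

    Parameters
    ----------
    fit_plateau : bool, default True
        Fit a free plateau (incomplete washout); if False the plateau is fixed
        at zero.

    Attributes
    ----------
    kobs_ : float
        Fitted decay rate constant (1/s).
    stderr_ : float
        Standard error of ``kobs_`` from the fit covariance.
    y0_, plateau_ : float
        Fitted initial value and plateau.
    flagged_ : bool
        True when the fit was degenerate (zero amplitude) or non-decaying.
    """

    def __init__(self, fit_plateau: bool = True):
        self.fit_plateau = fit_plateau

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        yy = np.asarray(y, dtype=float).reshape(-1)
        if t.size != yy.size:
            raise ValueError("X and y must have the same length")
        if t.size < 5:
            raise ValueError(f"need at least 5 post-onset frames, got {t.size}")
        t0 = t[0]
        ts = t - t0

        amp0 = yy[0] - yy[-1]
        span = float(np.ptp(yy))
        if span == 0 or abs(amp0) < 1e-12 * max(1.0, abs(yy[0])):
            raise FitConvergenceError("trace has zero amplitude; no decay to fit")

        plateau0 = float(yy[-1]) if self.fit_plateau else 0.0
        k0 = self._initial_rate(ts, yy, plateau0) or 1.0 / max(ts[-1] / 3.0, 1e-9)

        # analytic Jacobian: finite differences would cap precision near sqrt(eps)
        if self.fit_plateau:
            model = _decay

            def jac(tt, kobs, y0, plateau):  # noqa: ANN001
                e = np.exp(-kobs * tt)
                return np.column_stack([-(y0 - plateau) * tt * e, e, 1.0 - e])

            p0 = [k0, float(yy[0]), plateau0]
        else:
            def model(tt, kobs, y0):  # noqa: ANN001
                return _decay(tt, kobs, y0, 0.0)

            def jac(tt, kobs, y0):  # noqa: ANN001
                e = np.exp(-kobs * tt)
                return np.column_stack([-y0 * tt * e, e])

            p0 = [k0, float(yy[0])]

        try:
            popt, pcov = curve_fit(
                model, ts, yy, p0=p0, jac=jac, maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except RuntimeError as exc:  # pragma: no cover - rare
            raise FitConvergenceError(f"decay fit failed to converge: {exc}") from exc

        self.kobs_ = float(popt[0])
        self.y0_ = float(popt[1])
        self.plateau_ = float(popt[2]) if self.fit_plateau else 0.0
        self.stderr_ = float(np.sqrt(max(pcov[0, 0], 0.0)))
        self.flagged_ = not (self.kobs_ > 0)
        self.t_onset_ = float(t0)
        self.n_points_ = int(t.size)
        return self

    @staticmethod
    def _initial_rate(ts, yy, plateau0):
        # log-linear slope on the early, above-plateau part of the trace
        resid = yy - plateau0
        sign = np.sign(resid[0]) or 1.0
        good = sign * resid > 1e-12
        if good.sum() < 2:
            return None
        slope = np.polyfit(ts[good], np.log(sign * resid[good]), 1)[0]
        return -slope if slope < 0 else None

    def predict(self, X):
        check_is_fitted(self)
        t = np.asarray(X, dtype=float).reshape(-1)
        return _decay(t - self.t_onset_, self.kobs_, self.y0_, self.plateau_)


def fit_decay_trace(trace: DissociationTrace, fit_plateau: bool = True) -> RateEstimate:
    """Fit a single exponential decay to the post-illumination part of a trace.

    Only frames at or after ``illumination_onset_index`` enter the fit.  A
    non-decaying trace (fitted ``kobs <= 0``) is returned flagged rather than
    clamped; a zero-amplitude trace raises :class:`FitConvergenceError`.
    """
    i0 = trace.illumination_onset_index
    t = trace.times[i0:]
    y = trace.fluorescence[i0:]
    est = ExponentialDecayModel(fit_plateau=fit_plateau).fit(t, y)
    return RateEstimate(
        kobs=est.kobs_, stderr=est.stderr_, n_points=est.n_points_, flagged=est.flagged_
    )


class PhotoKineticModel(RegressorMixin, BaseEstimator):
    """Least-squares fit of the two-step unbinding model to (intensity, k_obs).

    Parameters
    ----------
    weighted : bool, default False
        If True, weight residuals by ``1/stderr**2`` (requires stderrs at fit).

    Attributes
    ----------
    k1_, k2_, k3_ : float
        Fitted rate constants.
    covariance_ : ndarray (3, 3)
        Covariance of ``(k1, k2, k3)``.
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, X, y, stderr: Sequence[float] | None = None):
        nu = np.asarray(X, dtype=float).reshape(-1)
        kobs = np.asarray(y, dtype=float).reshape(-1)
        if nu.size != kobs.size:
            raise ValueError("X and y must have the same length")
        if np.unique(nu).size < 4:
            raise ValueError(
                f"need >= 4 distinct intensities to fit 3 parameters, got {np.unique(nu).size}"
            )
        if np.any(nu < 0):
            raise ValueError("intensities must be non-negative")
        # a usable program spans dark to saturation (relative spread near 1);
        # points clustered on the plateau cannot separate k1, k2 and k3
        spread = np.ptp(kobs) / max(np.max(np.abs(kobs)), 1e-300)
        if spread < 0.05:
            raise ValueError(
                "k_obs values are indistinguishable across intensities "
                "(all intensities saturating?); model is not identifiable"
            )

        k3_0 = max(float(np.min(kobs)) * 0.999, 1e-9)
        k2_0 = max(float(np.max(kobs)) - k3_0, 1e-6)
        # half-saturation heuristic: intensity where kobs crosses k3 + k2/2
        half = k3_0 + k2_0 / 2.0
        above = nu[kobs >= half]
        nu_half = float(np.min(above[above > 0])) if np.any(above > 0) else float(np.max(nu))
        k1_0 = k2_0 / max(nu_half, 1e-6)

        sigma = None
        if self.weighted:
            if stderr is None:
                raise ValueError("weighted fit requires stderr values")
            sigma = np.asarray(stderr, dtype=float).reshape(-1)

        def model(v, k1, k2, k3):  # noqa: ANN001
            return k1 * v * k2 / (k1 * v + k2) + k3

        try:
            popt, pcov = curve_fit(
                model,
                nu,
                kobs,
                p0=[k1_0, k2_0, k3_0],
                sigma=sigma,
                absolute_sigma=self.weighted,
                bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=50000,
            )
        except RuntimeError as exc:
            raise FitConvergenceError(f"photokinetic fit failed to converge: {exc}") from exc

        self.k1_, self.k2_, self.k3_ = map(float, popt)
        self.covariance_ = 0.5 * (pcov + pcov.T)
        return self

    def predict(self, X):
        check_is_fitted(self)
        return predict_kobs(self.params_, np.asarray(X, dtype=float).reshape(-1))

    @property
    def params_(self) -> PhotoKineticParams:
        check_is_fitted(self)
        return PhotoKineticParams(
            k1=self.k1_, k2=self.k2_, k3=self.k3_, covariance=self.covariance_
        )


def fit_photokinetic_params(
    estimates: Sequence[tuple[float, RateEstimate]], weighted: bool = False
) -> PhotoKineticParams:
    """Fit ``(k1, k2, k3)`` to measured ``(intensity, k_obs)`` pairs.

    ``estimates`` is a sequence of ``(intensity, RateEstimate)``.  Requires at
    least 4 distinct intensities; ideally one near zero (pins ``k3``) and one
    near saturation (pins ``k2 + k3``).
    """
    nu = [float(i) for i, _ in estimates]
    kobs = [e.kobs for _, e in estimates]
    err = [e.stderr for _, e in estimates]
    model = PhotoKineticModel(weighted=weighted).fit(nu, kobs, stderr=err if weighted else None)
    return model.params_


def halflife_from_intensity(
    params: PhotoKineticParams,
    intensity: float,
    calibration: IntensityCalibration | None = None,
) -> float:
    """Enforced ligand binding half-life ``tau = ln2 / k_obs`` at a light level.

    When ``calibration`` is given, ``intensity`` is interpreted as an LED
    voltage and converted via the measured calibration curve (no
    extrapolation).
    """
    nu = calibration.to_intensity(intensity) if calibration is not None else float(intensity)
    return LN2 / predict_kobs(params, nu)
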