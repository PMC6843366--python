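"""Voigt deconvolution of vibrational band envelopes.

The O-H stretching envelope of a cyclodextrin inclusion complex
(3800-3000 cm^-1) is decomposed into six Voigt sub-bands assigned, from high
to low wavenumber, to intracavity water (~3525), primary OH of the host
(~3439), interstitial water (~3360), guest OH (~3277), secondary host OH
(~3191) and strongly bound interstitial water (~3084 cm^-1).  Sub-band
positions are seeded from the minima of the Savitzky-Golay second
derivative; the envelope is then fitted by least squares as a sum of
area-parameterized Voigt profiles plus a linear baseline, after the
overlapping C-H stretching doublet (~2922/~2848 cm^-1) has been modelled in
its own window and subtracted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter
from scipy.special import voigt_profile, wofz

from .exceptions import NumericalError, ValidationError
from .spectra import Spectrum, crop

__all__ = [
    "VoigtPeak",
    "voigt",
    "subtract_overlap",
    "second_derivative_minima",
    "VoigtBandModel",
    "Deconvolution",
    "fit_bands",
    "percent_areas",
]

OH_WINDOW = (3000.0, 3800.0)
CH_WINDOW = (2700.0, 3000.0)
# canonical six-component O-H scheme, descending: intracavity water, primary
# host OH, interstitial water, guest OH, secondary host OH, bound water
OH_SIX_CENTERS = (3525.0, 3439.0, 3360.0, 3277.0, 3191.0, 3084.0)


@dataclass(frozen=True)
class VoigtPeak:
    """One Voigt sub-band: Gaussian sigma convolved with Lorentzian gamma.

    ``area`` is the integrated intensity, so the profile is
    ``area * V(x - center; sigma, gamma)`` with V normalized to unit area.
    """

    center: float
    area: float
    sigma: float
    gamma: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        if self.area < 0:
            raise ValidationError("area must be non-negative")

    def __call__(self, x) -> np.ndarray:
        return self.area * voigt_profile(np.asarray(x, dtype=float) - self.center,
                                         self.sigma, self.gamma)

    @property
    def fwhm(self) -> float:
        """Olivero-Longbothum approximation to the Voigt FWHM."""
        fg = 2.0 * self.sigma * math.sqrt(2.0 * math.log(2.0))
        fl = 2.0 * self.gamma
        return 0.5346 * fl + math.sqrt(0.2166 * fl ** 2 + fg ** 2)


def voigt(x, center: float, area: float, sigma: float, gamma: float) -> np.ndarray:
    """Area-parameterized Voigt profile on ``x``."""
    return area * voigt_profile(np.asarray(x, dtype=float) - center, sigma, gamma)


def _multi_voigt(x, params, n_peaks):
    """Model: sum of n Voigts + linear baseline. params = [c,a,s,g]*n + [b0,b1]."""
    y = params[4 * n_peaks] + params[4 * n_peaks + 1] * x
    for i in range(n_peaks):
        c, a, s, g = params[4 * i: 4 * i + 4]
        y = y + a * voigt_profile(x - c, s, g)
    return y


_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


def _multi_voigt_jac(x, params, n_peaks):
    """Analytic Jacobian of :func:`_multi_voigt` w.r.t. all parameters.

    Uses V(u; s, g) = Re w(z) / (s*sqrt(2*pi)) with z = (u + i*g)/(s*sqrt 2)
    and w'(z) = -2 z w(z) + 2i/sqrt(pi).
    """
    m = x.size
    J = np.empty((m, 4 * n_peaks + 2))
    for i in range(n_peaks):
        c, a, s, g = params[4 * i: 4 * i + 4]
        u = x - c
        z = (u + 1j * g) / (s * _SQRT2)
        w = wofz(z)
        wp = -2.0 * z * w + 2j / math.sqrt(math.pi)
        V = w.real / (s * _SQRT2PI)
        dV_du = (wp / (s * _SQRT2)).real / (s * _SQRT2PI)
        dV_dg = (wp * 1j / (s * _SQRT2)).real / (s * _SQRT2PI)
        dV_ds = (wp * (-z / s)).real / (s * _SQRT2PI) - w.real / (s * s * _SQRT2PI)
        J[:, 4 * i] = -a * dV_du
        J[:, 4 * i + 1] = V
        J[:, 4 * i + 2] = a * dV_ds
        J[:, 4 * i + 3] = a * dV_dg
    J[:, 4 * n_peaks] = 1.0
    J[:, 4 * n_peaks + 1] = x
    return J


def subtract_overlap(spectrum: Spectrum, overlap_window=CH_WINDOW,
                     n_overlap_peaks: int = 2) -> Spectrum:
    """Model and remove a neighbouring band (default the C-H doublet).

    Voigt peaks restricted to ``overlap_window`` are fitted there together
    with a local linear baseline; their modelled profiles (tails included)
    are then subtracted from the whole trace and the result clipped at zero.
    When the window holds no signal (max below 3x the noise MAD) the
    spectrum is returned unchanged.
    """
    lo, hi = min(overlap_window), max(overlap_window)
    try:
        win = crop(spectrum, lo, hi)
    except ValidationError:
        raise ValidationError("overlap window does not intersect the spectrum")
    noise = float(np.median(np.abs(np.diff(win.intensity)))) / math.sqrt(2.0) + 1e-30
    if win.intensity.max() < 3.0 * noise:
        warnings.warn("no signal in overlap window; returning spectrum unchanged")
        return spectrum
    centers = np.linspace(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo), n_overlap_peaks)
    dec = fit_bands(win, centers, center_slack=(hi - lo) / 2, max_rounds=2)
    model = np.zeros_like(spectrum.intensity)
    for p in dec.peaks:
        model += p(spectrum.axis)
    return spectrum.with_intensity(np.clip(spectrum.intensity - model, 0.0, None))


def second_derivative_minima(spectrum: Spectrum, smooth_window: int = 11,
                             min_prominence: float = 0.05) -> np.ndarray:
    """Sub-band candidate centers from Savitzky-Golay second derivatives.

    A Voigt (or Gaussian) component produces a local minimum of d2y/dx2 at
    its center, which survives overlap far better than a shoulder in the raw
    trace.  Minima deeper than ``min_prominence`` times the largest |d2| are
    returned in ascending axis order.
    """
    if smooth_window % 2 == 0:
        smooth_window += 1
    if smooth_window > len(spectrum):
        raise ValidationError("smooth_window exceeds the number of points")
    dx = float(np.mean(np.diff(spectrum.axis)))
    d2 = savgol_filter(spectrum.intensity, smooth_window, polyorder=3,
                       deriv=2, delta=dx)
    depth = np.abs(d2).max()
    if depth <= 0:
        return np.array([])
    idx, _ = find_peaks(-d2, height=min_prominence * depth)
    return spectrum.axis[idx]


class VoigtBandModel:
    """Least-squares model: sum of Voigt sub-bands plus a linear baseline.

    Parameters
    ----------
    spectrum : Spectrum
        The trace to fit, already cropped to the analysis window
        (3800-3000 cm^-1 for the O-H analysis).
    init_centers : sequence of float
        Starting sub-band positions, e.g. from
        :func:`second_derivative_minima`.
    center_slack : float
        Each fitted center is bounded to its initial value +/- this (cm^-1);
        keeps the physical assignment of sub-bands stable while leaving all
        parameters free within it.
    """

    def __init__(self, spectrum: Spectrum, init_centers, center_slack: float = 40.0):
        if len(init_centers) < 1:
            raise ValidationError("need at least one initial center")
        self.spectrum = spectrum
        self.init_centers = np.sort(np.asarray(init_centers, dtype=float))
        self.center_slack = float(center_slack)

    def fit(self, max_rounds: int = 3) -> "Deconvolution":
        x = self.spectrum.axis
        # fit on a unit-max trace so convergence (and hence the result) is
        # exactly equivariant under intensity scaling; areas are scaled back
        y_raw = self.spectrum.intensity
        y_scale = float(np.abs(y_raw).max())
        if y_scale <= 0:
            raise ValidationError("cannot fit an all-zero spectrum")
        y = y_raw / y_scale
        n = self.init_centers.size
        span = x[-1] - x[0]
        sep = span / max(n, 1)
        sigma0 = max(min(sep / 4.0, span / 8.0), 2.0)

        # linear baseline through the window endpoints as the starting guess
        b1 = (y[-1] - y[0]) / (x[-1] - x[0])
        b0 = y[0] - b1 * x[0]
        base = b0 + b1 * x

        p0, lb, ub = [], [], []
        for c in self.init_centers:
            amp = max(float(np.interp(c, x, y - base)), 1e-6 * max(y.max(), 1e-12))
            area0 = amp * sigma0 * math.sqrt(2.0 * math.pi)
            p0 += [c, area0, sigma0, sigma0 / 4.0]
            lb += [c - self.center_slack, 0.0, 1e-3, 0.0]
            ub += [c + self.center_slack, np.inf, span, span]
        p0 += [b0, b1]
        lb += [-np.inf, -np.inf]
        ub += [np.inf, np.inf]
        lb, ub = np.asarray(lb), np.asarray(ub)

        def resid(p):
            return _multi_voigt(x, p, n) - y

        def solve(p_start):
            return least_squares(resid, p_start, bounds=(lb, ub), method="trf",
                                 jac=lambda p: _multi_voigt_jac(x, p, n),
                                 xtol=1e-10, ftol=1e-12)

        # restart rounds: refit from a perturbed copy of the running best
        # solution until R^2 stops improving (escapes shallow local minima)
        tss = float(np.sum((y - y.mean()) ** 2)) + 1e-300
        rng = np.random.default_rng(12345)
        sol = solve(np.asarray(p0))
        best_p, best_r2 = sol.x, 1.0 - 2.0 * sol.cost / tss
        for _ in range(max_rounds - 1):
            p_try = best_p.copy()
            for i in range(n):
                p_try[4 * i] += rng.uniform(-0.1, 0.1) * self.center_slack
                p_try[4 * i + 1] *= rng.uniform(0.7, 1.3)
                p_try[4 * i + 2] *= rng.uniform(0.8, 1.25)
                p_try[4 * i + 3] = p_try[4 * i + 3] * rng.uniform(0.5, 1.5) + 0.1
            sol = solve(np.clip(p_try, lb, ub))
            r2 = 1.0 - 2.0 * sol.cost / tss
            improved = r2 - best_r2
            if improved > 0:
                best_p, best_r2 = sol.x, r2
            if improved < 1e-6:
                break
        if best_p is None or not np.all(np.isfinite(best_p)):
            raise NumericalError(f"band fit failed; last R^2 = {best_r2:.6f}")

        peaks = []
        for i in range(n):
            c, a, s, g = best_p[4 * i: 4 * i + 4]
            peaks.append(VoigtPeak(center=float(c), area=float(a * y_scale),
                                   sigma=float(s), gamma=float(g)))
        peaks.sort(key=lambda p: -p.center)  # omega_1 = highest wavenumber
        return Deconvolution(
            model=self,
            peaks=tuple(peaks),
            baseline=(float(best_p[-2] * y_scale), float(best_p[-1] * y_scale)),
            r_squared=float(best_r2),
        )


@dataclass(frozen=True)
class Deconvolution:
    """A fitted set of Voigt sub-bands, ordered by descending center."""

    model: VoigtBandModel = field(repr=False)
    peaks: tuple
    baseline: tuple
    r_squared: float

    @property
    def percent_areas(self) -> np.ndarray:
        return percent_areas(self)

    def predicted(self, x=None) -> np.ndarray:
        x = self.model.spectrum.axis if x is None else np.asarray(x, dtype=float)
        y = self.baseline[0] + self.baseline[1] * x
        for p in self.peaks:
            y = y + p(x)
        return y

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "baseline": list(self.baseline),
            "peaks": [
                {"center_cm1": p.center, "area": p.area, "sigma_cm1": p.sigma,
                 "gamma_cm1": p.gamma, "percent_area": float(i)}
                for p, i in zip(self.peaks, self.percent_areas)
            ],
        }

    def summary(self) -> str:
        lines = [
            "Voigt band deconvolution",
            "------------------------",
            f"R^2 = {self.r_squared:.6f}   ({len(self.peaks)} sub-bands)",
            f"{'center':>8s} {'sigma':>7s} {'gamma':>7s} {'I_i %':>7s}",
        ]
        for p, i in zip(self.peaks, self.percent_areas):
            lines.append(f"{p.center:8.1f} {p.sigma:7.1f} {p.gamma:7.1f} {i:7.2f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Envelope, fitted sum and individual sub-bands; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.spectrum
        ax.plot(s.axis, s.intensity, "k.", ms=2, label="data")
        ax.plot(s.axis, self.predicted(), "r-", lw=1, label="fit")
        for p in self.peaks:
            ax.plot(s.axis, p(s.axis), "--", lw=0.7)
        ax.invert_xaxis()
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("absorbance")
        ax.legend()
        return ax


def percent_areas(deconv: Deconvolution) -> np.ndarray:
    """Percent area I_i of each sub-band, summing to 100."""
    areas = np.array([p.area for p in deconv.peaks])
    total = areas.sum()
    if total <= 0:
        raise ValidationError("all sub-band areas are zero")
    return 100.0 * areas / total


def fit_bands(spectrum: Spectrum, init_centers, center_slack: float = 40.0,
              max_rounds: int = 3) -> Deconvolution:
    """Functional wrapper around :class:`VoigtBandModel`."""
    return VoigtBandModel(spectrum, init_centers, center_slack).fit(max_rounds=max_rounds)
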