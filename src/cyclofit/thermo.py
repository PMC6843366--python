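"""Two-state hydrogen-bond thermodynamics from temperature series.

The six O-H sub-bands are grouped into a high-wavenumber class of free (or
weakly H-bonded) oscillators (omega_1, omega_2) and a low-wavenumber class
of H-bonded ones (omega_3..omega_6).  The population ratio

    R(T) = (I1 + I2) / (I3 + I4 + I5 + I6)

grows with temperature as hydrogen bonds break; a linear fit of ln R against
1/T yields the mean H-bond rupture enthalpy |slope| * R_gas and the
corresponding entropy from the intercept.  A prerequisite of the two-state
picture is an isosbestic point: a wavenumber where all (area-normalized)
spectra of the series cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .bands import OH_SIX_CENTERS, Deconvolution, VoigtBandModel, second_derivative_minima
from .exceptions import DomainError, ValidationError
from .phase_solubility import R_GAS
from .spectra import SpectralSeries, normalize

__all__ = [
    "population_ratio",
    "hydrogen_bond_enthalpy",
    "VantHoffModel",
    "VantHoffResult",
    "vant_hoff_fit",
    "IsosbesticPoint",
    "find_isosbestic",
]


def population_ratio(deconv: Deconvolution) -> float:
    """Free-to-bonded population ratio R from a six-band deconvolution.

    Peaks must be ordered by descending center (the :class:`Deconvolution`
    convention), so indices 0-1 are the free class and 2-5 the bonded class.
    """
    if len(deconv.peaks) != 6:
        raise ValidationError(
            f"the two-state analysis needs exactly six sub-bands, got {len(deconv.peaks)}"
        )
    I = deconv.percent_areas
    denom = I[2:].sum()
    if denom <= 0:
        raise DomainError("H-bonded class has zero total area")
    return float(I[:2].sum() / denom)


def hydrogen_bond_enthalpy(series: SpectralSeries, init_centers=OH_SIX_CENTERS,
                           center_slack: float = 40.0, max_rounds: int = 3,
                           smooth_window: int = 11,
                           min_prominence: float = 0.05) -> "VantHoffResult":
    """Full two-state pipeline: deconvolute a temperature series, fit ln R vs 1/T.

    Each spectrum is decomposed into six Voigt sub-bands.  Centers are
    seeded from the second-derivative minima when exactly six are found,
    otherwise from ``init_centers`` (default the canonical O-H scheme); the
    population ratio R of each deconvolution then enters the van 't Hoff
    fit.  The series' condition values are the temperatures in kelvin.
    """
    ratios = []
    for spec in series.spectra:
        centers = second_derivative_minima(spec, smooth_window=smooth_window,
                                           min_prominence=min_prominence)
        if centers.size != 6:
            centers = np.asarray(init_centers, dtype=float)
        dec = VoigtBandModel(spec, centers, center_slack=center_slack).fit(max_rounds=max_rounds)
        ratios.append(population_ratio(dec))
    return VantHoffModel(series.condition, ratios).fit()


class VantHoffModel:
    """OLS of ln R on 1/T for a temperature series of population ratios."""

    def __init__(self, temperatures, ratios):
        t = np.asarray(temperatures, dtype=float)
        r = np.asarray(ratios, dtype=float)
        if t.size != r.size:
            raise ValidationError("temperatures and ratios lengths differ")
        if t.size < 3:
            raise ValidationError("need at least three temperatures")
        if np.unique(t).size != t.size or np.any(t <= 0):
            raise ValidationError("temperatures must be distinct and positive")
        if np.any(r <= 0):
            raise DomainError("ratios must be positive to take logarithms")
        order = np.argsort(t)
        self.temperatures = t[order]
        self.ratios = r[order]

    def fit(self) -> "VantHoffResult":
        x = sm.add_constant(1.0 / self.temperatures)
        ols = sm.OLS(np.log(self.ratios), x).fit()
        intercept, slope = ols.params
        intercept_se, slope_se = ols.bse
        return VantHoffResult(
            model=self,
            delta_h=abs(float(slope)) * R_GAS,
            delta_h_se=float(slope_se) * R_GAS,
            delta_s=float(intercept) * R_GAS,
            delta_s_se=float(intercept_se) * R_GAS,
            slope=float(slope),
            fit_r_squared=float(ols.rsquared),
        )


@dataclass(frozen=True)
class VantHoffResult:
    """H-bond rupture enthalpy/entropy from the ln R vs 1/T line.

    ``delta_h`` is reported as a positive magnitude (J/mol): breaking
    hydrogen bonds costs enthalpy, and the free population grows with T so
    the fitted slope against 1/T is negative.
    """

    model: VantHoffModel = field(repr=False)
    delta_h: float
    delta_h_se: float
    delta_s: float
    delta_s_se: float
    slope: float
    fit_r_squared: float

    @property
    def temperatures(self) -> np.ndarray:
        return self.model.temperatures

    @property
    def ratios(self) -> np.ndarray:
        return self.model.ratios

    def to_dict(self) -> dict:
        return {
            "delta_h_J_per_mol": self.delta_h,
            "delta_h_se_J_per_mol": self.delta_h_se,
            "delta_s_J_per_mol_K": self.delta_s,
            "delta_s_se_J_per_mol_K": self.delta_s_se,
            "fit_r_squared": self.fit_r_squared,
        }

    def summary(self) -> str:
        return "\n".join([
            "van 't Hoff two-state fit (ln R vs 1/T)",
            "---------------------------------------",
            f"n temperatures : {self.temperatures.size}"
            f" ({self.temperatures.min():.0f}-{self.temperatures.max():.0f} K)",
            f"dH_HB (J/mol)  : {self.delta_h:.0f} +/- {self.delta_h_se:.0f}",
            f"dS_HB (J/mol/K): {self.delta_s:.2f} +/- {self.delta_s_se:.2f}",
            f"r-squared      : {self.fit_r_squared:.4f}",
        ])

    def plot(self, ax=None):
        """van 't Hoff plot with the fitted line; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        invt = 1.0 / self.temperatures
        ax.plot(invt, np.log(self.ratios), "o", label="ln R")
        intercept = self.delta_s / R_GAS
        ax.plot(invt, intercept + self.slope * invt, "-", label="fit")
        ax.set_xlabel("1/T (K$^{-1}$)")
        ax.set_ylabel("ln R")
        ax.legend()
        return ax


def vant_hoff_fit(temperatures, ratios) -> VantHoffResult:
    """Functional wrapper around :class:`VantHoffModel`."""
    return VantHoffModel(temperatures, ratios).fit()


@dataclass(frozen=True)
class IsosbesticPoint:
    """Candidate isosbestic point of a spectral series."""

    center: float | None
    spread: float
    present: bool
    degenerate: bool = False


def find_isosbestic(series: SpectralSeries, rel_threshold: float = 0.05) -> IsosbesticPoint:
    """Locate the axis point where all spectra of a series cross.

    Spectra are area-normalized first (the comparison across conditions is
    only meaningful per absorber).  The candidate is the point of minimal
    across-condition standard deviation; it is flagged present when that SD
    is below ``rel_threshold`` times the median SD over the axis.  A series
    of (numerically) identical spectra is degenerate: every point ties and
    no isosbestic is reported.
    """
    if len(series) < 3:
        raise ValidationError("need at least three spectra to test for an isosbestic point")
    mat = np.vstack([normalize(s, "unit-area").intensity for s in series.spectra])
    sd = mat.std(axis=0)
    mean = mat.mean(axis=0)
    # an isosbestic point is a crossing of *bands*: restrict the search to
    # the signal region, else the empty baseline (SD ~ 0) always wins
    signal = mean >= 0.05 * mean.max()
    med = float(np.median(sd[signal]))
    scale = float(np.abs(mat).max())
    if med <= 1e-12 * max(scale, 1e-30):
        return IsosbesticPoint(center=None, spread=0.0, present=False, degenerate=True)
    sd_masked = np.where(signal, sd, np.inf)
    i = int(np.argmin(sd_masked))
    spread = float(sd[i] / med)
    return IsosbesticPoint(center=float(series.axis[i]), spread=spread,
                           present=spread < rel_threshold)
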