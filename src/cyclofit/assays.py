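"""Deterministic assay arithmetic: viability, LDH release, permeation,
HPLC calibration.

These are the bookkeeping formulas around the biological and analytical
experiments: percent viability and LDH release are signal ratios; cumulative
permeation through a Franz-cell membrane must be corrected for the receptor
volume withdrawn and replaced at each sampling time; HPLC calibration is a
straight line whose detection and quantitation limits follow the S/N = 3 and
S/N = 10 convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, ValidationError

__all__ = [
    "viability_percent",
    "ldh_release_percent",
    "PermeationSeries",
    "cumulative_permeation",
    "CalibrationCurve",
    "fit_calibration",
    "moles_from_mass",
    "mucosal_accumulation_percent",
]


def moles_from_mass(mass_g: float, molar_mass: float) -> float:
    """Moles from a weighed mass and a (possibly average) molar mass, g/mol."""
    if molar_mass <= 0:
        raise DomainError("molar mass must be positive")
    if mass_g < 0:
        raise ValidationError("mass must be non-negative")
    return mass_g / molar_mass


def viability_percent(abs_treated: float, abs_control: float) -> float:
    """Cell viability as 100 * AbsT / AbsC (MTT-type readout)."""
    if abs_control <= 0:
        raise DomainError("control absorbance must be positive")
    if abs_treated < 0:
        raise ValidationError("treated absorbance must be non-negative")
    return 100.0 * abs_treated / abs_control


def ldh_release_percent(released: float, total: float) -> float:
    """LDH leakage as a percentage of the total lysis signal."""
    if total <= 0:
        raise DomainError("total signal must be positive")
    if released < 0:
        raise ValidationError("released signal must be non-negative")
    pct = 100.0 * released / total
    if pct > 100.0:
        warnings.warn(f"released exceeds total ({pct:.1f}%)")
    return pct


@dataclass(frozen=True)
class PermeationSeries:
    """Franz-cell sampling record for one donor dose.

    ``sample_conc`` are the guest concentrations measured in the aliquots
    withdrawn at ``times``; each aliquot of ``sample_volume`` is replaced by
    fresh receptor phase, so later concentrations are diluted by what was
    already removed.
    """

    times: np.ndarray  # h
    sample_conc: np.ndarray  # mass / mL, same units as dose/volume implies
    receptor_volume: float = 4.5  # mL
    sample_volume: float = 0.5  # mL
    dose: float | None = None  # total guest amount applied to the donor

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.sample_conc, dtype=float)
        if t.size != c.size:
            raise ValidationError("times and sample_conc lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be non-negative")
        if not 0 < self.sample_volume < self.receptor_volume:
            raise ValidationError("sample volume must be positive and below the receptor volume")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sample_conc", c)


def cumulative_permeation(series: PermeationSeries) -> pd.DataFrame:
    """Cumulative permeated amount with the sampling-replacement correction.

    Q_n = C_n * V_receptor + sum_{i<n} C_i * V_sample: the receptor holds
    C_n * V_r at time n, plus everything already carried away in earlier
    aliquots.  Adds percent of dose when the series carries a dose.
    """
    c = series.sample_conc
    removed = np.concatenate(([0.0], np.cumsum(c[:-1] * series.sample_volume)))
    q = c * series.receptor_volume + removed
    out = pd.DataFrame({"time_h": series.times, "cumulative_amount": q})
    if series.dose is not None:
        if series.dose <= 0:
            raise DomainError("dose must be positive")
        out["percent_of_dose"] = 100.0 * q / series.dose
    return out


def mucosal_accumulation_percent(recovered: float, dose: float,
                                 recovery_factor: float | None = None) -> float:
    """Percent of the dose accumulated in the mucosa.

    ``recovery_factor`` (e.g. 0.97 for a 97% w/w extraction recovery)
    corrects the recovered amount for incomplete extraction when given.
    """
    if dose <= 0:
        raise DomainError("dose must be positive")
    if recovered < 0:
        raise ValidationError("recovered amount must be non-negative")
    if recovery_factor is not None:
        if not 0 < recovery_factor <= 1:
            raise DomainError("recovery factor must be in (0, 1]")
        recovered = recovered / recovery_factor
    return 100.0 * recovered / dose


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear HPLC calibration with S/N-based LOD and LOQ."""

    concentrations: np.ndarray = field(repr=False)
    responses: np.ndarray = field(repr=False)
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    noise_sd: float
    lod: float
    loq: float

    def predict_concentration(self, response) -> np.ndarray:
        """Invert the line: concentration of an unknown from its peak area."""
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope

    def summary(self) -> str:
        return "\n".join([
            "HPLC calibration",
            "----------------",
            f"levels    : {self.concentrations.size}"
            f" ({self.concentrations.min():g}-{self.concentrations.max():g} ug/mL)",
            f"slope     : {self.slope:.4g} +/- {self.slope_se:.2g}",
            f"intercept : {self.intercept:.4g}",
            f"r-squared : {self.r_squared:.5f}",
            f"LOD       : {self.lod:.3g} ug/mL   (S/N = 3)",
            f"LOQ       : {self.loq:.3g} ug/mL   (S/N = 10)",
        ])


def fit_calibration(concentrations, responses, noise_sd: float) -> CalibrationCurve:
    """Least-squares calibration line with LOD = 3s/m and LOQ = 10s/m."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size != r.size:
        raise ValidationError("concentrations and responses lengths differ")
    if c.size < 5:
        raise ValidationError("need at least five calibration levels")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    ols = sm.OLS(r, sm.add_constant(c)).fit()
    intercept, slope = ols.params
    if slope <= 0:
        raise ValidationError("calibration slope must be positive")
    return CalibrationCurve(
        concentrations=c,
        responses=r,
        slope=float(slope),
        slope_se=float(ols.bse[1]),
        intercept=float(intercept),
        r_squared=float(ols.rsquared),
        noise_sd=float(noise_sd),
        lod=3.0 * noise_sd / float(slope),
        loq=10.0 * noise_sd / float(slope),
    )
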