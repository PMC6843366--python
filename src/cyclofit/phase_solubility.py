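"""Higuchi-Connors phase-solubility analysis.

A phase-solubility experiment equilibrates excess guest (drug) with
increasing host (cyclodextrin) concentrations and measures the dissolved
guest S at each level.  For a soluble 1:1 complex the isotherm is the linear
A_L diagram

    S(c) = S0 + c * Kc*S0 / (1 + Kc*S0),

so the association constant follows from the fitted slope as

    Kc = slope / (S0 * (1 - slope)),

valid for 0 < slope < 1.  ``S0`` is the guest's intrinsic solubility, best
taken from a direct measurement; the fitted intercept is the fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError, ValidationError

__all__ = [
    "PhaseSolubilityData",
    "PhaseSolubilityModel",
    "PhaseSolubilityResults",
    "fit_phase_solubility",
    "stability_constant",
    "gibbs_from_kc",
    "R_GAS",
    "KCAL",
]

R_GAS = 8.31446  # J mol^-1 K^-1
KCAL = 4184.0  # J per kcal (thermochemical)


@dataclass(frozen=True)
class PhaseSolubilityData:
    """Host concentration grid and measured guest solubility, both molar."""

    cd_conc: np.ndarray
    solubility: np.ndarray
    temperature: float = 298.15

    def __post_init__(self):
        cd = np.asarray(self.cd_conc, dtype=float)
        s = np.asarray(self.solubility, dtype=float)
        if cd.size != s.size:
            raise ValidationError("cd_conc and solubility lengths differ")
        if cd.size < 3:
            raise ValidationError("need at least three host-concentration levels")
        if cd[0] != 0.0:
            raise ValidationError("the grid must include the host-free level (0 M)")
        if np.any(cd < 0) or np.any(np.diff(cd) <= 0):
            raise ValidationError("host concentrations must be non-negative and strictly increasing")
        if np.any(s <= 0):
            raise ValidationError("solubilities must be positive")
        object.__setattr__(self, "cd_conc", cd)
        object.__setattr__(self, "solubility", s)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: float = 298.15):
        return cls(df["cd_conc_M"].to_numpy(), df["solubility_M"].to_numpy(), temperature)


def stability_constant(slope: float, s0: float) -> float:
    """1:1 association constant (M^-1) from an A_L diagram slope.

    Raises :class:`DomainError` outside 0 < slope < 1, where the 1:1 A_L
    interpretation does not apply.
    """
    if not 0.0 < slope < 1.0:
        raise DomainError(f"A_L formula needs 0 < slope < 1, got {slope}")
    if s0 <= 0:
        raise DomainError("intrinsic solubility must be positive")
    return slope / (s0 * (1.0 - slope))


def stability_constant_se(slope: float, slope_se: float, s0: float) -> float:
    """Delta-method standard error of Kc given the slope's SE."""
    return slope_se / (s0 * (1.0 - slope) ** 2)


def gibbs_from_kc(kc: float, temperature: float, unit: str = "kcal/mol") -> float:
    """Standard binding free energy -RT ln Kc.

    Note Kc carries units of M^-1; the standard-state convention (1 M) is
    implicit, as is usual when quoting cyclodextrin binding energies.
    """
    if kc <= 0:
        raise DomainError("kc must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    dg_j = -R_GAS * temperature * math.log(kc)
    if unit == "kJ/mol":
        return dg_j / 1000.0
    if unit == "kcal/mol":
        return dg_j / KCAL
    raise ValidationError(f"unknown unit {unit!r}")


class PhaseSolubilityModel:
    """Ordinary least-squares model for an A-type phase-solubility diagram.

    Parameters
    ----------
    data : PhaseSolubilityData
    s0 : float, optional
        Measured intrinsic solubility (M).  When omitted the fitted
        intercept estimates S0.
    linearity_threshold : float
        Minimum r-squared for the diagram to be classified A_L.
    """

    def __init__(self, data: PhaseSolubilityData, s0: float | None = None,
                 linearity_threshold: float = 0.99):
        self.data = data
        self.s0 = s0
        self.linearity_threshold = linearity_threshold

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(PhaseSolubilityData.from_dataframe(df), **kwargs)

    def fit(self) -> "PhaseSolubilityResults":
        x = sm.add_constant(self.data.cd_conc)
        ols = sm.OLS(self.data.solubility, x).fit()
        intercept, slope = ols.params
        intercept_se, slope_se = ols.bse
        r2 = float(ols.rsquared)
        is_al = (0.0 < slope < 1.0) and r2 >= self.linearity_threshold
        kc = kc_se = None
        s0 = self.s0 if self.s0 is not None else float(intercept)
        if is_al:
            kc = stability_constant(float(slope), s0)
            kc_se = stability_constant_se(float(slope), float(slope_se), s0)
        return PhaseSolubilityResults(
            model=self,
            slope=float(slope),
            slope_se=float(slope_se),
            intercept=float(intercept),
            intercept_se=float(intercept_se),
            r_squared=r2,
            diagram_class="A_L" if is_al else "nonlinear",
            s0_used=s0,
            kc=kc,
            kc_se=kc_se,
        )


@dataclass(frozen=True)
class PhaseSolubilityResults:
    """Fitted A_L line, diagram classification and derived constants."""

    model: PhaseSolubilityModel = field(repr=False)
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    diagram_class: str
    s0_used: float
    kc: float | None
    kc_se: float | None

    def delta_g(self, temperature: float | None = None, unit: str = "kcal/mol") -> float:
        """Binding free energy from the fitted Kc at the data's temperature."""
        if self.kc is None:
            raise DomainError("no Kc available for a nonlinear diagram")
        t = temperature if temperature is not None else self.model.data.temperature
        return gibbs_from_kc(self.kc, t, unit)

    def to_dict(self) -> dict:
        out = {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept_M": self.intercept,
            "r_squared": self.r_squared,
            "diagram_class": self.diagram_class,
            "s0_used_M": self.s0_used,
            "kc_per_M": self.kc,
            "kc_se_per_M": self.kc_se,
        }
        if self.kc is not None:
            out["delta_g_kcal_per_mol"] = self.delta_g()
        return out

    def summary(self) -> str:
        lines = [
            "Phase-solubility fit (Higuchi-Connors)",
            "--------------------------------------",
            f"diagram class : {self.diagram_class}",
            f"slope         : {self.slope:.4f} +/- {self.slope_se:.4f}",
            f"intercept (M) : {self.intercept:.3e} +/- {self.intercept_se:.3e}",
            f"r-squared     : {self.r_squared:.5f}",
        ]
        if self.kc is not None:
            lines += [
                f"S0 used (M)   : {self.s0_used:.3e}",
                f"Kc (M^-1)     : {self.kc:.0f} +/- {self.kc_se:.0f}",
                f"dG (kcal/mol) : {self.delta_g():.2f}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagram with the fitted line; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        ax.plot(d.cd_conc * 1e3, d.solubility * 1e3, "o", label="data")
        xs = np.linspace(0, d.cd_conc.max(), 50)
        ax.plot(xs * 1e3, (self.intercept + self.slope * xs) * 1e3, "-",
                label=f"{self.diagram_class} fit")
        ax.set_xlabel("host (mM)")
        ax.set_ylabel("dissolved guest (mM)")
        ax.legend()
        return ax


def fit_phase_solubility(data: PhaseSolubilityData, s0: float | None = None,
                         linearity_threshold: float = 0.99) -> PhaseSolubilityResults:
    """Functional wrapper around :class:`PhaseSolubilityModel`."""
    return PhaseSolubilityModel(data, s0=s0, linearity_threshold=linearity_threshold).fit()
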