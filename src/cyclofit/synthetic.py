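"""Seeded generators emulating the study's experimental inputs.

Each generator is a deterministic function of its parameters and a seed and
produces data with the statistical structure the matching analysis assumes:

* :func:`gen_phase_solubility` — linear A_L isotherms with the association
  constant Kc = 6031 M^-1 and intrinsic solubility S0 = 2e-5 M of the
  idebenone / HP-beta-cyclodextrin system, multiplicative measurement noise;
* :func:`gen_titration` — Beer-Lambert UV-Vis absorbance matrices at the
  seven host concentrations of the titration protocol (plus the guest-only
  reference), additive detector noise;
* :func:`gen_oh_series` — temperature series (250-340 K) of O-H stretching
  envelopes built from six Voigt sub-bands whose class populations follow a
  two-state van 't Hoff law with total area conserved;
* :func:`gen_diffusion` — DOSY-style diffusion coefficients near
  2.3-2.7e-10 m^2/s under fast-exchange averaging.

Passing each generator's noiseless output through its analysis stage
recovers the generating parameters to numerical precision; that round trip
is the package's master self-test.
"""

from __future__ import annotations

import math

import numpy as np

from .bands import VoigtPeak
from .equilibria import BindingModel, TitrationData, solve_speciation, speciation_matrix
from .exceptions import ValidationError
from .nmr import DiffusionMeasurement
from .phase_solubility import PhaseSolubilityData, R_GAS
from .spectra import Spectrum, SpectralSeries

__all__ = [
    "gen_phase_solubility",
    "gen_titration",
    "gen_oh_series",
    "gen_diffusion",
    "DEFAULT_H_GRID",
    "DEFAULT_OH_SUBBANDS",
    "default_epsilon_specs",
]

# the seven host levels of the titration protocol, preceded by the
# guest-only reference measurement
DEFAULT_H_GRID = np.array(
    [0.0, 4.43e-5, 8.86e-5, 1.33e-4, 2.21e-4, 4.43e-4, 6.64e-4, 2.21e-3]
)

# six-band O-H scheme: (center cm^-1, sigma, gamma, class, within-class weight)
# class "free" = high-wavenumber pair, class "bonded" = the other four
DEFAULT_OH_SUBBANDS = (
    (3525.0, 30.0, 8.0, "free", 0.45),
    (3439.0, 32.0, 8.0, "free", 0.55),
    (3360.0, 33.0, 8.0, "bonded", 0.30),
    (3277.0, 32.0, 8.0, "bonded", 0.25),
    (3191.0, 30.0, 7.0, "bonded", 0.25),
    (3084.0, 26.0, 6.0, "bonded", 0.20),
)


def gen_phase_solubility(kc: float = 6031.0, s0: float = 2e-5, cd_grid=None,
                         cv: float = 0.02, seed: int = 0,
                         temperature: float = 298.15) -> PhaseSolubilityData:
    """Synthetic A_L phase-solubility table.

    S(c) = s0 + c * Kc*s0/(1 + Kc*s0) with multiplicative Gaussian noise of
    coefficient of variation ``cv``; default grid 0-9 mM in 1 mM steps.
    """
    if kc <= 0 or s0 <= 0:
        raise ValidationError("kc and s0 must be positive")
    if cd_grid is None:
        cd_grid = np.arange(0.0, 10.0) * 1e-3
    cd = np.asarray(cd_grid, dtype=float)
    slope = kc * s0 / (1.0 + kc * s0)
    s = s0 + slope * cd
    if cv > 0:
        rng = np.random.default_rng(seed)
        s = s * (1.0 + cv * rng.standard_normal(s.size))
        s = np.clip(s, 1e-12, None)
    return PhaseSolubilityData(cd, s, temperature)


def default_epsilon_specs():
    """Gaussian-mixture molar absorptivity shapes (M^-1 cm^-1 over nm).

    Free guest: pi->pi* band near 280 nm plus a deeper-UV shoulder; bound
    guest: slightly red-shifted and hyperchromic, as inclusion of a quinone
    chromophore typically produces.  Keys are species (h, g) tuples.
    """
    return {
        (0, 1): [(1.55e4, 280.0, 24.0), (6.0e3, 230.0, 16.0)],
        (1, 1): [(1.75e4, 287.0, 26.0), (5.0e3, 233.0, 17.0)],
    }


def _epsilon_matrix(model: BindingModel, specs: dict, wavelengths: np.ndarray) -> np.ndarray:
    E = np.zeros((len(model.absorbing), wavelengths.size))
    for i, key in enumerate(model.absorbing):
        for amp, center, width in specs.get(key, ()):
            E[i] += amp * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
    return E


def gen_titration(model: BindingModel | None = None, epsilon_specs: dict | None = None,
                  g_tot: float = 4.43e-5, h_grid=None, wavelengths=None,
                  noise_sd: float = 0.002, seed: int = 0,
                  path_length: float = 1.0) -> TitrationData:
    """Synthetic multiwavelength titration (Beer-Lambert + additive noise).

    Defaults reproduce the study conditions: a 1:1 complex with
    log10 beta = log10(6025), guest total 4.43e-5 M, the seven printed host
    concentrations plus the guest-only reference, and a 200-400 nm grid in
    2 nm steps.
    """
    if model is None:
        model = BindingModel([(1, 1, math.log10(6025.0))])
    if epsilon_specs is None:
        epsilon_specs = default_epsilon_specs()
    h = DEFAULT_H_GRID if h_grid is None else np.asarray(h_grid, dtype=float)
    wl = np.arange(200.0, 401.0, 2.0) if wavelengths is None else np.asarray(wavelengths, dtype=float)
    E = _epsilon_matrix(model, epsilon_specs, wl)
    if np.any(E < 0):
        raise ValidationError("absorptivity shapes must be non-negative")
    C = speciation_matrix(model, h, g_tot)
    A = path_length * C @ E
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + noise_sd * rng.standard_normal(A.shape)
    return TitrationData(g_tot, h, wl, A, path_length)


def _two_state_ratio(temperature: float, delta_h: float, delta_s: float) -> float:
    """R(T) under the magnitude-convention van 't Hoff law.

    ln R = -delta_h / (R_gas T) + delta_s / R_gas, so R grows with T for a
    positive rupture enthalpy.
    """
    return math.exp(-delta_h / (R_GAS * temperature) + delta_s / R_GAS)


def gen_oh_series(subbands=DEFAULT_OH_SUBBANDS, delta_h: float = 10596.0,
                  delta_s: float = 30.0, temperatures=None, noise: float = 0.01,
                  seed: int = 0, grid=None) -> SpectralSeries:
    """Temperature series of six-Voigt O-H envelopes, total area = 1.

    The free-class weight is w(T) = R/(1+R) with R from the van 't Hoff law;
    within each class the sub-band proportions stay fixed, so the series has
    an exact isosbestic point where the two class basis spectra cross.
    Noise is multiplicative per point.
    """
    sb = list(subbands)
    if len(sb) != 6:
        raise ValidationError("the O-H scheme uses exactly six sub-bands")
    free = [(c, s, g, w) for c, s, g, cls, w in sb if cls == "free"]
    bonded = [(c, s, g, w) for c, s, g, cls, w in sb if cls == "bonded"]
    if not free or not bonded:
        raise ValidationError("both sub-band classes must have nonzero area")
    wf = sum(w for *_, w in free)
    wb = sum(w for *_, w in bonded)
    if wf <= 0 or wb <= 0:
        raise ValidationError("class areas must be positive")
    if temperatures is None:
        temperatures = np.linspace(250.0, 340.0, 10)
    temperatures = np.asarray(temperatures, dtype=float)
    x = np.arange(3000.0, 3801.0, 2.0) if grid is None else np.asarray(grid, dtype=float)

    def class_profile(bands, total):
        y = np.zeros_like(x)
        for c, s, g, w in bands:
            y += VoigtPeak(center=c, area=w / total, sigma=s, gamma=g)(x)
        return y  # unit-area basis spectrum of the class

    basis_free = class_profile(free, wf)
    basis_bonded = class_profile(bonded, wb)
    rng = np.random.default_rng(seed)
    spectra = []
    for t in temperatures:
        r = _two_state_ratio(float(t), delta_h, delta_s)
        w = r / (1.0 + r)
        y = w * basis_free + (1.0 - w) * basis_bonded
        if noise > 0:
            y = y * (1.0 + noise * rng.standard_normal(y.size))
            y = np.clip(y, 0.0, None)
        spectra.append(Spectrum(x, y, modality="FTIR-ATR", temperature=float(t)))
    return SpectralSeries(tuple(spectra), temperatures)


def gen_diffusion(kc: float = 6025.0, d_free: float = 2.69e-10,
                  d_complex: float = 1.30e-10, h_tot: float = 14e-3,
                  g_tot: float = 14e-3, noise: float = 0.0,
                  seed: int = 0) -> DiffusionMeasurement:
    """Fast-exchange DOSY observation of the guest diffusion coefficient.

    Speciates the 1:1 equilibrium at the given totals, averages
    d_obs = (1-f) d_free + f d_complex over the bound fraction f, and adds
    relative Gaussian noise to the observed value.
    """
    if d_complex >= d_free:
        raise ValidationError("d_complex must be below d_free")
    if kc <= 0:
        raise ValidationError("kc must be positive")
    model = BindingModel([(1, 1, math.log10(kc))])
    st = solve_speciation(model, h_tot, g_tot)
    f = st.bound_guest_fraction()
    d_obs = (1.0 - f) * d_free + f * d_complex
    if noise > 0:
        rng = np.random.default_rng(seed)
        d_obs *= 1.0 + noise * rng.standard_normal()
    return DiffusionMeasurement(d_free_guest=d_free, d_obs_guest=float(d_obs),
                                d_complex=d_complex, h_tot=h_tot, g_tot=g_tot)
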