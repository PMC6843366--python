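"""NMR evidence of inclusion: chemical-shift displacements and DOSY.

Complexation perturbs the guest protons' chemical shifts (here a downfield
displacement, the guest sitting near the host's oxygens) and, under fast
exchange, averages the guest's diffusion coefficient between its free and
bound values, so a DOSY experiment yields the bound fraction directly:

    f = (D_free - D_obs) / (D_free - D_complex).

With known totals, inverting the 1:1 mass-action law on f gives an
association constant, an extension beyond the qualitative DOSY comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError

__all__ = [
    "shift_displacements",
    "DiffusionMeasurement",
    "bound_fraction",
    "kc_from_diffusion",
]


def shift_displacements(free, complexed, labels=None) -> pd.DataFrame:
    """Per-proton displacement table Delta-delta = delta_complex - delta_free.

    ``free`` and ``complexed`` may be mappings from proton label to ppm, or
    sequences accompanied by ``labels``.  The returned frame carries a
    ``downfield`` attribute: True iff every displacement is positive.
    """
    if isinstance(free, dict) and isinstance(complexed, dict):
        if set(free) != set(complexed):
            raise ValidationError("proton labels of free and complexed shifts differ")
        labels = list(free)
        f = np.array([free[k] for k in labels], dtype=float)
        c = np.array([complexed[k] for k in labels], dtype=float)
    else:
        f = np.asarray(free, dtype=float)
        c = np.asarray(complexed, dtype=float)
        if f.size != c.size:
            raise ValidationError("shift lists have different lengths")
        labels = list(labels) if labels is not None else [str(i + 1) for i in range(f.size)]
        if len(labels) != f.size:
            raise ValidationError("label count does not match shift count")
    table = pd.DataFrame({
        "proton": labels,
        "delta_free_ppm": f,
        "delta_complex_ppm": c,
        "delta_delta_ppm": c - f,
    })
    table.attrs["downfield"] = bool(np.all(c - f > 0))
    return table


@dataclass(frozen=True)
class DiffusionMeasurement:
    """Guest diffusion coefficients (m^2/s) for the two-site exchange model.

    ``d_complex`` is the diffusion of the fully bound guest, in practice
    approximated by the host's (or the complex's) measured value.
    """

    d_free_guest: float
    d_obs_guest: float
    d_complex: float
    h_tot: float | None = None
    g_tot: float | None = None

    def __post_init__(self):
        for name in ("d_free_guest", "d_obs_guest", "d_complex"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.d_complex >= self.d_free_guest:
            raise DomainError("d_complex must be smaller than d_free_guest")


def bound_fraction(meas: DiffusionMeasurement) -> float:
    """Bound guest fraction from fast-exchange population-weighted diffusion.

    Observed values outside [d_complex, d_free_guest] are clipped into [0, 1]
    with a warning (noise can push D_obs slightly past either limit).
    """
    f = (meas.d_free_guest - meas.d_obs_guest) / (meas.d_free_guest - meas.d_complex)
    if not 0.0 <= f <= 1.0:
        warnings.warn(f"bound fraction {f:.3f} outside [0, 1]; clipping")
        f = min(max(f, 0.0), 1.0)
    return float(f)


def kc_from_diffusion(f: float, h_tot: float, g_tot: float) -> float:
    """1:1 association constant from a bound fraction and the totals.

    With bound guest b = f * g_tot, Kc = b / ((g_tot - b)(h_tot - b)).
    """
    if not 0.0 < f < 1.0:
        raise DomainError("bound fraction must lie strictly between 0 and 1")
    if h_tot <= 0 or g_tot <= 0:
        raise DomainError("totals must be positive")
    b = f * g_tot
    if b >= h_tot:
        raise DomainError("bound guest exceeds the available host")
    return b / ((g_tot - b) * (h_tot - b))
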