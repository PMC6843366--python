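"""Spectral containers and I/O.

A :class:`Spectrum` is a single intensity trace on a strictly monotone axis
(wavenumber in cm^-1 for vibrational data, wavelength in nm for UV-Vis),
optionally tagged with a modality and a temperature.  A
:class:`SpectralSeries` is an ordered stack of spectra sharing one axis grid,
indexed by a per-spectrum condition such as temperature or titrant
concentration.

Two plain-text dialects are supported: a two-column CSV (``axis,intensity``,
optional single header line) and JCAMP-DX (``##XYDATA=(X++(Y..Y))`` and
``##XYPOINTS=(XY..XY)`` forms), which is the lingua franca for exchanging
infrared spectra.  ``##TEMPERATURE`` is honoured on read and emitted on
write when the spectrum carries one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import FormatError, ValidationError

__all__ = [
    "Spectrum",
    "SpectralSeries",
    "read_spectrum",
    "write_spectrum",
    "crop",
    "normalize",
]

_MODALITIES = {"FTIR-ATR", "NIR", "Raman", "UV-Vis"}


@dataclass(frozen=True)
class Spectrum:
    """One intensity trace on a strictly ascending axis.

    Parameters
    ----------
    axis : array_like
        Wavenumber (cm^-1) or wavelength (nm).  Stored ascending; a
        descending input is reversed together with the intensities.
    intensity : array_like
        Absorbance or counts, same length as ``axis``.
    modality : str, optional
        One of ``FTIR-ATR``, ``NIR``, ``Raman``, ``UV-Vis``.
    temperature : float, optional
        Sample temperature in kelvin.
    """

    axis: np.ndarray
    intensity: np.ndarray
    modality: str | None = None
    temperature: float | None = None

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValidationError("axis and intensity must be 1-D")
        if axis.size != intensity.size:
            raise ValidationError(
                f"axis ({axis.size}) and intensity ({intensity.size}) lengths differ"
            )
        if axis.size < 2:
            raise ValidationError("a spectrum needs at least two points")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(intensity))):
            raise ValidationError("axis and intensity must be finite")
        d = np.diff(axis)
        if np.all(d < 0):  # descending input: flip to the internal convention
            axis = axis[::-1]
            intensity = intensity[::-1]
            d = -d[::-1]
        if not np.all(d > 0):
            raise ValidationError("axis must be strictly monotone (duplicates found)")
        if self.modality is not None and self.modality not in _MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {sorted(_MODALITIES)}"
            )
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self):
        return self.axis.size

    @property
    def area(self) -> float:
        """Trapezoidal integral of intensity over the axis."""
        return float(np.trapezoid(self.intensity, self.axis))

    def crop(self, lo: float, hi: float) -> "Spectrum":
        return crop(self, lo, hi)

    def normalize(self, mode: str = "unit-area") -> "Spectrum":
        return normalize(self, mode)

    def with_intensity(self, intensity) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class SpectralSeries:
    """Spectra on one shared grid, ordered by a scalar condition.

    ``condition`` is typically temperature (K) or titrant concentration (M);
    members are sorted by it on construction.
    """

    spectra: tuple
    condition: np.ndarray = field(default=None)

    def __post_init__(self):
        spectra = tuple(self.spectra)
        if len(spectra) < 1:
            raise ValidationError("a series needs at least one spectrum")
        cond = np.asarray(self.condition, dtype=float)
        if cond.size != len(spectra):
            raise ValidationError("one condition value per spectrum required")
        if np.unique(cond).size != cond.size:
            raise ValidationError("condition values must be unique")
        ref = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.size != ref.size or not np.allclose(s.axis, ref, rtol=0, atol=0):
                raise ValidationError("all spectra in a series must share one axis grid")
        order = np.argsort(cond)
        object.__setattr__(self, "spectra", tuple(spectra[i] for i in order))
        object.__setattr__(self, "condition", cond[order])

    def __len__(self):
        return len(self.spectra)

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].axis

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) stack of intensities in condition order."""
        return np.vstack([s.intensity for s in self.spectra])


def crop(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to the closed axis window [lo, hi].

    The bounds may be given in either order (spectroscopists quote IR windows
    high-to-low); intensities of retained points are untouched.
    """
    lo, hi = (lo, hi) if lo < hi else (hi, lo)
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"crop window [{lo}, {hi}] retains fewer than two axis points"
        )
    return replace(spectrum, axis=spectrum.axis[mask], intensity=spectrum.intensity[mask])


def normalize(spectrum: Spectrum, mode: str = "unit-area") -> Spectrum:
    """Scale intensities to unit trapezoidal area or unit maximum.

    Unit-area normalization is the convention for comparing O-H envelopes
    across temperature: it removes changes in the effective number of
    absorbers so only the band *shape* carries information.
    """
    if mode == "unit-area":
        a = spectrum.area
        if a <= 0:
            raise ValidationError("unit-area normalization needs positive integral")
        return spectrum.with_intensity(spectrum.intensity / a)
    if mode == "unit-max":
        m = spectrum.intensity.max()
        if m <= 0:
            raise ValidationError("unit-max normalization needs a positive maximum")
        return spectrum.with_intensity(spectrum.intensity / m)
    raise ValidationError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# file I/O


def _infer_format(path) -> str:
    p = str(path).lower()
    if p.endswith((".jdx", ".dx", ".jcm", ".jcamp")):
        return "jcamp-dx"
    return "csv"


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from CSV or JCAMP-DX.

    ``format`` is inferred from the extension when omitted (.jdx/.dx →
    JCAMP-DX, anything else CSV).
    """
    fmt = format or _infer_format(path)
    with open(path, "r") as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if fmt == "csv":
        return _read_csv(text, path)
    if fmt == "jcamp-dx":
        return _read_jcamp(text, path)
    raise ValidationError(f"unknown spectrum format {fmt!r}")


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> None:
    """Write a spectrum so that :func:`read_spectrum` round-trips it."""
    fmt = format or _infer_format(path)
    if fmt == "csv":
        text = _to_csv(spectrum)
    elif fmt == "jcamp-dx":
        text = _to_jcamp(spectrum)
    else:
        raise ValidationError(f"unknown spectrum format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(text)


def _read_csv(text: str, path) -> Spectrum:
    modality = None
    temperature = None
    rows = []
    lines = text.splitlines()
    for i, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(modality|temperature)\s*[:=]\s*(.+)", line, re.I)
            if m:
                key, val = m.group(1).lower(), m.group(2).strip()
                if key == "modality":
                    modality = val
                else:
                    temperature = float(val)
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise FormatError(f"{path}: expected two comma-separated columns", line=i)
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if not rows:  # single header line auto-detected by non-numeric token
                continue
            raise FormatError(f"{path}: non-numeric value {parts[0]!r}", line=i)
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than two data rows")
    arr = np.asarray(rows)
    return Spectrum(arr[:, 0], arr[:, 1], modality=modality, temperature=temperature)


def _to_csv(spectrum: Spectrum) -> str:
    out = []
    if spectrum.modality is not None:
        out.append(f"# modality: {spectrum.modality}")
    if spectrum.temperature is not None:
        out.append(f"# temperature: {spectrum.temperature:.6g}")
    out.append("axis,intensity")
    out.extend(
        f"{x:.10g},{y:.10g}" for x, y in zip(spectrum.axis, spectrum.intensity)
    )
    return "\n".join(out) + "\n"


def _to_jcamp(spectrum: Spectrum) -> str:
    lines = [
        "##TITLE=cyclofit spectrum",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
    ]
    if spectrum.modality is not None:
        lines.append(f"##$MODALITY={spectrum.modality}")
    if spectrum.temperature is not None:
        lines.append(f"##TEMPERATURE={spectrum.temperature:.6g}")
    lines.append(f"##NPOINTS={len(spectrum)}")
    lines.append("##XYPOINTS=(XY..XY)")
    lines.extend(
        f"{x:.10g}, {y:.10g}" for x, y in zip(spectrum.axis, spectrum.intensity)
    )
    lines.append("##END=")
    return "\n".join(lines) + "\n"


_NUM = r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?"


def _read_jcamp(text: str, path) -> Spectrum:
    headers: dict[str, str] = {}
    data_mode = None  # "xypoints" | "xydata"
    xs: list[float] = []
    ys: list[float] = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("$$")[0].strip()  # strip inline comments
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "END":
                break
            if key == "XYPOINTS":
                data_mode = "xypoints"
            elif key == "XYDATA":
                data_mode = "xydata"
            else:
                headers[key] = val
            continue
        if data_mode == "xypoints":
            nums = re.findall(_NUM, line)
            if len(nums) % 2:
                raise FormatError(f"{path}: odd number of values in XY pair line", line=i)
            vals = list(map(float, nums))
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
        elif data_mode == "xydata":
            nums = re.findall(_NUM, line)
            if len(nums) < 2:
                raise FormatError(f"{path}: XYDATA line needs X then Y values", line=i)
            xs.append(float(nums[0]))
            ys.extend(map(float, nums[1:]))
        # header block before any data table: ignore free text
    if data_mode is None or not ys:
        raise FormatError(f"{path}: no XYDATA/XYPOINTS table found")
    yfac = float(headers.get("YFACTOR", 1.0))
    xfac = float(headers.get("XFACTOR", 1.0))
    if data_mode == "xydata":
        n = int(headers.get("NPOINTS", len(ys)))
        firstx = float(headers["FIRSTX"]) if "FIRSTX" in headers else xs[0] * xfac
        lastx = float(headers["LASTX"]) if "LASTX" in headers else None
        if lastx is not None and n > 1:
            axis = np.linspace(firstx, lastx, n)
        else:
            # fall back to per-line start X and uniform spacing from DELTAX
            dx = float(headers.get("DELTAX", 1.0))
            axis = firstx + dx * np.arange(len(ys))
        intensity = np.asarray(ys[:n], dtype=float) * yfac
        axis = axis[: intensity.size]
    else:
        axis = np.asarray(xs, dtype=float) * xfac
        intensity = np.asarray(ys, dtype=float) * yfac
    temperature = None
    if "TEMPERATURE" in headers:
        temperature = float(re.findall(_NUM, headers["TEMPERATURE"])[0])
    modality = headers.get("$MODALITY")
    try:
        return Spectrum(axis, intensity, modality=modality, temperature=temperature)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc
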