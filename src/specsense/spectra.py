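"""Wavelength-grid spectra and the rhodopsin absorbance template.

A :class:`Spectrum` is a function of wavelength sampled on a strictly
increasing nanometre grid.  The same container holds spectral sensitivity
curves, opsin absorbance templates, wing reflectance and LED/monochromator
emission spectra; the ``kind`` tag records which.

The visual-pigment template implemented here is the A1 alpha-band template
of Govardovskii et al. (2000): a universal absorbance curve parameterized
only by the wavelength of peak absorbance (lambda-max).  The beta
(short-wavelength) band is deliberately omitted — over the 310–630 nm
range used for butterfly photoreceptor fits the alpha band dominates, and
red-shifted long-wavelength cells whose sensitivity is shaped by screening
pigments are classified but not mechanistically modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "Spectrum",
    "rhodopsin_template",
    "template_value",
    "resample",
    "normalize_peak",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

SPECTRUM_KINDS = ("sensitivity", "absorbance", "reflectance", "emission", "response")

# Govardovskii A1 alpha-band constants
_A = 69.7
_B = 28.0
_b = 0.922
_C = -14.9
_c = 1.104
_D = 0.674


@dataclass(frozen=True)
class Spectrum:
    """A spectral quantity sampled on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "response"

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.values))])

    def __call__(self, wl) -> np.ndarray:
        """Linear interpolation within the grid span (no extrapolation)."""
        wl = np.asarray(wl, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError("requested wavelength outside the spectrum's span")
        return np.interp(wl, self.wavelengths, self.values)


def _alpha_band(x: np.ndarray, a: float) -> np.ndarray:
    return 1.0 / (
        np.exp(_A * (a - x)) + np.exp(_B * (_b - x)) + np.exp(_C * (_c - x)) + _D
    )


@lru_cache(maxsize=4096)
def _peak_x(a: float) -> float:
    """Argmax of the alpha band in x.

    The raw template peaks a fraction of a percent away from x = 1 (the
    offset drifts with the ``a`` constant); evaluation is re-centered so
    the peak lands exactly at lambda_max.
    """
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda x: -_alpha_band(np.asarray(x), a),
        bounds=(0.9, 1.1),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def template_value(lambda_max: float, wl) -> np.ndarray:
    """Evaluate the (unnormalized) A1 alpha-band template at wavelength(s) wl.

    ``S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D)`` with
    ``x ∝ lambda_max / wl`` and
    ``a = 0.8795 + 0.0459 exp(-(lambda_max-300)^2/11940)``; x is scaled so
    the curve attains its maximum exactly at ``wl = lambda_max``.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside [300, 700]")
    wl = np.asarray(wl, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    x = _peak_x(round(a, 12)) * lambda_max / wl
    return _alpha_band(x, a)


def rhodopsin_template(lambda_max: float, grid=None) -> Spectrum:
    """Absorbance template for a visual pigment peaking at ``lambda_max``.

    Parameters
    ----------
    lambda_max : peak absorbance wavelength in nm, within [300, 700].
    grid : nm array within [250, 800]; default 300–700 nm at 1 nm.

    The returned spectrum is peak-normalized on its grid, so its maximum is
    exactly 1 and sits within half a grid step of ``lambda_max`` (when
    ``lambda_max`` lies inside the grid span).
    """
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 250.0 or grid[-1] > 800.0:
        raise ValueError("template grid must lie within [250, 800] nm")
    vals = template_value(lambda_max, grid)
    return normalize_peak(Spectrum(grid, vals, kind="absorbance"))


def resample(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid within its span."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spectrum.wavelengths[0] or grid[-1] > spectrum.wavelengths[-1]:
        raise ValueError("resample target grid extends beyond the source span")
    return Spectrum(grid, spectrum(grid), kind=spectrum.kind)


def normalize_peak(spectrum: Spectrum) -> Spectrum:
    """Scale so the maximum absolute value is 1 (shape preserved)."""
    peak = float(np.max(np.abs(spectrum.values)))
    if peak == 0.0:
        raise ValueError("cannot peak-normalize an all-zero spectrum")
    return replace(spectrum, values=spectrum.values / peak)


def read_spectrum_csv(path, kind: str = "response") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV with a one-line header."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Spectrum(data[:, 0], data[:, 1], kind=kind)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    header = f"wavelength_nm,{spectrum.kind}"
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths, spectrum.values]),
        delimiter=",",
        header=header,
        comments="",
        fmt="%.10g",
    )
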