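"""Spectral-class and inhibition labeling of QC-passing photoreceptors.

Spectral classes follow the lambda-max partition UV [330, 420) nm,
blue [420, 500), green [500, 580) (requiring a good template fit), and
red-shifted LW >= 580 nm, with a shape-based override: cells whose
half-max bandwidth (relative to lambda-max) exceeds 1.5x the template's
own relative bandwidth are labeled broadband, the signature of blue+LW
opsin co-expression.

Inter-photoreceptor inhibition is scored at a fixed probe wavelength
(530 nm for UV cells, 590 nm for blue cells): a cell is inhibited when its
repeat-mean response there is hyperpolarizing and its magnitude exceeds
5 * baseline_sd / sqrt(n_repeats) (a one-sided criterion on the standard
error of the mean response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ResponseFeatures
from .sensitivity import TemplateFit
from .spectra import Spectrum, template_value

__all__ = [
    "CellSummary",
    "classify_photoreceptor",
    "classify_inhibition",
    "PROBE_WAVELENGTHS",
    "CLASS_BOUNDARIES",
]

CLASS_BOUNDARIES = {"UV": (330.0, 420.0), "blue": (420.0, 500.0),
                    "green": (500.0, 580.0)}
PROBE_WAVELENGTHS = {"UV": 530.0, "blue": 590.0}
GREEN_R2_MIN = 0.8
BROADBAND_RATIO = 1.5


@dataclass
class CellSummary:
    """Per-cell unit of analysis for group statistics."""

    cell_id: str
    individual_id: str
    group: str
    cell_class: str
    lambda_max: float
    r2: float
    inhibited: bool | None = None  # defined only for UV/blue classes
    inhibition_amplitude: float | None = None  # signed, normalized to peak amp
    lmax_latency: float | None = None  # ms
    probe_latency: float | None = None  # ms
    qc_passed: bool = True
    qc_reasons: tuple = ()


def _halfmax_span(wl: np.ndarray, vals: np.ndarray) -> float:
    """Width of the region where vals >= 0.5 * max, linearly interpolated."""
    v = vals / vals.max()
    above = v >= 0.5
    if not above.any():
        return 0.0
    idx = np.flatnonzero(above)
    lo_i, hi_i = idx[0], idx[-1]
    lo = wl[lo_i]
    if lo_i > 0:
        lo = np.interp(0.5, [v[lo_i - 1], v[lo_i]], [wl[lo_i - 1], wl[lo_i]])
    hi = wl[hi_i]
    if hi_i < wl.size - 1:
        hi = np.interp(0.5, [v[hi_i + 1], v[hi_i]], [wl[hi_i + 1], wl[hi_i]])
    return float(hi - lo)


def relative_bandwidth(sens: Spectrum) -> float:
    """Half-max span of the sensitivity divided by its peak wavelength."""
    keep = sens.values > 0
    return _halfmax_span(sens.wavelengths[keep], sens.values[keep]) / sens.peak_wavelength


def template_relative_bandwidth(lambda_max: float, grid=None) -> float:
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    vals = template_value(lambda_max, grid)
    return _halfmax_span(grid, vals) / lambda_max


def classify_photoreceptor(fit: TemplateFit, sens: Spectrum) -> str:
    """Assign a spectral class from the template fit and curve shape."""
    lmax = fit.lambda_max
    # shape-based broadband check first: it applies regardless of lambda-max
    if relative_bandwidth(sens) > BROADBAND_RATIO * template_relative_bandwidth(lmax):
        return "broadband"
    if CLASS_BOUNDARIES["UV"][0] <= lmax < CLASS_BOUNDARIES["UV"][1]:
        return "UV"
    if CLASS_BOUNDARIES["blue"][0] <= lmax < CLASS_BOUNDARIES["blue"][1]:
        return "blue"
    if CLASS_BOUNDARIES["green"][0] <= lmax < CLASS_BOUNDARIES["green"][1]:
        return "green" if fit.r2 >= GREEN_R2_MIN else "unknown"
    if lmax >= CLASS_BOUNDARIES["green"][1]:
        return "redLW"
    return "unknown"


def classify_inhibition(
    cell_class: str,
    probe_features: ResponseFeatures,
    peak_amplitude: float,
    n_repeats: int = 4,
) -> tuple:
    """Inhibition flag and signed normalized probe amplitude.

    Returns ``(inhibited, inhibition_amplitude)``; both are None when the
    class has no probe wavelength or probe data are missing.
    """
    if cell_class not in PROBE_WAVELENGTHS:
        return None, None
    if probe_features is None:
        return None, None
    sem_scale = max(probe_features.baseline_sd, 0.05) / np.sqrt(max(n_repeats, 1))
    amp = probe_features.amplitude
    inhibited = bool(amp < 0 and abs(amp) > 5.0 * sem_scale)
    norm = amp / peak_amplitude if peak_amplitude else np.nan
    return inhibited, float(norm)
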