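"""Predicted photoreceptor excitation by wing stimuli.

The drive a wing delivers to a photoreceptor is modeled as the quantum-
catch-style integral of the wing reflectance weighted by the receptor's
opsin absorbance template (and optionally an illuminant):

    E(lambda_max, wing) = integral R(lambda) S(lambda) L(lambda) dlambda,

computed by trapezoidal integration on a common wavelength grid, with a
flat illuminant by default.  No receptor-noise color space is involved:
the question is only how strongly each wing color excites a UV receptor as
its spectral tuning varies.  For display, excitations are normalized per
lambda_max so that the most excitatory wing color scores 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .spectra import Spectrum, resample, rhodopsin_template

__all__ = ["predicted_excitation", "excitation_sweep"]


def predicted_excitation(
    reflectance: Spectrum,
    lambda_max: float,
    illuminant: Spectrum | None = None,
    grid=None,
    relative: bool = False,
) -> float:
    """Excitation integral of one wing spectrum through one template.

    With ``relative=True`` the integral is divided by the template's own
    integral ``integral S L dlambda`` — the catch relative to the
    receptor's overall sensitivity (its adapted drive).  The raw integral
    scales with template bandwidth and hence with lambda_max; the relative
    catch is the quantity that stays invariant when a wing excites
    receptors of different tuning "identically".
    """
    if grid is None:
        lo = max(reflectance.wavelengths[0], 300.0)
        hi = min(reflectance.wavelengths[-1], 700.0)
        if illuminant is not None:
            lo = max(lo, illuminant.wavelengths[0])
            hi = min(hi, illuminant.wavelengths[-1])
        if lo >= hi:
            warnings.warn("disjoint wavelength supports; excitation is 0")
            return 0.0
        grid = np.arange(lo, hi + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    r = resample(reflectance, grid).values
    s = rhodopsin_template(lambda_max, grid).values
    if illuminant is not None:
        s = s * resample(illuminant, grid).values
    e = float(np.trapezoid(r * s, grid))
    if relative:
        return e / float(np.trapezoid(s, grid))
    return e


def excitation_sweep(
    colors: dict,
    lambda_max_range,
    illuminant: Spectrum | None = None,
) -> pd.DataFrame:
    """Excitation for each (lambda_max, wing color) pair.

    ``colors`` maps a color label to its reflectance Spectrum.  The result
    has columns lambda_max_nm, color, excitation (raw integral) and
    excitation_norm (normalized so max over colors = 1 at each lambda_max).
    """
    rows = []
    for lmax in np.asarray(lambda_max_range, dtype=float):
        raw = {
            label: predicted_excitation(spec, lmax, illuminant=illuminant)
            for label, spec in colors.items()
        }
        rel = {
            label: predicted_excitation(spec, lmax, illuminant=illuminant,
                                        relative=True)
            for label, spec in colors.items()
        }
        top = max(raw.values())
        for label, e in raw.items():
            rows.append(
                dict(
                    lambda_max_nm=float(lmax),
                    color=label,
                    excitation=e,
                    excitation_rel=rel[label],
                    excitation_norm=e / top if top > 0 else 0.0,
                )
            )
    return pd.DataFrame(rows)
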