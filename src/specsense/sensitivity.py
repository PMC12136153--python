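"""Spectral sensitivity estimation.

The isoquantal spectral responses of a photoreceptor are converted to a
spectral sensitivity curve by inverting the cell's own intensity-response
(V–log I) relation, modeled with the Naka–Rushton equation

    V(I) = v_max * I^n / (I^n + K^n).

For a mean depolarizing response V(lambda) to the standard intensity I0,
the equivalent intensity the cell effectively absorbed is
``I_eq = K * (V / (v_max - V))**(1/n)`` and the relative sensitivity is
``S(lambda) = I_eq(lambda) / I0``, peak-normalized.  Hyperpolarizing mean
responses reflect inhibitory input rather than opsin absorption; they map
to S = 0 and are excluded from template fitting (the annotation is kept).

The wavelength of peak sensitivity (lambda-max) is then estimated by
least-squares fitting of the peak-normalized sensitivity with the
rhodopsin template: a 1 nm grid scan over the search range followed by
bounded local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .simulate import naka_rushton
from .spectra import Spectrum, normalize_peak, template_value

__all__ = [
    "VLogICurve",
    "NakaRushtonFit",
    "TemplateFit",
    "fit_naka_rushton",
    "responses_to_sensitivity",
    "fit_lambda_max",
]

R2_FLOOR = 0.5  # template fits below this are flagged unreliable


@dataclass(frozen=True)
class VLogICurve:
    """Mean response amplitude vs log10 stimulus intensity at one wavelength."""

    log10_intensity: np.ndarray
    response: np.ndarray  # mV, mean over repeats
    wavelength: float  # nm

    def __post_init__(self):
        li = np.asarray(self.log10_intensity, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if li.shape != r.shape or li.ndim != 1:
            raise ValueError("log10_intensity and response must be equal-length 1-D")
        object.__setattr__(self, "log10_intensity", li)
        object.__setattr__(self, "response", r)


@dataclass(frozen=True)
class NakaRushtonFit:
    v_max: float  # mV
    log10_K: float  # log10 photons/cm^2/s
    n: float  # Hill exponent
    rss: float  # mV^2
    ok: bool = True
    message: str = ""

    def predict(self, intensity):
        return naka_rushton(intensity, self.v_max, 10.0**self.log10_K, self.n)


@dataclass(frozen=True)
class TemplateFit:
    lambda_max: float  # nm
    r2: float
    residuals: np.ndarray
    reliable: bool


def fit_naka_rushton(curve: VLogICurve, noise_sd: float = 0.0) -> NakaRushtonFit:
    """Least-squares Naka–Rushton fit of a V–log(I) series.

    Requires at least 5 intensity levels and a peak response above five
    times ``noise_sd`` (when a noise estimate is supplied).  Degenerate
    curves yield a fit flagged ``ok=False`` rather than an exception.
    """
    li = curve.log10_intensity
    v = curve.response
    if li.size < 5:
        raise ValueError("need at least 5 intensity levels for a V-log(I) fit")
    vmax0 = float(v.max())
    if vmax0 <= 0 or (noise_sd > 0 and vmax0 < 5.0 * noise_sd):
        return NakaRushtonFit(np.nan, np.nan, np.nan, np.nan, ok=False,
                              message="response indistinguishable from noise")
    # Spearman-style monotonicity guard: heavily non-monotone curves fail
    order = np.argsort(li)
    if np.corrcoef(li[order], v[order])[0, 1] < 0.2:
        return NakaRushtonFit(np.nan, np.nan, np.nan, np.nan, ok=False,
                              message="non-monotone intensity-response curve")

    half = vmax0 / 2.0
    lk0 = float(np.interp(half, v[order], li[order]))

    def resid(theta):
        v_max, lk, n = theta
        return naka_rushton(10.0**li, v_max, 10.0**lk, n) - v

    res = optimize.least_squares(
        resid,
        x0=[vmax0 * 1.05, lk0, 1.0],
        bounds=([1e-6, li.min() - 4.0, 0.05], [np.inf, li.max() + 4.0, 20.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    v_max, lk, n = res.x
    return NakaRushtonFit(
        v_max=float(v_max), log10_K=float(lk), n=float(n),
        rss=float(np.sum(res.fun**2)), ok=True,
    )


def responses_to_sensitivity(
    wavelengths,
    responses,
    nr: NakaRushtonFit,
    iso_intensity: float,
) -> tuple:
    """Invert mean spectral responses to a peak-normalized sensitivity curve.

    Returns ``(Spectrum, qc_flags)`` where the spectrum carries S = 0 at
    hyperpolarizing wavelengths and ``qc_flags`` records clamping events and
    the hyperpolarizing wavelengths themselves.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    v = np.asarray(responses, dtype=float)
    order = np.argsort(wavelengths)
    wavelengths, v = wavelengths[order], v[order]
    if not nr.ok:
        raise ValueError("cannot invert responses with a failed Naka-Rushton fit")
    flags = {"clamped": [], "hyperpolarizing": []}
    s = np.zeros_like(v)
    for i, (wl, vi) in enumerate(zip(wavelengths, v)):
        if vi <= 0:
            if vi < 0:
                flags["hyperpolarizing"].append(float(wl))
            continue
        if vi >= nr.v_max:
            flags["clamped"].append(float(wl))
            vi = nr.v_max * 0.999
        i_eq = 10.0**nr.log10_K * (vi / (nr.v_max - vi)) ** (1.0 / nr.n)
        s[i] = i_eq / iso_intensity
    spec = normalize_peak(Spectrum(wavelengths, s, kind="sensitivity"))
    return spec, flags


def _template_sse(lmax: float, wl: np.ndarray, s: np.ndarray) -> float:
    t = template_value(lmax, wl)
    t = t / t.max()
    return float(np.sum((s - t) ** 2))


def fit_lambda_max(
    sens: Spectrum,
    search: tuple = (330.0, 650.0),
    exclude_zero: bool = True,
    r2_floor: float = R2_FLOOR,
) -> TemplateFit:
    """Estimate lambda-max by rhodopsin-template least squares.

    A 1 nm grid scan over ``search`` locates the global optimum basin
    (ties broken toward the smallest lambda-max), then bounded scalar
    minimization refines it.  Wavelengths with S = 0 (hyperpolarizing or
    absent responses) are excluded when ``exclude_zero``.
    """
    wl = sens.wavelengths
    s = np.asarray(sens.values, dtype=float)
    if exclude_zero:
        keep = s > 0
        wl, s = wl[keep], s[keep]
    if wl.size < 4:
        raise ValueError("too few usable wavelengths for a template fit")
    s = s / s.max()

    lo, hi = search
    grid = np.arange(lo, hi + 0.5, 1.0)
    sse = np.array([_template_sse(g, wl, s) for g in grid])
    best = grid[int(np.argmin(sse))]  # argmin returns the first (smallest) tie

    res = optimize.minimize_scalar(
        _template_sse,
        bounds=(max(lo, best - 2.0), min(hi, best + 2.0)),
        args=(wl, s),
        method="bounded",
        options={"xatol": 1e-4},
    )
    lmax = float(res.x)
    t = template_value(lmax, wl)
    t = t / t.max()
    residuals = s - t
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 0.0
    return TemplateFit(
        lambda_max=lmax, r2=r2, residuals=residuals, reliable=bool(r2 >= r2_floor)
    )
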