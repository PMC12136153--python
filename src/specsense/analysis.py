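"""Per-cell analysis: recording -> features -> sensitivity -> labels.

This is the chain applied to every photoreceptor: quality control,
per-wavelength response features, the Naka–Rushton fit of the intensity
series at the empirically best wavelength, inversion to a spectral
sensitivity curve, rhodopsin-template estimation of lambda-max, spectral
classification, and inhibition scoring at the class's probe wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PROBE_WAVELENGTHS, CellSummary, classify_inhibition, classify_photoreceptor
from .features import adaptation_deltas, extract_features, qc_cell
from .recording import CellRecording
from .sensitivity import (
    VLogICurve,
    fit_lambda_max,
    fit_naka_rushton,
    responses_to_sensitivity,
)
from .simulate import STANDARD_INTENSITY

__all__ = ["CellAnalysis", "analyze_recording", "analyze_experiment", "cells_table"]


@dataclass
class CellAnalysis:
    summary: CellSummary
    sensitivity: object | None = None
    nr_fit: object | None = None
    features: dict = field(default_factory=dict)  # wavelength -> ResponseFeatures
    adaptation: object | None = None
    flags: dict = field(default_factory=dict)


def analyze_recording(
    rec: CellRecording,
    iso_intensity: float = STANDARD_INTENSITY,
    default_n: float = 1.0,
) -> CellAnalysis:
    """Run the full per-cell chain on one recording.

    When the intensity series is missing or its fit fails, the class-default
    Hill exponent ``default_n`` (with half-saturation at the empirical peak's
    half response) is substituted and flagged.
    """
    features = {}
    for wl in rec.wavelengths:
        reps = rec.select(kind="spectral", led="off", wavelength=wl)
        if reps:
            features[float(wl)] = extract_features(reps)
    if not features:
        raise ValueError(f"cell {rec.cell_id}: no spectral presentations")

    qc = qc_cell(rec, features_by_wavelength=features)
    flags = {"qc_reasons": list(qc.reasons)}

    wls = np.array(sorted(features))
    amps = np.array([features[w].amplitude for w in wls])
    peak_wl = float(wls[int(np.argmax(amps))])
    peak_amp = float(amps.max())

    # Naka-Rushton fit of the intensity series at the empirical peak
    vlogi_traces = rec.select(kind="vlogi")
    nr = None
    if vlogi_traces:
        pts = sorted(
            ((np.log10(tr.intensity), extract_features(tr).amplitude)
             for tr in vlogi_traces),
            key=lambda t: t[0],
        )
        curve = VLogICurve(
            log10_intensity=np.array([p[0] for p in pts]),
            response=np.array([p[1] for p in pts]),
            wavelength=vlogi_traces[0].wavelength,
        )
        nr = fit_naka_rushton(curve)
        if not nr.ok:
            flags["nr_failed"] = nr.message
            nr = None
    if nr is None:
        # class-default fallback: exponent n, half-saturation where the peak
        # response would sit at ~97% of saturation (the protocol's top-of-
        # sigmoid placement); flagged so downstream users can exclude.
        from .sensitivity import NakaRushtonFit

        flags.setdefault("nr_fallback", True)
        v_max = peak_amp / 0.969
        nr = NakaRushtonFit(
            v_max=v_max, log10_K=np.log10(iso_intensity) - 1.5, n=default_n,
            rss=np.nan, ok=True, message="class-default fallback",
        )

    sens, sflags = responses_to_sensitivity(wls, amps, nr, iso_intensity)
    flags.update(sflags)
    tfit = fit_lambda_max(sens)
    cls = classify_photoreceptor(tfit, sens)

    probe_wl = PROBE_WAVELENGTHS.get(cls)
    probe_feat = None
    if probe_wl is not None:
        # nearest measured wavelength to the nominal probe
        j = int(np.argmin(np.abs(wls - probe_wl)))
        probe_feat = features[float(wls[j])]
    n_reps = max(len(rec.select(kind="spectral", led="off", wavelength=peak_wl)), 1)
    inhibited, inh_amp = classify_inhibition(cls, probe_feat, peak_amp, n_repeats=n_reps)

    adapt = None
    if {"before", "during", "after"} <= rec.led_phases:
        triple = [
            extract_features([tr for tr in rec.traces if tr.led == phase])
            for phase in ("before", "during", "after")
        ]
        adapt = adaptation_deltas(*triple)

    summary = CellSummary(
        cell_id=rec.cell_id,
        individual_id=rec.individual_id,
        group=rec.group,
        cell_class=cls,
        lambda_max=tfit.lambda_max,
        r2=tfit.r2,
        inhibited=inhibited,
        inhibition_amplitude=inh_amp,
        lmax_latency=features[peak_wl].onset_latency,
        probe_latency=(probe_feat.onset_latency if probe_feat is not None else None),
        qc_passed=qc.passed,
        qc_reasons=qc.reasons,
    )
    return CellAnalysis(
        summary=summary, sensitivity=sens, nr_fit=nr, features=features,
        adaptation=adapt, flags=flags,
    )


def analyze_experiment(recordings, iso_intensity: float = STANDARD_INTENSITY) -> list:
    return [analyze_recording(rec, iso_intensity=iso_intensity) for rec in recordings]


def cells_table(analyses) -> pd.DataFrame:
    """Flatten per-cell summaries into the cells CSV schema."""
    rows = []
    for a in analyses:
        s = a.summary
        rows.append(
            dict(
                cell_id=s.cell_id,
                individual_id=s.individual_id,
                group=s.group,
                cell_class=s.cell_class,
                lambda_max_nm=s.lambda_max,
                r2=s.r2,
                inhibited=s.inhibited,
                inhibition_amplitude=s.inhibition_amplitude,
                lmax_latency_ms=s.lmax_latency,
                probe_latency_ms=s.probe_latency,
                qc_passed=s.qc_passed,
                qc_reasons=";".join(s.qc_reasons),
            )
        )
    return pd.DataFrame(rows)
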