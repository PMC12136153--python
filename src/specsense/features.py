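"""Per-trace and per-cell feature extraction.

Operations defined here mirror how intracellular photoreceptor recordings
are quantified: the resting potential is characterized over the 500 ms
immediately preceding the flash; onset latency is the first post-onset time
at which the voltage departs from the baseline mean by more than five
baseline standard deviations (sustained for at least 1 ms); response
amplitude is the signed extremum of the repeat-averaged trace in a
post-onset window; half-max duration is the total time the depolarizing
response stays above half its peak.  Adapting-LED experiments are reduced
to three deltas (resting-potential shift, amplitude attenuation, recovery),
and cells failing quality control (max depolarization < 30 mV, LED recovery
< 80%, or excessive baseline drift) are flagged out of downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import CellRecording, Trace

__all__ = [
    "ResponseFeatures",
    "AdaptationDeltas",
    "QCResult",
    "baseline_stats",
    "onset_latency",
    "halfmax_duration",
    "average_traces",
    "extract_features",
    "adaptation_deltas",
    "qc_cell",
]

BASELINE_WINDOW = 500.0  # ms before onset used for resting-potential stats
SD_FLOOR = 0.05  # mV; substitute for pathological zero-noise baselines
DEBOUNCE = 1.0  # ms a threshold crossing must be sustained
RESPONSE_WINDOW = 500.0  # ms after onset searched for the response extremum
SMOOTH_MS = 5.0  # boxcar applied before amplitude/duration extraction
AMPLITUDE_QC_MV = 30.0  # minimum max depolarization for a healthy cell
RECOVERY_QC = 0.8  # minimum post-LED amplitude recovery fraction
DRIFT_QC_MV_PER_S = 10.0  # maximum |baseline linear trend|


@dataclass(frozen=True)
class ResponseFeatures:
    baseline_mean: float  # mV
    baseline_sd: float  # mV
    amplitude: float  # mV, signed (depolarizing positive)
    polarity: str  # {depolarizing, hyperpolarizing, none}
    onset_latency: float | None  # ms from stimulus onset
    halfmax_duration: float | None  # ms


@dataclass(frozen=True)
class AdaptationDeltas:
    delta_resting: float  # mV, during-LED minus before
    amplitude_ratio: float  # during / before, at lambda-max
    recovery_fraction: float  # after / before
    qc_pass: bool


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple


def _baseline_slice(trace: Trace) -> np.ndarray:
    i_on = int(round(trace.stimulus_onset / trace.dt))
    n_base = int(round(BASELINE_WINDOW / trace.dt))
    if i_on < n_base:
        raise ValueError(
            f"need {BASELINE_WINDOW:.0f} ms of pre-onset baseline, "
            f"have {i_on * trace.dt:.0f} ms"
        )
    return trace.voltage[i_on - n_base : i_on]


def baseline_stats(trace: Trace) -> tuple:
    """Mean and SD of the resting potential over the 500 ms before onset."""
    seg = _baseline_slice(trace)
    return float(seg.mean()), float(seg.std(ddof=0))


def baseline_drift(trace: Trace) -> float:
    """Linear trend of the baseline in mV/s."""
    seg = _baseline_slice(trace)
    t = np.arange(seg.size) * trace.dt / 1000.0  # s
    slope = np.polyfit(t, seg, 1)[0]
    return float(slope)


def onset_latency(trace: Trace, polarity_hint: str | None = None):
    """First sustained 5-sigma departure from baseline after stimulus onset.

    Returns ``(latency_ms, polarity)``; latency is None when the trace never
    departs from baseline.  The crossing must hold for at least 1 ms
    (debounce) so single-sample noise excursions do not register.  With
    ``polarity_hint`` only departures of that sign are considered.
    """
    mean, sd = baseline_stats(trace)
    sd = max(sd, SD_FLOOR)
    thresh = 5.0 * sd
    i_on = int(round(trace.stimulus_onset / trace.dt))
    post = trace.voltage[i_on:]
    dev = post - mean
    if polarity_hint == "depolarizing":
        above = dev > thresh
    elif polarity_hint == "hyperpolarizing":
        above = dev < -thresh
    else:
        above = np.abs(dev) > thresh
    n_debounce = max(1, int(round(DEBOUNCE / trace.dt)))
    if post.size < n_debounce or not above.any():
        return None, "none"
    # first index where the crossing is sustained for n_debounce samples
    sustained = (
        np.convolve(above.astype(int), np.ones(n_debounce, dtype=int), "valid")
        == n_debounce
    )
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        return None, "none"
    i0 = int(idx[0])
    polarity = "depolarizing" if dev[i0] > 0 else "hyperpolarizing"
    return float(i0 * trace.dt), polarity


def halfmax_duration(trace: Trace):
    """Total time the depolarizing response stays above 50% of its peak.

    Crossings are linearly interpolated; disjoint supra-half-max intervals
    are summed.  Returns None when there is no depolarizing response.
    """
    mean, sd = baseline_stats(trace)
    sd = max(sd, SD_FLOOR)
    i_on = int(round(trace.stimulus_onset / trace.dt))
    post = trace.voltage[i_on:] - mean
    peak = post.max()
    if peak <= 5.0 * sd:
        return None
    half = peak / 2.0
    above = post > half
    total = 0.0
    dt = trace.dt
    # walk the crossings, interpolating entry and exit times
    changes = np.flatnonzero(np.diff(above.astype(int)))
    bounds = []
    if above[0]:
        bounds.append(0.0)
    for i in changes:
        frac = (half - post[i]) / (post[i + 1] - post[i])
        bounds.append((i + frac) * dt)
    if above[-1]:
        bounds.append((post.size - 1) * dt)
    for start, stop in zip(bounds[::2], bounds[1::2]):
        total += stop - start
    return float(total)


def smooth_trace(trace: Trace, width_ms: float = SMOOTH_MS) -> Trace:
    """Boxcar low-pass (reflect-padded); amplitude estimation uses this so the
    extremum is not dominated by the maximum of per-sample noise."""
    w = max(1, int(round(width_ms / trace.dt)))
    if w <= 1:
        return trace
    v = trace.voltage
    pad = np.r_[v[w - 1 :: -1], v, v[: -w - 1 : -1]]
    sm = np.convolve(pad, np.ones(w) / w, mode="same")[w : w + v.size]
    out = Trace(
        voltage=sm,
        sample_rate=trace.sample_rate,
        stimulus_onset=trace.stimulus_onset,
        wavelength=trace.wavelength,
        intensity=trace.intensity,
        led=trace.led,
        repeat=trace.repeat,
        kind=trace.kind,
    )
    return out


def average_traces(traces: list) -> Trace:
    """Point-wise repeat average (metadata from the first trace)."""
    if not traces:
        raise ValueError("no traces to average")
    n = min(tr.voltage.size for tr in traces)
    v = np.mean([tr.voltage[:n] for tr in traces], axis=0)
    t0 = traces[0]
    return Trace(
        voltage=v,
        sample_rate=t0.sample_rate,
        stimulus_onset=t0.stimulus_onset,
        wavelength=t0.wavelength,
        intensity=t0.intensity,
        led=t0.led,
        repeat=-1,
        kind=t0.kind,
    )


def extract_features(traces) -> ResponseFeatures:
    """Features of one stimulus condition from its (repeat-averaged) traces.

    Accepts a single Trace or a list of repeats; repeats are averaged before
    extraction.  Amplitude is the signed extremum of the averaged trace in
    the post-onset response window relative to the baseline mean; polarity
    requires the extremum to exceed five baseline SDs.
    """
    if isinstance(traces, Trace):
        avg = traces
    else:
        avg = average_traces(list(traces))
    mean, sd = baseline_stats(avg)
    sd_eff = max(sd, SD_FLOOR)
    sm = smooth_trace(avg)
    i_on = int(round(avg.stimulus_onset / avg.dt))
    n_win = int(round(RESPONSE_WINDOW / avg.dt))
    window = sm.voltage[i_on : i_on + n_win] - mean
    i_ext = int(np.argmax(np.abs(window)))
    amplitude = float(window[i_ext])
    if abs(amplitude) > 5.0 * sd_eff:
        polarity = "depolarizing" if amplitude > 0 else "hyperpolarizing"
    else:
        polarity = "none"
    latency, _ = onset_latency(avg)
    duration = halfmax_duration(sm) if polarity == "depolarizing" else None
    return ResponseFeatures(
        baseline_mean=mean,
        baseline_sd=sd,
        amplitude=amplitude,
        polarity=polarity,
        onset_latency=latency if polarity != "none" else None,
        halfmax_duration=duration,
    )


def adaptation_deltas(
    before: tuple, during: tuple, after: tuple
) -> AdaptationDeltas:
    """LED-adaptation summary from (features, or (amplitude, baseline)) triples.

    Each argument is a ResponseFeatures (whose baseline_mean/amplitude are
    used) measured at the cell's peak wavelength in the corresponding phase.
    """
    feats = []
    for phase in (before, during, after):
        if phase is None:
            raise ValueError("all three LED phases (before/during/after) required")
        feats.append(phase)
    b, d, a = feats
    if b.amplitude == 0:
        raise ValueError("before-phase amplitude is zero; deltas undefined")
    delta_resting = d.baseline_mean - b.baseline_mean
    amplitude_ratio = d.amplitude / b.amplitude
    recovery = a.amplitude / b.amplitude
    return AdaptationDeltas(
        delta_resting=float(delta_resting),
        amplitude_ratio=float(amplitude_ratio),
        recovery_fraction=float(recovery),
        qc_pass=bool(recovery >= RECOVERY_QC),
    )


def qc_cell(recording: CellRecording, features_by_wavelength=None) -> QCResult:
    """Quality control for one cell.

    Fails when the maximum depolarization across the spectral series is
    below 30 mV (proxy for the white-light criterion), when the post-LED
    recovery is below 80%, or when the baseline drifts faster than
    10 mV/s.
    """
    reasons = []
    if features_by_wavelength is None:
        features_by_wavelength = {}
        for wl in recording.wavelengths:
            reps = recording.select(kind="spectral", led="off", wavelength=wl)
            if reps:
                features_by_wavelength[wl] = extract_features(reps)
    if features_by_wavelength:
        max_depol = max(f.amplitude for f in features_by_wavelength.values())
        if max_depol < AMPLITUDE_QC_MV:
            reasons.append("amplitude")
    else:
        reasons.append("no_spectral_data")

    phases = recording.led_phases
    if {"before", "during", "after"} <= phases:
        triple = []
        for phase in ("before", "during", "after"):
            reps = [tr for tr in recording.traces if tr.led == phase]
            triple.append(extract_features(reps))
        deltas = adaptation_deltas(*triple)
        if not deltas.qc_pass:
            reasons.append("led_recovery")

    drift_traces = recording.select(kind="spectral", led="off")
    if drift_traces:
        avg = average_traces(drift_traces[: min(8, len(drift_traces))])
        if abs(baseline_drift(avg)) > DRIFT_QC_MV_PER_S:
            reasons.append("baseline_drift")

    return QCResult(passed=not reasons, reasons=tuple(reasons))
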